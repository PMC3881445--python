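# Methods

This note documents the models and procedures implemented in
`triadnet`, the defaults that matter, and the choices made where the
design was genuinely open.

## Problem setting

Metabolic transformations are modelled as ordered triads (substrate,
enzyme, product). Given a catalogue of compounds and enzymes, the task
is binary: does a candidate triad correspond to a real transformation
(*networking*) or not (*nonnetworking*)? Triads are direction-sensitive:
(a, e, b) and (b, e, a) are different samples, and substrate and product
contribute separate feature blocks.

## Compound encoding (79 descriptors)

Structures are read from SMILES or SDF (RDKit). The shipped registry has
exactly 79 descriptors in three categories:

- **Elemental analysis (14).** Atom fractions and counts on the
  explicit-hydrogen graph (C/H/O/N/P/S/halogen/heteroatom fractions,
  atom and heavy-atom counts). Hydrogens are made explicit before
  counting — an H fraction is meaningless on an implicit-H graph.
- **Geometry (36).** Conformer extents (min/max/span along the three
  principal axes), shape indices (radius of gyration, asphericity,
  eccentricity, spherocity, inertial shape factor, normalized principal
  moment ratios, plane of best fit, maximum interatomic distance) and
  ring topology on the SSSR basis: ring counts partitioned by
  carbo/hetero and aromatic/aliphatic, fused-ring counts (rings sharing
  ≥ 1 bond), ring-system sizes (connected components of the
  shared-bond relation), smallest/largest ring sizes, rotatable bonds
  and stereo double bonds. An acyclic molecule scores 0 on every ring
  descriptor, with 0 as the sentinel for the smallest ring size.
- **Chemistry (29).** Crippen logP and molar refractivity, additive
  atomic polarizability, Labute van der Waals surface area, FreeSASA
  solvent-accessible surface area (total, and restricted to atoms of
  negative / positive Gasteiger partial charge), TPSA, molecular
  weight, H-bond donors/acceptors, charge extremes, and standard
  topological indices (Balaban J, Bertz complexity, Chi/Kappa indices,
  Hall–Kier alpha), amide/double/triple bond counts, sp3-carbon count
  and aromatic-atom fraction.

**Conformers.** 3D coordinates come from seeded distance-geometry
embedding (ETKDGv3) with no force-field refinement, centred on the
centroid and rotated to principal axes (variance order x ≥ y ≥ z, axis
signs fixed by the third central moment). This makes geometry
descriptors deterministic for a (structure, seed) pair and
orientation-stable; molecules that fail to embed fall back to a flat
2D-layout geometry with a logged warning. Force-field or semi-empirical
conformer optimization is out of scope, so geometry values are not
expected to match any particular external descriptor package
numerically.

**Rotatable bonds** use the convention: non-ring single bond between
two non-terminal heavy atoms, excluding amide C–N bonds.

**Imputation.** A descriptor that raises or returns a non-finite value
(e.g. partial charges on exotic atoms) is replaced by its registry
fallback (0.0 unless overridden) and logged. This keeps the fixed-length
vector contract; the registry is replaceable when a different descriptor
set is preferred.

## Enzyme encoding (132 descriptors)

Sequences are read from FASTA; residues outside the 20-letter alphabet
(B, J, O, U, X, Z) are removed with a logged count, and sequences must
have ≥ 4 residues. The default layout concatenates seven blocks,
totalling exactly 132:

| block | length | construction |
|---|---|---|
| amino acids composition | 20 | residue fractions, alphabetical by one-letter code |
| hydrophobicity CTD | 21 | 3 classes: polar RKEDQN / neutral GASTPHY / hydrophobic CLVIMFW |
| polarizability CTD | 21 | 3 classes: GASDT / CPNVEQIL / KMHFRYW |
| normalized van der Waals volume CTD | 21 | 3 classes: GASTPDC / NVEQIL / MHKFRYW |
| polarity CTD | 21 | 3 classes: LIFWCMVY / PATGS / HQRKNED |
| solvent accessibility CTD | 13 | 2 classes: buried ALFCGIVW / exposed (rest) |
| predicted secondary structure CTD | 15 | 3 states H/E/C, distribution at 3 quantiles |

A CTD block for a k-class grouping is: **composition** (k class
fractions), **transition** (k(k−1)/2 unordered adjacent-pair change
frequencies over the L−1 neighbouring pairs), **distribution** (per
class, the sequence position — as % of L — at which the first, 25%, 50%,
75% and 100% of that class's residues have occurred; the q-quantile
occurrence is ⌈qN⌉ for a class with N members, and an absent class
contributes zeros). The secondary-structure block uses quantiles
(first, 50%, 100%) so the layout closes at 132. The groupings are the
canonical CTD property tables, shipped as versioned package data; the
solvent-accessibility block is reduced to two classes (the classic
buried class against everything else) to meet the layout's
dimensionality, and the whole layout is swappable if a different
132-dimension breakdown is preferred.

**Secondary structure** is predicted internally by a deterministic
propensity rule: helix and strand propensities (Chou–Fasman values,
shipped as data) are averaged over a centred window of 5; a position is
H (or E) when the corresponding average is the larger and ≥ 1.0, else C.
Externally computed 3-state strings can be supplied per enzyme id and
bypass the predictor. This keeps the pipeline self-contained; it is not
a modern profile-based predictor, and the block should be read as a
"propensity summary", not a structure assignment.

## Dataset construction

Positive triads come from a three-column TSV (substrate_id, enzyme_id,
product_id) validated against the loaded tables; duplicates are dropped
and unresolvable rows skipped, both logged. Negatives are drawn
uniformly **without replacement** from the full triple space minus the
positives — sampling indexes the space over sorted id lists, so a
(positives, id sets, ratio, seed) tuple always reproduces the same
negative set. The default ratio is 50 negatives per positive, the
design ratio of the study this pipeline implements; the sampler refuses
to run when the combination space cannot hold the requested number of
distinct negatives.

## Feature selection

- **Discretization:** three bins per feature at μ ± t·σ (population σ,
  t = 0.5 by default, configurable); constant columns map to the middle
  bin.
- **Mutual information:** plug-in estimate in bits over observed cells.
- **MaxRel:** descending I(f; class), ties broken by column index.
- **mRMR:** greedy MID (difference) criterion; the quotient variant is
  available behind a flag but the difference form is the default since
  it needs no zero-redundancy guard. Pairwise MI values are computed
  once per (selected, candidate) pair. Features whose discretized
  column is constant are deferred to the end of the ordering: they have
  zero relevance and zero redundancy, so their MID score (exactly 0)
  would otherwise outrank genuinely informative features whose
  redundancy exceeds their relevance — the usual variance prefilter
  expressed as a tie policy.
- **IFS:** every prefix of the ranking is evaluated with the
  cross-validated classifier under a fold assignment fixed across
  prefixes; the selected subset is the smallest prefix attaining the
  maximum MCC. Distances are accumulated one feature at a time, making
  the sweep linear rather than quadratic in the number of prefixes.

## Classification and evaluation

k-NN with Euclidean distance; k must be odd (default 1, the
convention when k is unreported in this literature) and is recorded in
run metadata. Columns are z-scored with statistics fitted on the
training folds only — descriptors span wildly different scales and
Euclidean distance is scale-sensitive. Distance ties break by
training-row index and (even-vote) ties toward the negative class, so
predictions are deterministic. Cross-validation is stratified (at 50:1
imbalance unstratified folds can lack positives entirely) and seeded;
pooled TP/TN/FP/FN over the folds feed SN, SP, ACC and MCC, with
MCC defined as 0 whenever a denominator factor vanishes.

## Synthetic worlds

The generator emits real, encodable data in the pipeline's own input
formats: SMILES built from a valence-safe grammar (acyclic chains,
carbocycles, aromatic/hetero/fused rings, stereo double bonds, nitrile,
carboxyl and phosphate terminals — the first draws cycle through every
scaffold so all ring-descriptor branches are exercised), and enzyme
sequences of length 50–400 drawn from per-enzyme Dirichlet residue
distributions.

Positive triads are planted at the descriptor level: a linear score
Σ_j w_j z_j over z-scored planted columns is evaluated for uniformly
drawn candidate triples, Gaussian noise (sd 0.5) is added, and a triple
is accepted when the score reaches the upper `positive_fraction`
(default 0.2) quantile of the exact score distribution over the triple
space. This keeps every matrix a true image of encodable structures
(encoders are exercised, not bypassed). The weights w_j are the
configured effect sizes (default ±2.0): the realized class-conditional
mean shift grows with w_j but is diluted by the joint score norm
(about 0.4–0.5 sd per feature at ten planted features) — an exact
per-feature shift cannot be targeted when features live on real
molecules. With all effects zero the positives are uniform over the
triple space (null world).

The default planted set (3 substrate, 3 product, 4 enzyme-AAC features)
was chosen for *privacy*: pairwise in-pool correlations below ~0.2 and
no strong proxy column (max |r| with any same-role feature ≤ ~0.5 in a
reference world). Recovery of a planted signal by mRMR is only a
meaningful property when the signal is actually sparse in the feature
space; planting on aggregate composition features whose "collector"
proxies accumulate shift from several planted columns tests the
correlation structure of the encoders, not the selector.

**What the synthetic worlds do not emulate:** chemical reaction
feasibility, enzyme-family structure, and the long-range sequence
correlations of real proteins. Passing recovery tests therefore shows
that the selector and classifier behave correctly under the assumed
statistical model (label driven by a sparse descriptor subset), not
that real metabolic networks satisfy that model.

## Problem sizes and reported quantities

The acceptance script (`scripts/acceptance.py`) and test suite run at
desk scale, chosen so the whole workflow completes in minutes on one
CPU:

- structural contracts at full printed scale: 79/132/290 dimensions and
  the 14,592 → 729,600 negative-sampling count at ratio 50;
- feature recovery on ten worlds of 100 compounds × 50 enzymes with
  1,000 positives + 1,000 negatives each (a balanced case-control
  design, the standard choice for feature discovery — the imbalance
  stress is exercised separately);
- the imbalanced evaluation run at 500 positives, ratio 10;
- the accuracy/MCC dissociation on pure-noise 50:1 data (20 positives ×
  51, ten seeds): accuracy stays at the majority-class level while MCC
  stays near zero, which is why MCC is the selection criterion.

Full-scale metabolic matrices (hundreds of thousands of triads with
externally computed descriptors) are ingestible through the same file
interfaces but are outside the scope of the shipped experiments.

## Known limitations

- Geometry descriptors depend on a single unrefined conformer; values
  are internally consistent but not comparable to force-field-optimized
  descriptor sets.
- The secondary-structure predictor is a propensity heuristic.
- mRMR uses discretized MI only; continuous estimators are out of
  scope.
- Some nonnetworking samples may be true interactions by chance; no
  label-noise correction is applied (none is specified for this
  design).
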