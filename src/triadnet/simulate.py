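"""Synthetic worlds: compounds, enzymes and triads with planted signal.

The generator emits real, encodable structures — SMILES built from a
small valence-safe grammar (acyclic chains, carbocycles, aromatic and
hetero rings, fused systems, stereo double bonds, phosphate tails) and
enzyme sequences drawn from per-enzyme Dirichlet residue distributions.
Positive triads are selected by rejection sampling against a logistic
score on z-scored planted descriptor columns, so the class label
depends on a sparse, known feature subset while every feature value is
still the true descriptor of an encodable structure. The planted
ground truth is returned for recovery experiments.

A candidate triple is accepted as positive when its linear planted
score (plus Gaussian noise) reaches the score's upper
``positive_fraction`` quantile over the whole triple space, so the
positive class occupies a large, diverse region while every planted
feature's class-conditional mean shifts in proportion to its weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from .compounds import Compound, default_registry, encode_compounds
from .dataset import (NETWORKING, FeatureMatrix, SamplerConfig, Triad,
                      assemble_matrix, sample_negatives)
from .enzymes import AMINO_ACIDS, EnzymeRecord, default_layout, encode_enzymes

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "DEFAULT_PLANTED",
    "generate_world",
    "plant_triads",
    "build_world_matrix",
    "write_world",
]

# Default planted signal: ten features spread over roles and
# categories, picked for privacy — mutual in-pool correlations below
# ~0.2 and no strong proxy (max |r| with any other same-role column
# <= ~0.5 in a reference world) — so the planted subset is genuinely
# sparse and recoverable rather than diffused over correlated columns.
DEFAULT_PLANTED: dict[str, float] = {
    "Substrate_AmideBondCount": 2.0,
    "Substrate_SComposition": 2.0,
    "Substrate_TripleBondCount": 2.0,
    "Product_StereoDoubleBondCount": 2.0,
    "Product_HeteroAliphaticRingCount": -2.0,
    "Product_TripleBondCount": 2.0,
    "AminoAcidsComposition_Arg": 2.0,
    "AminoAcidsComposition_Trp": -2.0,
    "AminoAcidsComposition_Ile": 2.0,
    "AminoAcidsComposition_Asp": -2.0,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    n_compounds: int = 100
    n_enzymes: int = 50
    seed: int = 0
    n_positive: int = 2000
    ratio: int = 10  # negatives per positive in the assembled matrix
    planted_features: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED))
    noise_sd: float = 0.5  # Gaussian noise on the acceptance score
    positive_fraction: float = 0.2  # score quantile defining the positive region

    def __post_init__(self) -> None:
        if self.n_positive < 10:
            raise ValueError("n_positive must be >= 10")
        for v in self.planted_features.values():
            if not np.isfinite(v):
                raise ValueError("planted effect sizes must be finite")
        if not 0 < self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in (0, 1]")


@dataclass
class SyntheticWorld:
    compounds: list[Compound]
    enzymes: list[EnzymeRecord]
    config: SyntheticWorldConfig
    _compound_table: pd.DataFrame | None = None
    _enzyme_table: pd.DataFrame | None = None

    @property
    def compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def enzyme_ids(self) -> list[str]:
        return [e.id for e in self.enzymes]

    def tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Descriptor tables, encoded once and cached."""
        if self._compound_table is None:
            self._compound_table = encode_compounds(
                self.compounds, default_registry(), seed=self.config.seed)
            self._enzyme_table = encode_enzymes(self.enzymes, default_layout())
        return self._compound_table, self._enzyme_table


# --------------------------------------------------------------------------
# structure generation

_SCAFFOLDS = [
    None,                      # acyclic
    "c1ccccc1",                # benzene
    "C1CCCCC1",                # cyclohexane
    "C1CCCC1",                 # cyclopentane
    "c1ccncc1",                # pyridine
    "c1ccoc1",                 # furan
    "c1ccsc1",                 # thiophene
    "c1ccc2ccccc2c1",          # naphthalene (fused aromatic)
    "C1CCC2CCCCC2C1",          # decalin (fused aliphatic)
    "C1CCOC1",                 # THF (hetero aliphatic)
]
_CHAIN_UNITS = ["C", "C", "C", "CC", "O", "N", "S", "C(C)", "C(=O)", "/C=C/"]
_TERMINALS = ["", "", "O", "N", "C(=O)O", "OP(=O)(O)O", "C#N"]


def _random_smiles(rng: np.random.Generator, idx: int) -> str:
    # cycle scaffolds for the first draws so every branch is covered,
    # then draw freely
    if idx < len(_SCAFFOLDS):
        scaffold = _SCAFFOLDS[idx]
    else:
        scaffold = _SCAFFOLDS[rng.integers(0, len(_SCAFFOLDS))]
    n_units = int(rng.integers(1, 7))
    units = [_CHAIN_UNITS[rng.integers(0, len(_CHAIN_UNITS))] for _ in range(n_units)]
    terminal = _TERMINALS[rng.integers(0, len(_TERMINALS))]
    # chains must start on an atom that tolerates the scaffold bond
    smiles = (scaffold or "") + "".join(units) + terminal
    if smiles.startswith("/"):
        smiles = "C" + smiles
    return smiles


def generate_world(cfg: SyntheticWorldConfig) -> SyntheticWorld:
    """Deterministically generate compounds and enzymes for a seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    compounds: list[Compound] = []
    i = 0
    attempts = 0
    while len(compounds) < cfg.n_compounds:
        smiles = _random_smiles(rng, i)
        attempts += 1
        if attempts > 50 * cfg.n_compounds:
            raise RuntimeError("structure grammar failed to produce enough molecules")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar is valence-safe; guard regardless
            continue
        compounds.append(Compound(id=f"C{len(compounds):04d}", mol=mol))
        i += 1

    letters = np.array(list(AMINO_ACIDS))
    enzymes: list[EnzymeRecord] = []
    for j in range(cfg.n_enzymes):
        probs = rng.dirichlet(np.full(20, 2.0))
        length = int(rng.integers(50, 401))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        enzymes.append(EnzymeRecord(id=f"E{j:03d}", sequence=seq))
    return SyntheticWorld(compounds, enzymes, cfg)


# --------------------------------------------------------------------------
# signal planting

def _role_scores(world: SyntheticWorld, planted: Mapping[str, float]
                 ) -> dict[str, np.ndarray]:
    """Per-role linear scores over the entity pools: score_i = sum of
    effect * z-scored planted column value for pool member i."""
    compound_table, enzyme_table = world.tables()
    scores = {
        "substrate": np.zeros(len(compound_table)),
        "enzyme": np.zeros(len(enzyme_table)),
        "product": np.zeros(len(compound_table)),
    }
    for name, effect in planted.items():
        if name.startswith("Substrate_"):
            col, role, table = name[len("Substrate_"):], "substrate", compound_table
        elif name.startswith("Product_"):
            col, role, table = name[len("Product_"):], "product", compound_table
        else:
            col, role, table = name, "enzyme", enzyme_table
        if col not in table.columns:
            raise KeyError(f"planted feature {name!r} not in the 290-feature space")
        v = table[col].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"planted feature {name!r} is constant in this world")
        scores[role] += effect * (v - v.mean()) / sd
    return scores


def _score_threshold(scores: dict[str, np.ndarray], fraction: float,
                     rng: np.random.Generator) -> float:
    """Upper ``fraction`` quantile of the triple-score distribution,
    exact when the triple space is small enough to enumerate."""
    s_sub, s_enz, s_prod = scores["substrate"], scores["enzyme"], scores["product"]
    space = len(s_sub) * len(s_enz) * len(s_prod)
    if space <= 2_000_000:
        total = (s_sub[:, None, None] + s_enz[None, :, None]
                 + s_prod[None, None, :]).ravel()
    else:
        n = 1_000_000
        total = (s_sub[rng.integers(0, len(s_sub), n)]
                 + s_enz[rng.integers(0, len(s_enz), n)]
                 + s_prod[rng.integers(0, len(s_prod), n)])
    return float(np.quantile(total, 1.0 - fraction))


def plant_triads(world: SyntheticWorld,
                 cfg: SyntheticWorldConfig | None = None) -> tuple[list[Triad], dict[str, float]]:
    """Draw positive triads whose label depends on the planted features.

    Candidate (substrate, enzyme, product) triples are drawn uniformly
    and accepted when their linear planted score plus Gaussian noise
    reaches the upper ``positive_fraction`` score quantile; with all
    effects zero the positives are uniform over the triple space.
    Returns the positives and the planted name -> effect map.
    """
    cfg = cfg or world.config
    planted = dict(cfg.planted_features)
    scores = _role_scores(world, planted)
    rng = np.random.default_rng([cfg.seed, 1])
    tau = _score_threshold(scores, cfg.positive_fraction, rng)

    nc, ne = len(world.compounds), len(world.enzymes)
    region = max(cfg.positive_fraction * nc * nc * ne, 1)
    if region < 2 * cfg.n_positive:
        raise RuntimeError(
            f"positive region holds about {region:.0f} triples, too few for "
            f"{cfg.n_positive} distinct positives; use a larger world")

    accepted: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()
    max_draws = 2000 * max(cfg.n_positive, 1000)
    drawn = 0
    while len(accepted) < cfg.n_positive:
        if drawn >= max_draws:
            raise RuntimeError(
                "rejection sampling exhausted its draw budget; use a larger world "
                "or a smaller n_positive")
        batch = max(4 * (cfg.n_positive - len(accepted)), 1000)
        s = rng.integers(0, nc, size=batch)
        e = rng.integers(0, ne, size=batch)
        p = rng.integers(0, nc, size=batch)
        drawn += batch
        score = scores["substrate"][s] + scores["enzyme"][e] + scores["product"][p]
        if cfg.noise_sd > 0:
            score = score + rng.normal(0.0, cfg.noise_sd, size=batch)
        accept = score >= tau
        for si, ei, pi in zip(s[accept], e[accept], p[accept]):
            key = (int(si), int(ei), int(pi))
            if key in seen:
                continue
            seen.add(key)
            accepted.append(key)
            if len(accepted) == cfg.n_positive:
                break

    cids, eids = world.compound_ids, world.enzyme_ids
    positives = [Triad(cids[s], eids[e], cids[p], NETWORKING) for s, e, p in accepted]
    return positives, planted


def build_world_matrix(cfg: SyntheticWorldConfig) -> tuple[FeatureMatrix, dict[str, float]]:
    """World -> planted positives -> sampled negatives -> 290-column
    matrix, fully determined by ``cfg.seed``."""
    world = generate_world(cfg)
    positives, planted = plant_triads(world, cfg)
    negatives = sample_negatives(positives, world.compound_ids, world.enzyme_ids,
                                 SamplerConfig(ratio=cfg.ratio, seed=cfg.seed + 2))
    compound_table, enzyme_table = world.tables()
    m = assemble_matrix(positives + negatives, compound_table, enzyme_table)
    return m, planted


# --------------------------------------------------------------------------
# export in the pipeline's own input formats

def write_world(world: SyntheticWorld, positives: list[Triad], out_dir: str | Path) -> dict[str, Path]:
    """Write compounds.smi, enzymes.fasta and triads.tsv so a synthetic
    world is indistinguishable from user data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    smi = out / "compounds.smi"
    with open(smi, "w") as fh:
        for c in world.compounds:
            fh.write(f"{Chem.MolToSmiles(c.mol)} {c.id}\n")
    fasta = out / "enzymes.fasta"
    with open(fasta, "w") as fh:
        for e in world.enzymes:
            fh.write(f">{e.id}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i:i + 60] + "\n")
    triads = out / "triads.tsv"
    pd.DataFrame([t[:3] for t in positives],
                 columns=["substrate_id", "enzyme_id", "product_id"]).to_csv(
        triads, sep="\t", index=False)
    return {"compounds": smi, "enzymes": fasta, "triads": triads}
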