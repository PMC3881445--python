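"""Small-molecule ingest and the 79-descriptor compound encoder.

Substrates and products are represented by a fixed-length vector of 79
molecular descriptors spanning three categories: elemental analysis
(atom-count fractions of the explicit-hydrogen graph), geometry
(conformer extents, shape indices and ring topology) and chemistry
(logP, polarizability, surface areas, charges, topological indices).
Geometry descriptors are computed on a deterministic, seeded
distance-geometry conformer aligned to its principal axes so that
axis-extent descriptors such as ``MinZ`` are orientation-stable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, Descriptors3D, rdFreeSASA, rdMolDescriptors

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "CompoundFeatureVector",
    "Descriptor",
    "DescriptorRegistry",
    "EmbeddingError",
    "default_registry",
    "parse_structures",
    "elemental_composition",
    "ring_descriptors",
    "embed_conformer",
    "encode_compound",
    "encode_compounds",
    "write_compound_table",
    "read_compound_table",
]


class EmbeddingError(RuntimeError):
    """Raised when no 3D conformer can be generated for a compound."""


@dataclass
class Compound:
    """A small molecule with an identifier and (optionally) a conformer.

    ``mol`` is the heavy-atom RDKit graph as parsed; ``molh`` and
    ``coords`` are populated by :func:`embed_conformer` and hold the
    explicit-hydrogen molecule and its principal-axis-aligned 3D
    coordinates (Å, centroid at the origin).
    """

    id: str
    mol: Chem.Mol
    molh: Chem.Mol | None = None
    coords: np.ndarray | None = None

    @property
    def has_conformer(self) -> bool:
        return self.coords is not None


@dataclass
class CompoundFeatureVector:
    compound_id: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("descriptor values and names differ in length")


@dataclass(frozen=True)
class Descriptor:
    """One named descriptor: a category tag and a computing function."""

    name: str
    category: str  # "elemental analysis" | "geometry" | "chemistry"
    compute: Callable[[Compound], float]
    fallback: float = 0.0  # imputed when computation fails


class DescriptorRegistry:
    """Ordered collection of compound descriptors.

    The shipped default has exactly 79 entries; a custom registry (e.g.
    one mirroring an external descriptor package) can be passed anywhere
    a registry is accepted.
    """

    def __init__(self, entries: Iterable[Descriptor]):
        self.entries: tuple[Descriptor, ...] = tuple(entries)
        names = [d.name for d in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor names in registry")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.entries)

    @property
    def categories(self) -> dict[str, str]:
        return {d.name: d.category for d in self.entries}


# --------------------------------------------------------------------------
# parsing

def parse_structures(path: str | Path, format: str = "smiles") -> list[Compound]:
    """Read compounds from a SMILES file (``SMILES [id]`` per line) or SDF.

    Records keep file order; an unparseable record raises ``ValueError``
    naming its index, and an empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    compounds: list[Compound] = []
    if format == "smiles":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    raise ValueError(f"unparseable SMILES at line {lineno}: {parts[0]!r}")
                cid = parts[1] if len(parts) > 1 else f"M{lineno:05d}"
                compounds.append(Compound(id=cid, mol=mol))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unparseable SDF record at index {i}")
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"M{i:05d}"
            compounds.append(Compound(id=cid, mol=mol))
    else:
        raise ValueError(f"unsupported structure format: {format!r}")
    if not compounds:
        raise ValueError(f"no structures found in {path}")
    logger.info("parsed %d structures from %s", len(compounds), path)
    return compounds


# --------------------------------------------------------------------------
# elemental analysis

def _atom_counts(c: Compound) -> dict[str, int]:
    """Element -> atom count with hydrogens made explicit."""
    counts: dict[str, int] = {}
    n_h = 0
    for atom in c.mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        n_h += atom.GetTotalNumHs()
    counts["H"] = counts.get("H", 0) + n_h
    if counts.get("H") == 0:
        counts.pop("H", None)
    return counts


def elemental_composition(c: Compound, element: str) -> float:
    """Fraction of atoms (explicit-H graph) that are ``element``."""
    counts = _atom_counts(c)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"empty molecule: {c.id}")
    return counts.get(element, 0) / total


# --------------------------------------------------------------------------
# ring topology (SSSR basis)

def _ring_systems(bond_rings: Sequence[tuple[int, ...]]) -> list[list[int]]:
    """Group SSSR rings into fused systems (rings sharing >=1 bond)."""
    n = len(bond_rings)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(r) for r in bond_rings]
    for i in range(n):
        for j in range(i + 1, n):
            if sets[i] & sets[j]:
                parent[find(i)] = find(j)
    systems: dict[int, list[int]] = {}
    for i in range(n):
        systems.setdefault(find(i), []).append(i)
    return list(systems.values())


def ring_descriptors(c: Compound) -> dict[str, int]:
    """Ring-topology counts on the SSSR ring basis.

    Fused = shares at least one bond with another ring; carbo = every
    ring atom is carbon; hetero = at least one non-carbon ring atom.
    Acyclic molecules yield 0 everywhere (0 is the sentinel for
    ``SmallestRingSize``).
    """
    mol = c.mol
    ri = mol.GetRingInfo()
    atom_rings = ri.AtomRings()
    bond_rings = ri.BondRings()
    n_rings = len(atom_rings)
    out = {k: 0 for k in (
        "RingCount", "SmallestRingSize", "LargestRingSize",
        "SmallestRingSystemSize", "LargestRingSystemSize", "RingSystemCount",
        "FusedRingCount", "FusedAliphaticRingCount", "FusedAromaticRingCount",
        "CarboRingCount", "CarboAliphaticRingCount", "CarboAromaticRingCount",
        "HeteroRingCount", "HeteroAliphaticRingCount", "HeteroAromaticRingCount",
        "AliphaticRingCount", "AromaticRingCount",
    )}
    if n_rings == 0:
        return out

    aromatic = []
    carbo = []
    for ar, br in zip(atom_rings, bond_rings):
        aromatic.append(all(mol.GetBondWithIdx(b).GetIsAromatic() for b in br))
        carbo.append(all(mol.GetAtomWithIdx(a).GetSymbol() == "C" for a in ar))

    bond_sets = [set(r) for r in bond_rings]
    fused = [any(i != j and bond_sets[i] & bond_sets[j] for j in range(n_rings))
             for i in range(n_rings)]
    systems = _ring_systems(bond_rings)
    system_sizes = []
    for sys_rings in systems:
        atoms: set[int] = set()
        for r in sys_rings:
            atoms.update(atom_rings[r])
        system_sizes.append(len(atoms))

    out["RingCount"] = n_rings
    out["SmallestRingSize"] = min(len(r) for r in atom_rings)
    out["LargestRingSize"] = max(len(r) for r in atom_rings)
    out["SmallestRingSystemSize"] = min(system_sizes)
    out["LargestRingSystemSize"] = max(system_sizes)
    out["RingSystemCount"] = len(systems)
    for i in range(n_rings):
        aro, car, fu = aromatic[i], carbo[i], fused[i]
        out["AromaticRingCount"] += aro
        out["AliphaticRingCount"] += not aro
        out["CarboRingCount"] += car
        out["CarboAromaticRingCount"] += car and aro
        out["CarboAliphaticRingCount"] += car and not aro
        out["HeteroRingCount"] += not car
        out["HeteroAromaticRingCount"] += (not car) and aro
        out["HeteroAliphaticRingCount"] += (not car) and not aro
        out["FusedRingCount"] += fu
        out["FusedAliphaticRingCount"] += fu and not aro
        out["FusedAromaticRingCount"] += fu and aro
    return {k: int(v) for k, v in out.items()}


def rotatable_bond_count(c: Compound) -> int:
    """Non-ring single bonds between two non-terminal heavy atoms,
    excluding amide C-N bonds."""
    mol = c.mol
    count = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:
            continue
        if _is_amide_bond(a, b) or _is_amide_bond(b, a):
            continue
        count += 1
    return count


def _is_amide_bond(carbon: Chem.Atom, nitrogen: Chem.Atom) -> bool:
    if carbon.GetSymbol() != "C" or nitrogen.GetSymbol() != "N":
        return False
    for nb in carbon.GetBonds():
        other = nb.GetOtherAtom(carbon)
        if other.GetSymbol() == "O" and nb.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def stereo_double_bond_count(c: Compound) -> int:
    return sum(1 for b in c.mol.GetBonds()
               if b.GetBondType() == Chem.BondType.DOUBLE
               and b.GetStereo() != Chem.BondStereo.STEREONONE)


# --------------------------------------------------------------------------
# conformer generation

def embed_conformer(c: Compound, seed: int) -> Compound:
    """Attach a deterministic 3D conformer aligned to principal axes.

    Uses seeded distance-geometry embedding (no force-field refinement);
    the coordinate frame is centred on the centroid and rotated so the
    variance ordering is x >= y >= z, with axis signs fixed by the sign
    of the third central moment. Raises :class:`EmbeddingError` when
    embedding fails.
    """
    molh = Chem.AddHs(c.mol)
    n = molh.GetNumAtoms()
    if n == 0:
        raise EmbeddingError(f"empty molecule: {c.id}")
    if n == 1:
        coords = np.zeros((1, 3))
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
        molh.RemoveAllConformers()
        molh.AddConformer(conf, assignId=True)
        c.molh, c.coords = molh, coords
        return c
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    cid = AllChem.EmbedMolecule(molh, params)
    if cid < 0:
        params.useRandomCoords = True
        cid = AllChem.EmbedMolecule(molh, params)
    if cid < 0:
        raise EmbeddingError(f"3D embedding failed for compound {c.id}")
    coords = np.array(molh.GetConformer(cid).GetPositions(), dtype=float)
    coords = _align_principal_axes(coords)
    conf = molh.GetConformer(cid)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    c.molh, c.coords = molh, coords
    return c


def _align_principal_axes(coords: np.ndarray) -> np.ndarray:
    coords = coords - coords.mean(axis=0)
    cov = coords.T @ coords / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    aligned = coords @ evecs[:, order]
    for j in range(3):
        skew = float(np.sum(aligned[:, j] ** 3))
        if abs(skew) > 1e-9:
            if skew < 0:
                aligned[:, j] *= -1
        else:
            col = aligned[:, j]
            imax = int(np.argmax(np.abs(col)))
            if col[imax] < 0:
                aligned[:, j] *= -1
    return aligned


def _need_conformer(c: Compound) -> np.ndarray:
    if c.coords is None:
        raise EmbeddingError(f"compound {c.id} has no conformer")
    return c.coords


# --------------------------------------------------------------------------
# chemistry helpers

# Atomic polarizabilities (A^3), CRC values; fallback for exotic elements.
_ATOM_POLARIZABILITY = {
    "H": 0.667, "B": 3.03, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "Si": 5.38, "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
    "Se": 3.77, "As": 4.31,
}


def polarizability(c: Compound) -> float:
    """Additive molecular polarizability from atomic increments (A^3)."""
    counts = _atom_counts(c)
    return sum(_ATOM_POLARIZABILITY.get(el, 2.0) * n for el, n in counts.items())


def _gasteiger_charges(c: Compound) -> np.ndarray:
    molh = c.molh if c.molh is not None else Chem.AddHs(c.mol)
    AllChem.ComputeGasteigerCharges(molh)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise ValueError(f"Gasteiger charges undefined for {c.id}")
    return q


def _atom_sasa(c: Compound) -> np.ndarray:
    molh = c.molh
    if molh is None or molh.GetNumConformers() == 0:
        raise EmbeddingError(f"compound {c.id} has no conformer for SASA")
    radii = rdFreeSASA.classifyAtoms(molh)
    rdFreeSASA.CalcSASA(molh, radii)
    return np.array([float(a.GetProp("SASA")) for a in molh.GetAtoms()])


def water_accessible_surface_area(c: Compound, charge_sign: int = 0) -> float:
    """Solvent-accessible surface area (A^2); with ``charge_sign`` -1/+1,
    only the area of atoms with negative/positive partial charge."""
    sasa = _atom_sasa(c)
    if charge_sign == 0:
        return float(sasa.sum())
    q = _gasteiger_charges(c)
    mask = q < 0 if charge_sign < 0 else q > 0
    return float(sasa[mask].sum())


# --------------------------------------------------------------------------
# default 79-descriptor registry

def _ring(name: str) -> Callable[[Compound], float]:
    return lambda c: float(ring_descriptors(c)[name])


def _coord_stat(axis: int, fn: str) -> Callable[[Compound], float]:
    def compute(c: Compound) -> float:
        xyz = _need_conformer(c)
        col = xyz[:, axis]
        if fn == "min":
            return float(col.min())
        if fn == "max":
            return float(col.max())
        return float(col.max() - col.min())
    return compute


def _d3(name: str) -> Callable[[Compound], float]:
    fn = getattr(Descriptors3D, name)

    def compute(c: Compound) -> float:
        _need_conformer(c)
        return float(fn(c.molh))
    return compute


def _max_interatomic_distance(c: Compound) -> float:
    xyz = _need_conformer(c)
    if len(xyz) == 1:
        return 0.0
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _on_mol(fn: Callable[[Chem.Mol], float]) -> Callable[[Compound], float]:
    return lambda c: float(fn(c.mol))


def default_registry() -> DescriptorRegistry:
    """The shipped 79-descriptor registry (14 elemental + 36 geometry +
    29 chemistry)."""
    E, G, C = "elemental analysis", "geometry", "chemistry"
    halogens = {"F", "Cl", "Br", "I"}

    def _frac(el: str) -> Callable[[Compound], float]:
        return lambda c: elemental_composition(c, el)

    def _halogen_frac(c: Compound) -> float:
        counts = _atom_counts(c)
        total = sum(counts.values())
        return sum(v for k, v in counts.items() if k in halogens) / total

    def _hetero_frac(c: Compound) -> float:
        counts = _atom_counts(c)
        total = sum(counts.values())
        return sum(v for k, v in counts.items() if k not in {"C", "H"}) / total

    def _count(el: str) -> Callable[[Compound], float]:
        return lambda c: float(_atom_counts(c).get(el, 0))

    entries: list[Descriptor] = [
        # -- elemental analysis (14)
        Descriptor("CComposition", E, _frac("C")),
        Descriptor("HComposition", E, _frac("H")),
        Descriptor("OComposition", E, _frac("O")),
        Descriptor("NComposition", E, _frac("N")),
        Descriptor("PComposition", E, _frac("P")),
        Descriptor("SComposition", E, _frac("S")),
        Descriptor("HalogenComposition", E, _halogen_frac),
        Descriptor("HeteroAtomComposition", E, _hetero_frac),
        Descriptor("AtomCount", E, lambda c: float(sum(_atom_counts(c).values()))),
        Descriptor("HeavyAtomCount", E, lambda c: float(c.mol.GetNumAtoms())),
        Descriptor("CCount", E, _count("C")),
        Descriptor("HCount", E, _count("H")),
        Descriptor("OCount", E, _count("O")),
        Descriptor("NCount", E, _count("N")),
        # -- geometry: conformer extents and shape (19)
        Descriptor("MinX", G, _coord_stat(0, "min")),
        Descriptor("MaxX", G, _coord_stat(0, "max")),
        Descriptor("SpanX", G, _coord_stat(0, "span")),
        Descriptor("MinY", G, _coord_stat(1, "min")),
        Descriptor("MaxY", G, _coord_stat(1, "max")),
        Descriptor("SpanY", G, _coord_stat(1, "span")),
        Descriptor("MinZ", G, _coord_stat(2, "min")),
        Descriptor("MaxZ", G, _coord_stat(2, "max")),
        Descriptor("SpanZ", G, _coord_stat(2, "span")),
        Descriptor("RadiusOfGyration", G, _d3("RadiusOfGyration")),
        Descriptor("Asphericity", G, _d3("Asphericity")),
        Descriptor("Eccentricity", G, _d3("Eccentricity")),
        Descriptor("InertialShapeFactor", G, _d3("InertialShapeFactor")),
        Descriptor("SpherocityIndex", G, _d3("SpherocityIndex")),
        Descriptor("NormalizedPrincipalMomentRatio1", G, _d3("NPR1")),
        Descriptor("NormalizedPrincipalMomentRatio2", G, _d3("NPR2")),
        Descriptor("PrincipalMomentOfInertiaZ", G, _d3("PMI3")),
        Descriptor("PlaneOfBestFit", G, _d3("PBF")),
        Descriptor("MaxInteratomicDistance", G, _max_interatomic_distance),
        # -- geometry: ring topology and bond counts (17)
        Descriptor("RingCount", G, _ring("RingCount")),
        Descriptor("SmallestRingSize", G, _ring("SmallestRingSize")),
        Descriptor("LargestRingSize", G, _ring("LargestRingSize")),
        Descriptor("SmallestRingSystemSize", G, _ring("SmallestRingSystemSize")),
        Descriptor("LargestRingSystemSize", G, _ring("LargestRingSystemSize")),
        Descriptor("RingSystemCount", G, _ring("RingSystemCount")),
        Descriptor("FusedRingCount", G, _ring("FusedRingCount")),
        Descriptor("FusedAliphaticRingCount", G, _ring("FusedAliphaticRingCount")),
        Descriptor("FusedAromaticRingCount", G, _ring("FusedAromaticRingCount")),
        Descriptor("CarboRingCount", G, _ring("CarboRingCount")),
        Descriptor("CarboAliphaticRingCount", G, _ring("CarboAliphaticRingCount")),
        Descriptor("CarboAromaticRingCount", G, _ring("CarboAromaticRingCount")),
        Descriptor("HeteroRingCount", G, _ring("HeteroRingCount")),
        Descriptor("HeteroAliphaticRingCount", G, _ring("HeteroAliphaticRingCount")),
        Descriptor("HeteroAromaticRingCount", G, _ring("HeteroAromaticRingCount")),
        Descriptor("RotatableBondCount", G, lambda c: float(rotatable_bond_count(c))),
        Descriptor("StereoDoubleBondCount", G, lambda c: float(stereo_double_bond_count(c))),
        # -- chemistry (29)
        Descriptor("LogP", C, _on_mol(Descriptors.MolLogP)),
        Descriptor("MolarRefractivity", C, _on_mol(Descriptors.MolMR)),
        Descriptor("Polarizability", C, polarizability),
        Descriptor("VanDerWaalsSurfaceArea", C, _on_mol(rdMolDescriptors.CalcLabuteASA)),
        Descriptor("WaterAccessibleSurfaceArea", C, water_accessible_surface_area),
        Descriptor("WaterAccessibleSurfaceArea(Negative)", C,
                   lambda c: water_accessible_surface_area(c, -1)),
        Descriptor("WaterAccessibleSurfaceArea(Positive)", C,
                   lambda c: water_accessible_surface_area(c, +1)),
        Descriptor("TopologicalPolarSurfaceArea", C, _on_mol(Descriptors.TPSA)),
        Descriptor("MolecularWeight", C, _on_mol(Descriptors.MolWt)),
        Descriptor("HBondDonorCount", C, _on_mol(rdMolDescriptors.CalcNumHBD)),
        Descriptor("HBondAcceptorCount", C, _on_mol(rdMolDescriptors.CalcNumHBA)),
        Descriptor("FractionCSP3", C, _on_mol(rdMolDescriptors.CalcFractionCSP3)),
        Descriptor("FormalCharge", C, lambda c: float(Chem.GetFormalCharge(c.mol))),
        Descriptor("MaxPartialCharge", C, lambda c: float(_gasteiger_charges(c).max())),
        Descriptor("MinPartialCharge", C, lambda c: float(_gasteiger_charges(c).min())),
        Descriptor("MaxAbsPartialCharge", C,
                   lambda c: float(np.abs(_gasteiger_charges(c)).max())),
        Descriptor("BalabanJ", C, _on_mol(Descriptors.BalabanJ)),
        Descriptor("BertzComplexity", C, _on_mol(Descriptors.BertzCT)),
        Descriptor("Chi0v", C, _on_mol(Descriptors.Chi0v)),
        Descriptor("Chi1v", C, _on_mol(Descriptors.Chi1v)),
        Descriptor("Kappa1", C, _on_mol(Descriptors.Kappa1)),
        Descriptor("Kappa2", C, _on_mol(Descriptors.Kappa2)),
        Descriptor("Kappa3", C, _on_mol(Descriptors.Kappa3)),
        Descriptor("HallKierAlpha", C, _on_mol(Descriptors.HallKierAlpha)),
        Descriptor("AmideBondCount", C, _on_mol(rdMolDescriptors.CalcNumAmideBonds)),
        Descriptor("AromaticAtomFraction", C,
                   lambda c: (sum(a.GetIsAromatic() for a in c.mol.GetAtoms())
                              / max(c.mol.GetNumAtoms(), 1))),
        Descriptor("Sp3CarbonCount", C,
                   lambda c: float(sum(1 for a in c.mol.GetAtoms()
                                       if a.GetSymbol() == "C"
                                       and a.GetHybridization() == Chem.HybridizationType.SP3))),
        Descriptor("DoubleBondCount", C,
                   lambda c: float(sum(1 for b in c.mol.GetBonds()
                                       if b.GetBondType() == Chem.BondType.DOUBLE))),
        Descriptor("TripleBondCount", C,
                   lambda c: float(sum(1 for b in c.mol.GetBonds()
                                       if b.GetBondType() == Chem.BondType.TRIPLE))),
    ]
    registry = DescriptorRegistry(entries)
    assert len(registry) == 79
    return registry


# --------------------------------------------------------------------------
# encoding

def encode_compound(c: Compound, registry: DescriptorRegistry) -> CompoundFeatureVector:
    """Compute the full descriptor vector for one compound.

    A descriptor that raises or returns a non-finite value is imputed
    with its registry fallback and logged; the output vector is always
    ``len(registry)`` long and finite.
    """
    values = np.empty(len(registry))
    for i, d in enumerate(registry):
        try:
            v = float(d.compute(c))
            if not math.isfinite(v):
                raise ValueError("non-finite value")
        except Exception as exc:  # imputation absorbs descriptor failures
            logger.warning("descriptor %s failed on %s (%s); imputing %.3g",
                           d.name, c.id, exc, d.fallback)
            v = d.fallback
        values[i] = v
    return CompoundFeatureVector(c.id, values, registry.names)


def encode_compounds(compounds: Sequence[Compound],
                     registry: DescriptorRegistry | None = None,
                     seed: int = 0) -> "pd.DataFrame":
    """Embed conformers and encode a collection; returns a DataFrame
    indexed by compound id with one descriptor per column.

    Embedding failures fall back to a flat 2D-layout geometry with a
    logged warning, keeping the fixed-length contract.
    """
    import pandas as pd

    registry = registry or default_registry()
    rows = []
    ids = []
    for c in compounds:
        if not c.has_conformer:
            try:
                embed_conformer(c, seed)
            except EmbeddingError as exc:
                logger.warning("%s; falling back to 2D geometry", exc)
                _fallback_2d(c)
        vec = encode_compound(c, registry)
        rows.append(vec.values)
        ids.append(c.id)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="compound_id"),
                        columns=list(registry.names))


def _fallback_2d(c: Compound) -> None:
    from rdkit.Chem import rdDepictor

    molh = Chem.AddHs(c.mol)
    rdDepictor.Compute2DCoords(molh)
    coords = np.array(molh.GetConformer(0).GetPositions(), dtype=float)
    coords = _align_principal_axes(coords) if len(coords) > 1 else np.zeros((1, 3))
    conf = molh.GetConformer(0)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    c.molh, c.coords = molh, coords


def write_compound_table(table: "pd.DataFrame", path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_compound_table(path: str | Path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col="compound_id")
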