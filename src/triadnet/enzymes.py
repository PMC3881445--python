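"""Enzyme sequence ingest and the 132-dimensional physicochemical encoder.

Each enzyme sequence is summarised by seven feature blocks: amino-acid
composition (20), CTD (composition/transition/distribution) blocks over
three-class groupings for hydrophobicity, polarizability, normalized
van der Waals volume and polarity (21 each), a two-class
solvent-accessibility CTD block (13), and a CTD block over the
internally predicted three-state secondary structure with distribution
at three quantiles (15) — 132 values in total under the default layout.

The CTD construction for a k-class grouping is: class fractions (k),
adjacent-pair class-change frequencies over the L-1 neighbouring pairs
(k(k-1)/2, unordered), and, per class, the sequence positions (as % of
L) at which the first, 25%, 50%, 75% and 100% of that class's residues
have occurred (0 for an absent class).
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

__all__ = [
    "AMINO_ACIDS",
    "EnzymeRecord",
    "PropertyGrouping",
    "EnzymeFeatureVector",
    "EnzymeLayout",
    "read_fasta",
    "amino_acid_composition",
    "ctd_block",
    "ctd_feature_names",
    "predict_secondary_structure",
    "encode_enzyme",
    "encode_enzymes",
    "default_layout",
    "load_groupings",
    "write_enzyme_table",
    "read_enzyme_table",
]


@dataclass
class EnzymeRecord:
    """An identified amino-acid sequence restricted to the 20 canonical
    letters (ambiguous residues are removed at ingest)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)} in {self.id}")


@dataclass(frozen=True)
class PropertyGrouping:
    """An ordered partition of the 20 amino acids into 2 or 3 classes."""

    name: str
    classes: tuple[tuple[str, frozenset[str]], ...]  # (class name, letters)

    def __post_init__(self) -> None:
        letters = [l for _, members in self.classes for l in members]
        if sorted(letters) != sorted(AMINO_ACIDS):
            raise ValueError(f"grouping {self.name!r} is not a partition of the 20 letters")

    @property
    def k(self) -> int:
        return len(self.classes)

    def class_of(self, residue: str) -> int:
        for i, (_, members) in enumerate(self.classes):
            if residue in members:
                return i
        raise KeyError(residue)


@dataclass
class EnzymeFeatureVector:
    enzyme_id: str
    values: np.ndarray
    names: tuple[str, ...]
    block_layout: tuple[tuple[str, int, int, str], ...]  # (block, offset, length, category)


@functools.lru_cache(maxsize=1)
def load_groupings() -> dict[str, PropertyGrouping]:
    """The shipped CTD property groupings (versioned package data)."""
    text = resources.files("triadnet.data").joinpath("ctd_groupings.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for prop, classes in raw.items():
        out[prop] = PropertyGrouping(
            prop, tuple((cname, frozenset(members)) for cname, members in classes.items()))
    return out


@functools.lru_cache(maxsize=1)
def _load_propensities() -> tuple[dict[str, float], dict[str, float]]:
    text = resources.files("triadnet.data").joinpath("ss_propensities.yaml").read_text()
    raw = yaml.safe_load(text)
    return raw["helix"], raw["strand"]


# --------------------------------------------------------------------------
# ingest

def read_fasta(path: str | Path) -> list[EnzymeRecord]:
    """Read enzymes from FASTA; ids from the header token.

    Residues outside the 20-letter alphabet (B, J, O, U, X, Z, ...) are
    removed with a logged count; empty sequences and duplicate ids are
    errors.
    """
    records: list[EnzymeRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        clean = "".join(ch for ch in seq if ch in AMINO_ACIDS)
        n_dropped += len(seq) - len(clean)
        if not clean:
            raise ValueError(f"empty sequence for FASTA entry {entry.id!r}")
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(EnzymeRecord(entry.id, clean))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_dropped:
        logger.info("removed %d ambiguous residues across %d records", n_dropped, len(records))
    return records


# --------------------------------------------------------------------------
# feature blocks

def amino_acid_composition(e: EnzymeRecord) -> np.ndarray:
    """The 20 residue fractions, alphabetical by one-letter code."""
    if not e.sequence:
        raise ValueError(f"empty sequence: {e.id}")
    L = len(e.sequence)
    return np.array([e.sequence.count(a) / L for a in AMINO_ACIDS])


def _quantile_occurrence(n: int, q: float) -> int:
    """1-based occurrence index of quantile q in a class with n members;
    q = 0 denotes the first occurrence."""
    if q <= 0:
        return 1
    return max(1, math.ceil(q * n))


DEFAULT_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)
_QUANTILE_TAGS = {0.0: "first", 0.25: "p25", 0.5: "p50", 0.75: "p75", 1.0: "p100"}


def ctd_block(symbols: str, g: PropertyGrouping,
              quantiles: Sequence[float] = DEFAULT_QUANTILES) -> np.ndarray:
    """Composition/transition/distribution vector of ``symbols`` under
    grouping ``g``: k + k(k-1)/2 + k*len(quantiles) values.

    Distribution entries are percentages of sequence length in [0, 100];
    a class absent from the sequence contributes zeros.
    """
    L = len(symbols)
    if L < 4:
        raise ValueError(f"sequence too short for CTD (length {L} < 4)")
    classes = np.array([g.class_of(ch) for ch in symbols])
    k = g.k

    comp = np.bincount(classes, minlength=k) / L

    trans = np.zeros(k * (k - 1) // 2)
    pair_index = {}
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            pair_index[(i, j)] = idx
            idx += 1
    for a, b in zip(classes[:-1], classes[1:]):
        if a != b:
            trans[pair_index[(min(a, b), max(a, b))]] += 1
    trans /= L - 1

    dist = np.zeros(k * len(quantiles))
    for ci in range(k):
        positions = np.flatnonzero(classes == ci) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        for qi, q in enumerate(quantiles):
            occ = _quantile_occurrence(n, q)
            dist[ci * len(quantiles) + qi] = positions[occ - 1] / L * 100.0
    return np.concatenate([comp, trans, dist])


def ctd_feature_names(prefix: str, g: PropertyGrouping,
                      quantiles: Sequence[float] = DEFAULT_QUANTILES) -> list[str]:
    names = [f"{prefix}_C_{cname}" for cname, _ in g.classes]
    for i in range(g.k):
        for j in range(i + 1, g.k):
            names.append(f"{prefix}_T_{g.classes[i][0]}.{g.classes[j][0]}")
    for cname, _ in g.classes:
        for q in quantiles:
            names.append(f"{prefix}_D_{cname}_{_QUANTILE_TAGS[q]}")
    return names


def predict_secondary_structure(e: EnzymeRecord, supplied: str | None = None,
                                window: int = 5) -> str:
    """Three-state (H/E/C) string of the sequence length.

    Uses a deterministic propensity sliding window (helix vs strand
    averages over a centred window; coil when neither exceeds 1.0). An
    externally supplied 3-state string bypasses prediction.
    """
    L = len(e.sequence)
    if supplied is not None:
        if len(supplied) != L:
            raise ValueError(
                f"supplied secondary structure length {len(supplied)} != sequence length {L}")
        bad = set(supplied) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary-structure symbols {sorted(bad)}")
        return supplied
    helix, strand = _load_propensities()
    half = window // 2
    out = []
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        seg = e.sequence[lo:hi]
        pa = sum(helix[ch] for ch in seg) / len(seg)
        pb = sum(strand[ch] for ch in seg) / len(seg)
        if pa > pb and pa >= 1.0:
            out.append("H")
        elif pb > pa and pb >= 1.0:
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


def _ss_grouping() -> "SymbolGrouping":
    return SymbolGrouping("secondary_structure",
                          (("helix", frozenset("H")),
                           ("strand", frozenset("E")),
                           ("coil", frozenset("C"))))


@dataclass(frozen=True)
class SymbolGrouping(PropertyGrouping):
    """A grouping over an arbitrary symbol alphabet (e.g. H/E/C states)."""

    def __post_init__(self) -> None:  # partition check over its own alphabet
        seen: set[str] = set()
        for _, members in self.classes:
            if seen & members:
                raise ValueError(f"overlapping classes in {self.name!r}")
            seen |= members


# --------------------------------------------------------------------------
# layout and encoding

@dataclass(frozen=True)
class Block:
    name: str
    category: str
    length: int
    names: tuple[str, ...]
    compute: Callable[[EnzymeRecord, str | None], np.ndarray]


class EnzymeLayout:
    """Ordered feature blocks; the default totals exactly 132."""

    def __init__(self, blocks: Sequence[Block]):
        self.blocks = tuple(blocks)

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for b in self.blocks for n in b.names)

    @property
    def categories(self) -> dict[str, str]:
        return {n: b.category for b in self.blocks for n in b.names}


def _aac_block() -> Block:
    names = tuple(f"AminoAcidsComposition_{_THREE_LETTER[a]}" for a in AMINO_ACIDS)
    return Block("amino acids composition", "amino acids composition", 20, names,
                 lambda e, ss: amino_acid_composition(e))


def _ctd_property_block(prop_key: str, prefix: str, category: str,
                        quantiles: Sequence[float] = DEFAULT_QUANTILES) -> Block:
    g = load_groupings()[prop_key]
    names = tuple(ctd_feature_names(prefix, g, quantiles))
    k = g.k
    length = k + k * (k - 1) // 2 + k * len(quantiles)
    return Block(prefix, category, length, names,
                 lambda e, ss, _g=g, _q=quantiles: ctd_block(e.sequence, _g, _q))


def _ss_block() -> Block:
    g = _ss_grouping()
    quantiles = (0.0, 0.5, 1.0)
    names = tuple(ctd_feature_names("SecondaryStructure", g, quantiles))
    return Block("SecondaryStructure", "secondary structure", 15, names,
                 lambda e, ss, _g=g: ctd_block(
                     ss if ss is not None else predict_secondary_structure(e), _g,
                     (0.0, 0.5, 1.0)))


def default_layout() -> EnzymeLayout:
    """AAC (20) + 4 three-class CTD properties (84) + two-class solvent
    accessibility (13) + secondary-structure CTD (15) = 132."""
    layout = EnzymeLayout([
        _aac_block(),
        _ctd_property_block("hydrophobicity", "Hydrophobicity", "hydrophobicity"),
        _ctd_property_block("polarizability", "Polarizability", "polarizability"),
        _ctd_property_block("normalized_vdw_volume", "NormalizedVanDerWaalsVolume",
                            "normalized Van Der Waals volume"),
        _ctd_property_block("polarity", "Polarity", "polarity"),
        _ctd_property_block("solvent_accessibility", "SolventAccessibility",
                            "solvent accessibility"),
        _ss_block(),
    ])
    assert layout.length == 132
    return layout


def encode_enzyme(e: EnzymeRecord, layout: EnzymeLayout | None = None,
                  secondary_structure: str | None = None) -> EnzymeFeatureVector:
    """Concatenate the layout's blocks for one enzyme (default: 132 values)."""
    layout = layout or default_layout()
    if len(e.sequence) < 4:
        raise ValueError(f"sequence of {e.id} shorter than 4 residues")
    parts = []
    block_layout = []
    offset = 0
    for b in layout.blocks:
        v = np.asarray(b.compute(e, secondary_structure), dtype=float)
        if len(v) != b.length:
            raise RuntimeError(f"block {b.name} produced {len(v)} values, expected {b.length}")
        parts.append(v)
        block_layout.append((b.name, offset, b.length, b.category))
        offset += b.length
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite feature values for {e.id}")
    return EnzymeFeatureVector(e.id, values, layout.names, tuple(block_layout))


def encode_enzymes(records: Sequence[EnzymeRecord],
                   layout: EnzymeLayout | None = None,
                   secondary_structures: dict[str, str] | None = None) -> "pd.DataFrame":
    """Encode a collection into a DataFrame indexed by enzyme id."""
    import pandas as pd

    layout = layout or default_layout()
    rows, ids = [], []
    for e in records:
        ss = secondary_structures.get(e.id) if secondary_structures else None
        rows.append(encode_enzyme(e, layout, ss).values)
        ids.append(e.id)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate enzyme ids")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="enzyme_id"),
                        columns=list(layout.names))


def write_enzyme_table(table: "pd.DataFrame", path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_enzyme_table(path: str | Path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col="enzyme_id")
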