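"""Triad assembly: positive ingest, negative sampling, feature matrix.

A sample is an ordered (substrate, enzyme, product) triple ("triad").
Known metabolic transformations form the positive ("networking") set;
negatives ("nonnetworking") are drawn uniformly without replacement
from the full substrate x enzyme x product combination space minus the
positives, at a configurable imbalance ratio (50:1 by default, matching
the study design this pipeline implements). Feature rows concatenate
the substrate descriptor block, the enzyme block and the product block
(79 + 132 + 79 = 290 columns under the default encoders).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NETWORKING = "networking"
NONNETWORKING = "nonnetworking"

__all__ = [
    "Triad",
    "SamplerConfig",
    "FeatureMatrix",
    "load_positive_triads",
    "sample_negatives",
    "assemble_matrix",
    "category_distribution",
    "save_matrix",
    "load_matrix",
]


class Triad(NamedTuple):
    substrate_id: str
    enzyme_id: str
    product_id: str
    label: str  # NETWORKING or NONNETWORKING


@dataclass(frozen=True)
class SamplerConfig:
    ratio: int = 50  # negatives per positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("sampler ratio must be >= 1")


@dataclass
class FeatureMatrix:
    """Triads-by-features matrix with role/category column tags.

    ``X`` is indexed by row position; ``y`` holds 1 for networking and
    0 for nonnetworking rows; ``column_meta`` is indexed by column name
    with ``role`` (substrate/enzyme/product) and ``category`` columns.
    """

    X: pd.DataFrame
    y: np.ndarray
    column_meta: pd.DataFrame
    triads: tuple[Triad, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if len(self.X) != len(self.y):
            raise ValueError("X and y row counts differ")
        if list(self.column_meta.index) != list(self.X.columns):
            raise ValueError("column_meta does not match X columns")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# --------------------------------------------------------------------------
# positive ingest

def load_positive_triads(path: str | Path,
                         compound_ids: Iterable[str],
                         enzyme_ids: Iterable[str]) -> list[Triad]:
    """Read the positive-triad TSV (columns substrate_id, enzyme_id,
    product_id; header required).

    Duplicates are dropped and rows with unresolvable ids are skipped,
    both with logged counts; zero resolvable triads is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["substrate_id", "enzyme_id", "product_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"positive-triad table missing columns {missing}")
    compounds, enzymes = set(compound_ids), set(enzyme_ids)
    seen: set[tuple[str, str, str]] = set()
    out: list[Triad] = []
    n_dup = n_bad = 0
    for row in df.itertuples(index=False):
        key = (row.substrate_id, row.enzyme_id, row.product_id)
        if key in seen:
            n_dup += 1
            continue
        if key[0] not in compounds or key[2] not in compounds or key[1] not in enzymes:
            n_bad += 1
            logger.warning("skipping triad with unresolvable ids: %s", key)
            continue
        seen.add(key)
        out.append(Triad(*key, NETWORKING))
    if n_dup:
        logger.info("dropped %d duplicate positive triads", n_dup)
    if not out:
        raise ValueError(f"no resolvable positive triads in {path}")
    return out


# --------------------------------------------------------------------------
# negative sampling

def sample_negatives(positives: Sequence[Triad],
                     compound_ids: Iterable[str],
                     enzyme_ids: Iterable[str],
                     cfg: SamplerConfig) -> list[Triad]:
    """Draw ``ratio x |positives|`` nonnetworking triads uniformly
    without replacement from the triple space minus the positives.

    The triple space is indexed over the sorted id lists so the draw is
    reproducible for a fixed seed regardless of input ordering.
    """
    compounds = sorted(set(compound_ids))
    enzymes = sorted(set(enzyme_ids))
    nc, ne = len(compounds), len(enzymes)
    space = nc * nc * ne
    c_index = {c: i for i, c in enumerate(compounds)}
    e_index = {e: i for i, e in enumerate(enzymes)}

    def encode(t: Triad) -> int:
        return (c_index[t.substrate_id] * nc + c_index[t.product_id]) * ne + e_index[t.enzyme_id]

    pos_codes = {encode(t) for t in positives}
    need = cfg.ratio * len(positives)
    if space - len(pos_codes) < need:
        raise ValueError(
            f"triple space too small: {space} triples minus {len(pos_codes)} positives "
            f"< {need} requested negatives")

    rng = np.random.default_rng(cfg.seed)
    chosen: list[int] = []
    chosen_set: set[int] = set()
    while len(chosen) < need:
        batch = rng.integers(0, space, size=max(2 * (need - len(chosen)), 1024))
        for code in batch.tolist():
            if code in pos_codes or code in chosen_set:
                continue
            chosen_set.add(code)
            chosen.append(code)
            if len(chosen) == need:
                break

    out = []
    for code in chosen:
        e_i = code % ne
        sp = code // ne
        p_i = sp % nc
        s_i = sp // nc
        out.append(Triad(compounds[s_i], enzymes[e_i], compounds[p_i], NONNETWORKING))
    return out


# --------------------------------------------------------------------------
# matrix assembly

def assemble_matrix(triads: Sequence[Triad],
                    compound_table: pd.DataFrame,
                    enzyme_table: pd.DataFrame,
                    compound_categories: Mapping[str, str] | None = None,
                    enzyme_categories: Mapping[str, str] | None = None) -> FeatureMatrix:
    """Build the row-per-triad matrix: [Substrate_* | enzyme | Product_*].

    Category tags default to the shipped registry/layout definitions;
    missing descriptor rows raise with the offending ids listed.
    """
    if not triads:
        raise ValueError("cannot assemble a matrix from zero triads")
    if compound_categories is None:
        from .compounds import default_registry
        compound_categories = default_registry().categories
    if enzyme_categories is None:
        from .enzymes import default_layout
        enzyme_categories = default_layout().categories

    sub_ids = [t.substrate_id for t in triads]
    enz_ids = [t.enzyme_id for t in triads]
    prod_ids = [t.product_id for t in triads]
    missing = (set(sub_ids) | set(prod_ids)) - set(compound_table.index)
    missing |= set(enz_ids) - set(enzyme_table.index)
    if missing:
        raise KeyError(f"missing descriptor rows for ids: {sorted(missing)[:10]}"
                       f"{' ...' if len(missing) > 10 else ''}")

    sub = compound_table.loc[sub_ids].to_numpy(dtype=float)
    enz = enzyme_table.loc[enz_ids].to_numpy(dtype=float)
    prod = compound_table.loc[prod_ids].to_numpy(dtype=float)

    columns = ([f"Substrate_{c}" for c in compound_table.columns]
               + list(enzyme_table.columns)
               + [f"Product_{c}" for c in compound_table.columns])
    X = pd.DataFrame(np.hstack([sub, enz, prod]), columns=columns)
    y = np.array([1 if t.label == NETWORKING else 0 for t in triads], dtype=np.int8)

    meta_rows = []
    for c in compound_table.columns:
        meta_rows.append(("Substrate_" + c, "substrate", compound_categories[c]))
    for c in enzyme_table.columns:
        meta_rows.append((c, "enzyme", enzyme_categories[c]))
    for c in compound_table.columns:
        meta_rows.append(("Product_" + c, "product", compound_categories[c]))
    column_meta = pd.DataFrame(meta_rows, columns=["name", "role", "category"]).set_index("name")
    return FeatureMatrix(X, y, column_meta, tuple(triads))


def category_distribution(m: FeatureMatrix, feature_names: Sequence[str]) -> pd.DataFrame:
    """Counts of a feature subset per (role, category), with
    selected/available proportions per role.

    Unknown names raise ``KeyError``.
    """
    unknown = [n for n in feature_names if n not in m.column_meta.index]
    if unknown:
        raise KeyError(f"unknown feature names: {unknown[:5]}")
    meta = m.column_meta
    groups = meta.groupby(["role", "category"], sort=True).size().rename("available")
    if feature_names:
        sel = meta.loc[list(feature_names)]
        sel_counts = sel.groupby(["role", "category"], sort=True).size().rename("selected")
    else:
        sel_counts = pd.Series(dtype=int, name="selected")
    out = pd.concat([groups, sel_counts], axis=1).fillna(0).astype(int)
    out["proportion"] = out["selected"] / out["available"]
    return out.reset_index()


# --------------------------------------------------------------------------
# persistence

def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(float_format="%.10g").encode()).hexdigest()[:16]


def save_matrix(m: FeatureMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (features + label column) and
    ``<prefix>.meta.json`` (roles, categories, triads, digest)."""
    prefix = Path(prefix)
    table = m.X.copy()
    table["label"] = m.y
    table.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.10g")
    meta = {
        "roles": m.column_meta["role"].to_dict(),
        "categories": m.column_meta["category"].to_dict(),
        "triads": [list(t) for t in m.triads],
        "digest": _digest(m.X),
    }
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))


def load_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    table = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    y = table.pop("label").to_numpy(dtype=np.int8)
    column_meta = pd.DataFrame({
        "role": pd.Series(meta["roles"]),
        "category": pd.Series(meta["categories"]),
    }).loc[list(table.columns)]
    column_meta.index.name = "name"
    triads = tuple(Triad(*t) for t in meta.get("triads", []))
    return FeatureMatrix(table, y, column_meta, triads)
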