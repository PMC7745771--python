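"""Count-table containers, I/O, filtering, subsampling and the shuffled null.

The canonical in-memory layout is samples in rows, taxa (OTUs/ASVs) in
columns.  All readers normalize to this orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "CountMatrix",
    "TaxonomyTable",
    "SubsampleGrid",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "read_biom_json",
    "filter_samples_and_taxa",
    "shuffle_null",
    "subsample",
]

RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise DataError(f"duplicate {what} IDs: {dupes[:5]}")
    return ids


@dataclass
class AbundanceMatrix:
    """Real-valued samples x taxa abundance matrix with IDs."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("abundance matrix must be 2-dimensional")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.taxon_ids = _check_ids(self.taxon_ids, "taxon")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.taxon_ids):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample totals (library sizes)."""
        return self.values.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=pd.Index(self.taxon_ids, name="taxon_id"),
        )


@dataclass
class CountMatrix(AbundanceMatrix):
    """Non-negative integer samples x taxa count matrix.

    Entries must be integral and >= 0; IDs must be unique.
    """

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.any(~np.isfinite(arr.astype(float))):
            raise DataError("counts contain NaN/inf entries")
        if np.any(arr < 0):
            j, i = np.argwhere(arr < 0)[0]
            raise DataError(f"negative count at sample row {j}, taxon column {i}")
        if not np.allclose(arr, np.round(arr)):
            j, i = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise DataError(f"non-integer count at sample row {j}, taxon column {i}")
        self.values = np.round(arr).astype(np.int64)
        super().__post_init__()
        self.values = self.values.astype(np.int64)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(map(str, df.index)), list(map(str, df.columns)))


@dataclass
class TaxonomyTable:
    """Taxon -> (phylum .. genus) rank labels; missing ranks are 'unclassified'."""

    table: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.has_duplicates:
            raise DataError("duplicate taxon IDs in taxonomy table")
        for r in RANKS:
            if r not in df.columns:
                df[r] = UNCLASSIFIED
        df = df[list(RANKS)].astype(str)
        df = df.replace({"": UNCLASSIFIED, "nan": UNCLASSIFIED, "NA": UNCLASSIFIED})
        df.index = df.index.astype(str)
        df.index.name = "taxon_id"
        self.table = df

    def labels(self, taxa: Sequence[str], rank: str) -> pd.Series:
        if rank not in RANKS:
            raise DataError(f"unknown rank {rank!r}; choose from {RANKS}")
        out = self.table[rank].reindex([str(t) for t in taxa])
        return out.fillna(UNCLASSIFIED)

    @classmethod
    def from_blocks(cls, taxon_ids: Sequence[str], labels: dict[str, Sequence[str]]) -> "TaxonomyTable":
        df = pd.DataFrame(labels, index=pd.Index(list(taxon_ids), name="taxon_id"))
        return cls(df)


@dataclass
class SubsampleGrid:
    """Sizes x replicates design for random subsampling without replacement."""

    sizes: Sequence[int]
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [int(s) for s in self.sizes]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise DataError("subsample sizes must be strictly increasing")
        if any(s <= 0 for s in sizes):
            raise DataError("subsample sizes must be positive")
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")
        self.sizes = sizes


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
) -> CountMatrix:
    """Read a delimited count table into the canonical samples x taxa layout.

    Parameters
    ----------
    orientation
        ``"samples-in-rows"`` (default) or ``"taxa-in-rows"``; the latter is
        transposed on read.
    """
    path = Path(path)
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DataError(f"{path}: duplicate row or column IDs in header")
    if orientation == "taxa-in-rows":
        df = df.T
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna())))
        raise DataError(f"{path}: missing value at row {df.index[row]!r}, column {df.columns[col]!r}")
    arr = df.to_numpy()
    bad = (arr < 0) | ~np.isclose(arr.astype(float), np.round(arr.astype(float)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataError(
            f"{path}: invalid count {arr[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return CountMatrix.from_dataframe(df)


def write_count_table(cm: AbundanceMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    cm.to_dataframe().to_csv(path, sep=sep or _sep_for(path))


def read_taxonomy(path: str | Path, sep: str | None = None) -> TaxonomyTable:
    """Read a taxonomy table: either per-rank columns or a single
    semicolon-delimited lineage column (phylum;class;order;family;genus)."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0, dtype=str)
    cols_lower = {c.lower(): c for c in df.columns}
    if any(r in cols_lower for r in RANKS):
        df = df.rename(columns={v: k for k, v in cols_lower.items()})
        return TaxonomyTable(df)
    if df.shape[1] < 1:
        raise DataError(f"{path}: taxonomy table needs a lineage or rank columns")
    lineage = df.iloc[:, 0].fillna("")
    parts = lineage.str.split(";", expand=True).reindex(columns=range(len(RANKS)))
    parts.columns = list(RANKS)
    parts = parts.apply(lambda s: s.str.strip())
    return TaxonomyTable(parts.fillna(UNCLASSIFIED))


def read_biom_json(path: str | Path) -> CountMatrix:
    """Read a BIOM-format table (JSON dialect) into a CountMatrix.

    Supports both "dense" and "sparse" matrix_type payloads. BIOM stores
    observations (taxa) in rows and samples in columns; output is transposed
    to the canonical samples x taxa layout.
    """
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    return CountMatrix(mat.T, samples, taxa)


# ---------------------------------------------------------------------------
# Filtering, null, subsampling
# ---------------------------------------------------------------------------

def filter_samples_and_taxa(
    cm: CountMatrix,
    depth_percentile: float = 0.10,
    prevalence: float = 0.30,
    quantile_method: str = "linear",
) -> CountMatrix:
    """Drop shallow samples, then rarely observed taxa.

    Samples whose depth does not fall strictly above the ``depth_percentile``
    quantile of all depths are removed first; taxa present (count > 0) in
    fewer than ``prevalence`` of the retained samples are removed second.
    The quantile uses the linear-interpolation convention by default.
    """
    if not 0 <= depth_percentile < 1:
        raise DataError("depth_percentile must be in [0, 1)")
    if not 0 <= prevalence <= 1:
        raise DataError("prevalence must be in [0, 1]")
    depths = cm.depths
    if depth_percentile > 0:
        cut = np.quantile(depths, depth_percentile, method=quantile_method)
        keep_s = depths > cut
    else:
        keep_s = depths > 0
    if not keep_s.any():
        raise DataError("depth filter removed every sample")
    counts = cm.values[keep_s]
    present = (counts > 0).mean(axis=0)
    keep_t = present >= prevalence if prevalence > 0 else np.ones(cm.n_taxa, bool)
    if not keep_t.any():
        raise DataError("prevalence filter removed every taxon")
    return CountMatrix(
        counts[:, keep_t],
        [s for s, k in zip(cm.sample_ids, keep_s) if k],
        [t for t, k in zip(cm.taxon_ids, keep_t) if k],
    )


def shuffle_null(cm: CountMatrix, seed: int) -> CountMatrix:
    """Destroy all taxon-taxon association by permuting each taxon's counts
    independently across samples; per-taxon marginals are preserved exactly."""
    rng = np.random.default_rng(seed)
    out = cm.values.copy()
    for i in range(out.shape[1]):
        out[:, i] = out[rng.permutation(out.shape[0]), i]
    return CountMatrix(out, list(cm.sample_ids), list(cm.taxon_ids))


def subsample(
    cm: CountMatrix, grid: SubsampleGrid
) -> Iterator[tuple[int, int, CountMatrix]]:
    """Yield ``(size, replicate, CountMatrix)`` random subsamples without
    replacement, deterministically under ``grid.seed``."""
    if max(grid.sizes) > cm.n_samples:
        raise DataError(
            f"subsample size {max(grid.sizes)} exceeds n={cm.n_samples}"
        )
    rng = np.random.default_rng(grid.seed)
    for size in grid.sizes:
        for rep in range(grid.replicates):
            idx = rng.choice(cm.n_samples, size=size, replace=False)
            yield size, rep, CountMatrix(
                cm.values[idx],
                [cm.sample_ids[j] for j in idx],
                list(cm.taxon_ids),
            )
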