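"""Distances between association matrices, low-dimensional embeddings and
moment summaries of association-value distributions."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .associate import AssociationMatrix
from .data import DataError

__all__ = [
    "MomentSummary",
    "frobenius_distance",
    "spectral_distance",
    "cmd",
    "DISTANCES",
    "pairwise_distance_table",
    "distances_to_reference",
    "mds_embed",
    "moment_summary",
]


def _mat(R) -> np.ndarray:
    if isinstance(R, AssociationMatrix):
        return R.values
    return np.asarray(R, dtype=float)


def _check_pair(R, Rp) -> tuple[np.ndarray, np.ndarray]:
    a, b = _mat(R), _mat(Rp)
    if a.shape != b.shape:
        raise DataError(f"shape mismatch {a.shape} vs {b.shape}")
    if isinstance(R, AssociationMatrix) and isinstance(Rp, AssociationMatrix):
        if R.taxon_ids != Rp.taxon_ids:
            raise DataError("taxon orderings differ between matrices")
    return a, b


def frobenius_distance(R, Rp) -> float:
    """d_f: Frobenius norm of the entrywise difference."""
    a, b = _check_pair(R, Rp)
    return float(np.linalg.norm(a - b, "fro"))


def spectral_distance(R, Rp, literal_sqrt: bool = False) -> float:
    """d_s: operator 2-norm (largest singular value) of the difference.

    ``literal_sqrt`` returns the square root of the largest singular value
    instead (an alternative printed form of the same statistic).
    """
    a, b = _check_pair(R, Rp)
    smax = float(np.linalg.norm(a - b, 2)) if a.size else 0.0
    return float(np.sqrt(smax)) if literal_sqrt else smax


def cmd(R, Rp) -> float:
    """Correlation matrix distance 1 - tr(R R') / (||R||_F ||R'||_F) in [0,1]."""
    a, b = _check_pair(R, Rp)
    na, nb = np.linalg.norm(a, "fro"), np.linalg.norm(b, "fro")
    if na == 0 or nb == 0:
        raise DataError("cmd undefined for zero-norm input")
    return float(1.0 - np.trace(a @ b) / (na * nb))


DISTANCES = {"frobenius": frobenius_distance, "spectral": spectral_distance, "cmd": cmd}


def pairwise_distance_table(
    estimates: Mapping[tuple, AssociationMatrix] | Sequence[AssociationMatrix],
    metric: str = "frobenius",
) -> pd.DataFrame:
    """Score every unordered pair of estimates under one distance.

    ``estimates`` maps labels (e.g. ``(method, n, replicate)`` tuples) to
    association matrices.  Returns a tidy frame with one row per pair.
    """
    fn = DISTANCES[metric]
    if not isinstance(estimates, Mapping):
        estimates = {i: m for i, m in enumerate(estimates)}
    labels = list(estimates)
    rows = [
        {"estimate_a": a, "estimate_b": b, "metric": metric,
         "value": fn(estimates[a], estimates[b])}
        for a, b in combinations(labels, 2)
    ]
    return pd.DataFrame(rows, columns=["estimate_a", "estimate_b", "metric", "value"])


def distances_to_reference(
    estimates: Mapping[tuple, AssociationMatrix],
    reference: AssociationMatrix,
    metric: str = "frobenius",
) -> pd.DataFrame:
    """Distance of every estimate to a fixed (large-sample) reference."""
    fn = DISTANCES[metric]
    rows = [{"estimate": lab, "metric": metric, "value": fn(m, reference)}
            for lab, m in estimates.items()]
    return pd.DataFrame(rows, columns=["estimate", "metric", "value"])


def mds_embed(distance_matrix, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Deterministic up to rotation/reflection; coordinates are centered at the
    origin.  ``distance_matrix`` is a full symmetric matrix of pairwise
    distances (DataFrame or array).
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DataError("mds_embed needs a square distance matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise DataError("distance matrix must be symmetric")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


@dataclass
class MomentSummary:
    """Moments of the strictly-upper-triangle association values.

    Skewness and kurtosis are the standardized third and fourth central
    moments (kurtosis is not excess); both are NaN sentinels when the
    off-diagonal values are constant.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis: float


def moment_summary(R) -> MomentSummary:
    vals = R.offdiag() if isinstance(R, AssociationMatrix) else _offdiag(np.asarray(R, float))
    if len(vals) < 3:
        raise DataError("moment_summary needs p >= 3")
    var = float(np.var(vals))
    if var == 0.0:
        return MomentSummary(float(np.mean(vals)), 0.0, float("nan"), float("nan"))
    return MomentSummary(
        float(np.mean(vals)), var,
        float(stats.skew(vals, bias=True)),
        float(stats.kurtosis(vals, fisher=False, bias=True)),
    )


def _offdiag(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]
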