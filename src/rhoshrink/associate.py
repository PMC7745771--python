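"""Sample and shrinkage estimators of covariance, correlation and
proportionality.

The shrinkage estimators follow the Schafer-Strimmer scheme: off-diagonal
correlations are shrunk linearly toward zero (identity target) with a
data-driven intensity lambda1, and variances are shrunk toward their median
with a second intensity lambda2.  Both intensities minimize an estimate of
mean squared error built from the empirical variance of the per-observation
product terms.  The shrinkage proportionality estimator rho* (rhoshrink)
plugs the shrunk covariance entries into the proportionality statistic

    rho*(X_i, X_k) = 2 s*_ik / (s*_ii + s*_kk),

computed on centered log-ratio transformed data, and reduces exactly to the
sample proportionality rho_p when both intensities are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import AbundanceMatrix, DataError
from .normalize import NormalizedMatrix

__all__ = [
    "AssociationMatrix",
    "ShrinkageIntensities",
    "sample_covariance",
    "sample_correlation",
    "proportionality_rho",
    "estimate_shrinkage_intensities",
    "shrinkage_covariance",
    "shrinkage_correlation",
    "shrinkage_proportionality",
]


@dataclass
class ShrinkageIntensities:
    """Data-driven shrinkage weights, both clipped to [0, 1].

    ``lambda1`` scales off-diagonal correlations toward 0; ``lambda2`` pulls
    variances toward their median.
    """

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2"):
            lam = getattr(self, name)
            if not 0.0 <= lam <= 1.0:
                raise DataError(f"{name}={lam} outside [0, 1]")


@dataclass
class AssociationMatrix:
    """Symmetric p x p association matrix with estimator metadata."""

    values: np.ndarray
    metric: str  # covariance | correlation | rho_p | rho_star
    taxon_ids: list[str]
    normalization: str | None = None
    intensities: ShrinkageIntensities | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("association matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("association matrix must be symmetric")
        self.values = 0.5 * (v + v.T)
        if len(self.taxon_ids) != v.shape[0]:
            raise DataError("taxon_ids length does not match matrix size")
        if self.metric in ("correlation", "rho_p", "rho_star"):
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
                raise DataError(f"{self.metric} diagonal must be 1")
            if np.any(np.abs(self.values) > 1 + 1e-8):
                raise DataError(f"{self.metric} entries must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Strictly-upper-triangle values as a flat vector."""
        iu = np.triu_indices(self.p, k=1)
        return self.values[iu]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.taxon_ids)


def _data(X) -> tuple[np.ndarray, list[str], str | None]:
    if isinstance(X, NormalizedMatrix):
        return np.asarray(X.values, float), list(X.taxon_ids), X.method
    if isinstance(X, AbundanceMatrix):
        return np.asarray(X.values, float), list(X.taxon_ids), None
    arr = np.asarray(X, dtype=float)
    return arr, [f"T{i}" for i in range(arr.shape[1])], None


def _require_clr(method: str | None, strict: bool, what: str) -> None:
    if method != "clr":
        msg = f"{what} is defined on clr-transformed data (got {method!r})"
        if strict:
            raise DataError(msg)
        import warnings

        warnings.warn(msg, stacklevel=3)


# ---------------------------------------------------------------------------
# Sample estimators
# ---------------------------------------------------------------------------

def sample_covariance(X) -> AssociationMatrix:
    """Unbiased sample covariance of the taxa columns."""
    x, taxa, method = _data(X)
    n = x.shape[0]
    if n < 2:
        raise DataError("sample covariance needs n >= 2")
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / (n - 1)
    return AssociationMatrix(s, "covariance", taxa, normalization=method, n=n)


def sample_correlation(X) -> AssociationMatrix:
    """Pearson correlation R = D^{-1/2} S D^{-1/2} of the taxa columns."""
    cov = sample_covariance(X)
    d = np.diag(cov.values)
    if np.any(d <= 0):
        _, taxa, _ = _data(X)
        bad = [taxa[i] for i in np.where(d <= 0)[0]]
        raise DataError(f"zero-variance taxa: {bad[:10]}")
    inv = 1.0 / np.sqrt(d)
    r = np.clip(cov.values * np.outer(inv, inv), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(r, "correlation", cov.taxon_ids,
                             normalization=cov.normalization, n=cov.n)


def proportionality_rho(Xclr, strict: bool = True) -> AssociationMatrix:
    """Symmetric proportionality rho_p on clr-transformed data.

    rho_p(X_i, X_k) = 1 - var(X_i - X_k) / (var(X_i) + var(X_k))
                    = 2 cov(X_i, X_k) / (var(X_i) + var(X_k)).
    """
    x, taxa, method = _data(Xclr)
    _require_clr(method, strict, "rho_p")
    cov = sample_covariance(Xclr)
    d = np.diag(cov.values)
    if np.any(d <= 0):
        raise DataError("rho_p requires positive clr column variances")
    denom = d[:, None] + d[None, :]
    rho = np.clip(2.0 * cov.values / denom, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return AssociationMatrix(rho, "rho_p", taxa, normalization=method, n=cov.n)


# ---------------------------------------------------------------------------
# Shrinkage
# ---------------------------------------------------------------------------

def estimate_shrinkage_intensities(X) -> ShrinkageIntensities:
    """Estimate the Schafer-Strimmer intensities lambda1*, lambda2*.

    lambda1* = sum_{i != k} Var(r_ik) / sum_{i != k} r_ik^2 from the
    empirical variance of standardized cross-products; lambda2* shrinks
    variances toward their median analogously.  Both are clipped to [0, 1].
    """
    x, _, _ = _data(X)
    n, p = x.shape
    if n < 3:
        raise DataError("shrinkage intensity estimation needs n >= 3")
    xc = x - x.mean(axis=0)
    sd = np.sqrt((xc ** 2).sum(axis=0) / (n - 1))
    if np.any(sd <= 0):
        raise DataError("zero-variance taxa; filter before shrinkage")

    # --- lambda1 from standardized data ------------------------------------
    z = xc / sd
    wbar = z.T @ z / n                       # mean of per-observation products
    r = wbar * n / (n - 1)                   # sample correlation
    # Var-hat(r_ik) = n/(n-1)^3 * sum_j (z_ji z_jk - wbar_ik)^2
    sq = (z ** 2).T @ (z ** 2) / n           # mean of squared products
    var_w = sq - wbar ** 2                   # per-observation variance (biased)
    var_r = n ** 2 / (n - 1) ** 3 * var_w
    iu = np.triu_indices(p, k=1)
    denom = float((r[iu] ** 2).sum())
    if denom <= 0:
        lam1 = 1.0
    else:
        lam1 = float(np.clip(var_r[iu].sum() / denom, 0.0, 1.0))

    # --- lambda2 from centered squares --------------------------------------
    v = xc ** 2
    vbar = v.mean(axis=0)
    s_ii = vbar * n / (n - 1)
    var_s = n ** 2 / (n - 1) ** 3 * ((v - vbar) ** 2).mean(axis=0)
    med = np.median(s_ii)
    denom2 = float(((s_ii - med) ** 2).sum())
    lam2 = 1.0 if denom2 <= 0 else float(np.clip(var_s.sum() / denom2, 0.0, 1.0))
    return ShrinkageIntensities(lam1, lam2)


def _resolve(X, intensities) -> ShrinkageIntensities:
    if intensities is None or intensities == "auto":
        return estimate_shrinkage_intensities(X)
    if isinstance(intensities, ShrinkageIntensities):
        return intensities
    lam1, lam2 = intensities
    return ShrinkageIntensities(float(lam1), float(lam2))


def shrinkage_correlation(X, intensities=None) -> AssociationMatrix:
    """Shrunk correlation: off-diagonals scaled by (1 - lambda1)."""
    lam = _resolve(X, intensities)
    r = sample_correlation(X)
    out = (1.0 - lam.lambda1) * r.values
    np.fill_diagonal(out, 1.0)
    return AssociationMatrix(out, "correlation", r.taxon_ids,
                             normalization=r.normalization, intensities=lam, n=r.n)


def shrinkage_covariance(X, intensities=None,
                         consistent_diagonal: bool = False) -> AssociationMatrix:
    """Schafer-Strimmer shrinkage covariance.

    Off-diagonal: s*_ik = (1-lambda1) r_ik sqrt(s_ii s_kk) with *unshrunk*
    variances under the scaling (the printed form); diagonal: s*_ii =
    lambda2 * median(s) + (1-lambda2) s_ii.  ``consistent_diagonal`` uses the
    shrunk variances in the off-diagonal rescaling instead.
    """
    lam = _resolve(X, intensities)
    cov = sample_covariance(X)
    s = cov.values
    d = np.diag(s).copy()
    if np.any(d <= 0):
        raise DataError("zero-variance taxa; filter before shrinkage")
    med = np.median(d)
    d_star = lam.lambda2 * med + (1.0 - lam.lambda2) * d
    r = s / np.sqrt(np.outer(d, d))
    r_star = (1.0 - lam.lambda1) * r
    scale = d_star if consistent_diagonal else d
    out = r_star * np.sqrt(np.outer(scale, scale))
    np.fill_diagonal(out, d_star)
    return AssociationMatrix(out, "covariance", cov.taxon_ids,
                             normalization=cov.normalization, intensities=lam, n=cov.n)


def shrinkage_proportionality(Xclr, intensities=None, strict: bool = True,
                              consistent_diagonal: bool = False) -> AssociationMatrix:
    """Shrinkage proportionality rho* = 2 s*_ik / (s*_ii + s*_kk) on clr data."""
    _, _, method = _data(Xclr)
    _require_clr(method, strict, "rho*")
    cov = shrinkage_covariance(Xclr, intensities,
                               consistent_diagonal=consistent_diagonal)
    d = np.diag(cov.values)
    rho = np.clip(2.0 * cov.values / (d[:, None] + d[None, :]), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return AssociationMatrix(rho, "rho_star", cov.taxon_ids,
                             normalization=method, intensities=cov.intensities,
                             n=cov.n)
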