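"""Count normalization and transformation schemes for microbial survey data.

Eight schemes are provided, spanning simple rescaling (total-sum, cumulative-
sum, common-sum), RNA-seq style size-factor methods (relative log expression,
variance-stabilizing transform), zero-inflation-aware compositional correction
(Wrench), and variance-reducing transforms (inverse hyperbolic sine, centered
log-ratio).  Each scheme maps a non-negative integer count matrix W (samples x
taxa) to a real matrix X = f(W) of the same shape, tagged with the method and
parameters that produced it.

Pseudocount policy: methods that take logarithms or require strictly positive
input (``clr``, ``rle``, ``vst``) add a pseudocount (default 1) internally;
``tss``, ``css``, ``com``, ``wren`` and ``asinh`` consume raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import interp1d

from .data import AbundanceMatrix, CountMatrix, DataError

__all__ = [
    "NormalizedMatrix",
    "DispersionFit",
    "METHODS",
    "add_pseudocount",
    "normalize",
    "tss",
    "css",
    "com",
    "rle",
    "asinh_transform",
    "wrench",
    "fit_dispersion",
    "vst",
    "clr",
]


@dataclass
class NormalizedMatrix(AbundanceMatrix):
    """Samples x taxa real matrix tagged with the normalization that made it."""

    method: str = "raw"
    params: dict = field(default_factory=dict)

    @classmethod
    def _from(cls, src: AbundanceMatrix, values: np.ndarray, method: str, **params):
        return cls(values, list(src.sample_ids), list(src.taxon_ids),
                   method=method, params=params)


def _as_array(cm: AbundanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(cm, AbundanceMatrix):
        return np.asarray(cm.values, dtype=float)
    return np.asarray(cm, dtype=float)


def _wrap(cm, values, method, **params) -> NormalizedMatrix:
    if isinstance(cm, AbundanceMatrix):
        return NormalizedMatrix._from(cm, values, method, **params)
    n, p = values.shape
    return NormalizedMatrix(values, [f"S{j}" for j in range(n)],
                            [f"T{i}" for i in range(p)], method=method, params=params)


def _depths(w: np.ndarray, method: str) -> np.ndarray:
    m = w.sum(axis=1)
    if np.any(m <= 0):
        j = int(np.argmin(m))
        raise DataError(f"{method}: sample at row {j} has zero depth")
    return m


def add_pseudocount(cm: CountMatrix | AbundanceMatrix, c: float = 1.0) -> AbundanceMatrix:
    """Return a copy with ``c`` added to every entry (``c`` > 0)."""
    if c <= 0:
        raise DataError("pseudocount must be > 0")
    w = _as_array(cm)
    if isinstance(cm, AbundanceMatrix):
        return AbundanceMatrix(w + c, list(cm.sample_ids), list(cm.taxon_ids))
    return AbundanceMatrix(w + c, [f"S{j}" for j in range(w.shape[0])],
                           [f"T{i}" for i in range(w.shape[1])])


# ---------------------------------------------------------------------------
# Simple rescalings
# ---------------------------------------------------------------------------

def tss(cm) -> NormalizedMatrix:
    """Total sum scaling: each sample divided by its depth; rows sum to 1."""
    w = _as_array(cm)
    m = _depths(w, "tss")
    return _wrap(cm, w / m[:, None], "tss")


def _sample_quantiles(w: np.ndarray, probs: np.ndarray) -> np.ndarray:
    # per-sample type-7 quantiles of the full count vector (zeros included)
    return np.quantile(w, probs, axis=1, method="linear").T  # n x L


def css_reference_quantile(cm) -> tuple[float, np.ndarray]:
    """Locate the stable quantile level used by cumulative sum scaling.

    Per-sample quantiles q_l^(j) are taken on the grid l/p (type-7); their
    instability delta_l = med_j |q_l^(j) - med_j q_l^(j)| is scanned for the
    first l with delta_{l+1} - delta_l >= 0.1 * delta_l.  Falls back to the
    median (0.5) quantile when no level is stable.
    """
    w = _as_array(cm)
    n, p = w.shape
    probs = np.arange(1, p + 1) / p
    q = _sample_quantiles(w, probs)  # n x p
    qbar = np.median(q, axis=0)
    delta = np.median(np.abs(q - qbar), axis=0)
    lhat = None
    for l in range(len(probs) - 1):
        if delta[l + 1] - delta[l] >= 0.1 * delta[l] and delta[l] > 0:
            lhat = l
            break
    if lhat is None:
        prob = 0.5
    else:
        prob = probs[lhat]
    return prob, np.quantile(w, prob, axis=1, method="linear")


def css(cm, N: float = 1000.0) -> NormalizedMatrix:
    """Cumulative sum scaling: divide by the sum of counts up to a stable
    quantile, times a fixed constant ``N``."""
    if N <= 0:
        raise DataError("css: N must be > 0")
    w = _as_array(cm)
    if w.shape[0] < 2:
        raise DataError("css needs at least 2 samples")
    prob, qhat = css_reference_quantile(cm)
    scale = np.where(w <= qhat[:, None], w, 0.0).sum(axis=1)
    if np.any(scale <= 0):
        j = int(np.argmin(scale))
        raise DataError(f"css: zero scaling factor for sample at row {j}")
    return _wrap(cm, w * N / scale[:, None], "css", N=N, quantile=prob)


def com(cm) -> NormalizedMatrix:
    """Common sum scaling: rescale every sample to the minimum depth and
    floor to integers."""
    w = _as_array(cm)
    m = _depths(w, "com")
    return _wrap(cm, np.floor(w * (m.min() / m)[:, None]), "com")


def _geomean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


def rle_factors(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Median-of-ratios scaling factors: raw s^(j), normalized s-bar^(j)
    (geometric mean 1) and the global arithmetic-mean factor."""
    ref = _geomean(w, axis=0)
    s = np.median(w / ref, axis=1)
    sbar = s / _geomean(s)
    return s, sbar, float(sbar.mean())


def rle(cm, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Relative log expression (median-of-ratios) scaling.

    Per-sample factor s^(j) = med_i w_i^(j)/g(w_i), normalized by the
    geometric mean of all factors; the global factor is the arithmetic mean
    of the normalized factors.  A pseudocount makes all entries positive.
    """
    w = _as_array(cm)
    if pseudocount:
        w = w + pseudocount
    if np.any(w <= 0):
        raise DataError("rle requires positive entries; apply a pseudocount")
    _, sbar, sc = rle_factors(w)
    return _wrap(cm, sc * w / sbar[:, None], "rle", pseudocount=pseudocount)


def asinh_transform(cm) -> NormalizedMatrix:
    """Inverse hyperbolic sine log(w + sqrt(w^2+1)), then per-taxon mean
    centering."""
    w = _as_array(cm)
    x = np.arcsinh(w)
    return _wrap(cm, x - x.mean(axis=0), "asinh")


def wrench(cm, weights: str = "unit") -> NormalizedMatrix:
    """Wrench compositional correction with all samples in one group.

    The compositional scale factor for sample j is a (weighted) mean over
    taxa of the ratio between the sample's proportion and the across-sample
    average proportion of that taxon.  ``weights="unit"`` is the tested
    contract; ``"w2-approx"`` downweights taxa by the empirical variance of
    those ratios (a moment-based stand-in for hurdle-model weights).
    """
    w = _as_array(cm)
    m = _depths(w, "wren")
    y = w / m[:, None]
    ybar = y.mean(axis=0)
    if np.any(ybar <= 0):
        i = int(np.argmin(ybar))
        raise DataError(f"wren: taxon column {i} has zero mean proportion; filter first")
    ratio = y / ybar
    if weights == "unit":
        eta_inv = ratio.mean(axis=1)
    elif weights == "w2-approx":
        var = ratio.var(axis=0, ddof=1)
        e = 1.0 / (var + 1e-12)
        eta_inv = (ratio * e).sum(axis=1) / e.sum()
    else:
        raise DataError(f"wren: unknown weight scheme {weights!r}")
    return _wrap(cm, w / (m * eta_inv)[:, None], "wren", weights=weights)


# ---------------------------------------------------------------------------
# Variance-stabilizing transform
# ---------------------------------------------------------------------------

def size_factors(w: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the per-taxon geometric mean."""
    ref = _geomean(w, axis=0)
    return np.median(w / ref, axis=1)


@dataclass
class DispersionFit:
    """Fitted mean-variance relation of size-factor-normalized counts.

    The full variance is modelled as shot noise plus a smooth monotone
    excess term: v(mu) = shot_noise_coef * mu + v_excess(mu), where the
    excess is interpolated (and linearly extrapolated) in log-log space on
    ``(mu_grid, v_grid)``.  The shot-noise coefficient is mean(1/s) over the
    size factors; for pure counting noise the excess is negligible and
    v(mu) is essentially proportional to mu.
    """

    mu_grid: np.ndarray
    v_grid: np.ndarray  # excess variance on the grid, strictly positive
    size_factors_: np.ndarray
    shot_noise_coef: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.v_grid <= 0):
            raise DataError("fitted variance must be strictly positive")
        if self.shot_noise_coef < 0:
            raise DataError("shot-noise coefficient must be >= 0")
        self._interp = interp1d(
            np.log(self.mu_grid), np.log(self.v_grid),
            kind="linear", fill_value="extrapolate", assume_sorted=True,
        )

    def v(self, mu: np.ndarray) -> np.ndarray:
        """Full fitted variance at mean ``mu`` (strictly positive)."""
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
        return self.shot_noise_coef * mu + np.exp(self._interp(np.log(mu)))

    @classmethod
    def from_function(cls, fn: Callable[[np.ndarray], np.ndarray],
                      lo: float = 1e-4, hi: float = 1e7,
                      size_factors_: np.ndarray | None = None) -> "DispersionFit":
        """Wrap a closed-form variance function (no shot-noise split)."""
        grid = np.geomspace(lo, hi, 600)
        return cls(grid, np.asarray(fn(grid), dtype=float),
                   size_factors_ if size_factors_ is not None else np.array([1.0]))


def fit_dispersion(cm, pseudocount: float = 1.0, frac: float = 0.4) -> DispersionFit:
    """Fit the mean-variance relation of size-factor-normalized counts.

    Raw per-taxon variances of count/size-factor ratios are corrected for
    shot noise (z_i = mu_i * mean(1/s)), then smoothed by lowess in log-log
    space and made monotone non-decreasing.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    w = _as_array(cm)
    if pseudocount:
        w = w + pseudocount
    n = w.shape[0]
    if n < 3:
        raise DataError("fit_dispersion needs at least 3 samples")
    s = size_factors(w)
    q = w / s[:, None]
    mu = q.mean(axis=0)
    if len(np.unique(np.round(mu, 10))) < 3:
        raise DataError("fit_dispersion needs at least 3 distinct taxon means")
    raw_var = q.var(axis=0, ddof=1)
    coef = float(np.mean(1.0 / s))
    z = mu * coef
    excess = raw_var - z
    keep = (mu > 0) & (excess > 0)
    if keep.sum() < 3:
        # counting noise swamps any excess: a negligible excess floor
        grid = np.geomspace(max(mu.min(), 1e-3), mu.max() + 1.0, 50)
        return DispersionFit(grid, 1e-8 * grid, s, shot_noise_coef=coef)
    lx, ly = np.log(mu[keep]), np.log(excess[keep])
    order = np.argsort(lx)
    sm = lowess(ly[order], lx[order], frac=frac, return_sorted=True)
    gx, gy = sm[:, 0], np.maximum.accumulate(sm[:, 1])
    gx, idx = np.unique(gx, return_index=True)
    return DispersionFit(np.exp(gx), np.exp(gy[idx]), s, shot_noise_coef=coef)


def vst(cm, fit: DispersionFit | None = None, calibrate: bool = True,
        pseudocount: float = 1.0, grid_points: int = 2000) -> NormalizedMatrix:
    """Variance-stabilizing transform: u(w) = integral_0^w dmu / sqrt(v(mu)).

    The integral is evaluated by trapezoid quadrature after the substitution
    mu = t^2, which removes the integrable singularity at 0 (for v(mu) = mu
    the quadrature is exact and u(w) = 2*sqrt(w)).  With ``calibrate`` the
    result is affinely mapped so that large counts track log2 of size-factor-
    normalized counts.
    """
    w = _as_array(cm)
    if pseudocount:
        w = w + pseudocount
    if fit is None:
        fit = fit_dispersion(cm, pseudocount=pseudocount)
    wmax = w.max()
    t = np.linspace(0.0, np.sqrt(wmax), grid_points)
    integrand = np.empty_like(t)
    integrand[1:] = 2.0 * t[1:] / np.sqrt(fit.v(t[1:] ** 2))
    integrand[0] = integrand[1]  # continuous limit; exact for v ~ mu near 0
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(t))])
    u = np.interp(np.sqrt(w), t, cum)
    params = {"calibrated": calibrate, "pseudocount": pseudocount}
    if calibrate:
        s = fit.size_factors_
        norm = w / (s[:, None] if len(s) == w.shape[0] else 1.0)
        hi = w >= np.quantile(w, 0.75)
        a, b = np.polyfit(u[hi].ravel(), np.log2(norm[hi]).ravel(), 1)
        u = a * u + b
        params.update(slope=float(a), intercept=float(b))
    return _wrap(cm, u, "vst", **params)


# ---------------------------------------------------------------------------
# Centered log-ratio
# ---------------------------------------------------------------------------

def clr(cm, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio transform: log of each entry over the geometric
    mean of its sample; rows sum to zero."""
    w = _as_array(cm)
    if pseudocount:
        w = w + pseudocount
    if np.any(w <= 0):
        raise DataError("clr requires positive entries; apply a pseudocount")
    lw = np.log(w)
    return _wrap(cm, lw - lw.mean(axis=1, keepdims=True), "clr",
                 pseudocount=pseudocount)


METHODS: dict[str, Callable] = {
    "tss": tss, "css": css, "com": com, "rle": rle,
    "asinh": asinh_transform, "wren": wrench, "vst": vst, "clr": clr,
}


def normalize(cm, method: str, **params) -> NormalizedMatrix:
    """Dispatch to one of the eight schemes by name."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise DataError(f"unknown normalization {method!r}; choose from {sorted(METHODS)}")
    return fn(cm, **params)
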