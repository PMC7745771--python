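"""Synthetic zero-inflated compositional count data with known latent
association structure.

The generative family is logistic-normal-multinomial: a latent log-abundance
vector is drawn from a multivariate normal with a prescribed correlation
structure, mapped through softmax to a composition, and counts are drawn
multinomially at a heavy-tailed (log-normal) library size.  Extra zeros are
applied post hoc as independent per-taxon masking.  Because the clr of the
latent composition is exactly multivariate normal, the latent correlation
(and the proportionality it implies on noiseless clr space) is an honest
recovery target for clr-based estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import CountMatrix, DataError, RANKS, TaxonomyTable

__all__ = [
    "SyntheticSpec",
    "SimulationResult",
    "make_block_correlation",
    "block_spec",
    "simulate_counts",
    "make_taxonomy",
]


def make_block_correlation(p: int, blocks: Sequence[int], within: float,
                           between: float = 0.0) -> np.ndarray:
    """Block-constant correlation target with unit diagonal.

    Non-PSD requests are repaired by eigenvalue clipping followed by
    re-normalization to unit diagonal; an unrepairable request errors.
    """
    if abs(within) >= 1 or abs(between) >= 1:
        raise DataError("|within| and |between| must be < 1")
    if sum(blocks) != p:
        raise DataError(f"block sizes {blocks} do not sum to p={p}")
    C = np.full((p, p), float(between))
    start = 0
    for b in blocks:
        C[start:start + b, start:start + b] = within
        start += b
    np.fill_diagonal(C, 1.0)
    mineig = float(np.linalg.eigvalsh(C).min())
    if mineig < -1e-10:
        vals, vecs = np.linalg.eigh(C)
        C = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise DataError("could not repair non-PSD correlation request")
    return C


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``base_abundances`` are log-scale means of the latent abundances; a
    wide spread makes a few taxa dominate each sample, which reproduces the
    heavy-tailed abundance distributions and high zero fraction of real
    surveys.  ``latent_sd`` scales the log-scale fluctuations.  Library
    sizes are log-normal.
    """

    p: int
    n: int
    latent_correlation: np.ndarray
    base_abundances: np.ndarray
    latent_sd: np.ndarray | float = 1.0
    log_depth_mean: float = 9.0
    log_depth_sd: float = 0.6
    zero_inflation: np.ndarray | float = 0.0
    block_sizes: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.latent_correlation, dtype=float)
        if C.shape != (self.p, self.p):
            raise DataError("latent_correlation must be p x p")
        if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0):
            raise DataError("latent_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise DataError("latent_correlation must be PSD")
        self.latent_correlation = C
        self.base_abundances = np.asarray(self.base_abundances, dtype=float)
        if self.base_abundances.shape != (self.p,):
            raise DataError("base_abundances must have length p")
        self.latent_sd = np.broadcast_to(np.asarray(self.latent_sd, float), (self.p,)).copy()
        zi = np.broadcast_to(np.asarray(self.zero_inflation, float), (self.p,)).copy()
        if np.any((zi < 0) | (zi >= 1)):
            raise DataError("zero_inflation must lie in [0, 1)")
        self.zero_inflation = zi

    @property
    def latent_covariance(self) -> np.ndarray:
        s = self.latent_sd
        return self.latent_correlation * np.outer(s, s)

    def clr_truth(self) -> tuple[np.ndarray, np.ndarray]:
        """Correlation and proportionality implied on noiseless clr space.

        clr(softmax(a)) = a - mean(a), so the clr covariance is G Sigma G
        with G the centering projector.
        """
        p = self.p
        G = np.eye(p) - np.ones((p, p)) / p
        S = G @ self.latent_covariance @ G
        d = np.diag(S)
        corr = S / np.sqrt(np.outer(d, d))
        np.fill_diagonal(corr, 1.0)
        rho = 2.0 * S / (d[:, None] + d[None, :])
        np.fill_diagonal(rho, 1.0)
        return corr, rho


def block_spec(p: int = 100, n: int = 200, n_blocks: int = 10, within: float = 0.6,
               between: float = 0.0, zero_inflation: float = 0.0,
               base_spread: float = 2.0, sizes: Sequence[int] | None = None,
               seed: int = 0, **kw) -> SyntheticSpec:
    """Convenience builder: block correlation structure (equal sizes unless
    ``sizes`` is given) and heavy-tailed base abundances drawn once from
    N(0, base_spread^2)."""
    if sizes is None:
        sizes = [p // n_blocks] * n_blocks
        sizes[-1] += p - sum(sizes)
    sizes = list(sizes)
    C = make_block_correlation(p, sizes, within, between)
    rng = np.random.default_rng(seed)
    base = np.sort(rng.normal(0.0, base_spread, size=p))[::-1].copy()
    return SyntheticSpec(p=p, n=n, latent_correlation=C, base_abundances=base,
                         zero_inflation=zero_inflation, block_sizes=sizes,
                         seed=seed, **kw)


@dataclass
class SimulationResult:
    counts: CountMatrix
    latent_correlation: np.ndarray
    clr_correlation_truth: np.ndarray
    rho_truth: np.ndarray
    depths_premask: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)


def simulate_counts(spec: SyntheticSpec, seed: int | None = None) -> SimulationResult:
    """Draw one logistic-normal-multinomial dataset from ``spec``.

    Returns the counts together with the latent correlation, the implied
    noiseless-clr correlation and proportionality truths, and the
    pre-masking depths (row sums before extra-zero masking).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cov = spec.latent_covariance
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(spec.p))
    z = rng.standard_normal((spec.n, spec.p))
    loga = spec.base_abundances + z @ chol.T
    loga -= loga.max(axis=1, keepdims=True)  # softmax stability
    comp = np.exp(loga)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = np.maximum(
        np.round(rng.lognormal(spec.log_depth_mean, spec.log_depth_sd, spec.n)), 1
    ).astype(np.int64)
    counts = rng.multinomial(depths, comp).astype(np.int64)
    if np.any(spec.zero_inflation > 0):
        mask = rng.random((spec.n, spec.p)) < spec.zero_inflation[None, :]
        counts = np.where(mask, 0, counts)
    corr_truth, rho_truth = spec.clr_truth()
    cm = CountMatrix(counts, [f"S{j:05d}" for j in range(spec.n)],
                     [f"OTU{i:04d}" for i in range(spec.p)])
    return SimulationResult(cm, spec.latent_correlation.copy(), corr_truth,
                            rho_truth, depths, spec)


_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Verrucomicrobia", "Fusobacteria")


def make_taxonomy(spec: SyntheticSpec, fidelity: float = 1.0,
                  seed: int | None = None) -> TaxonomyTable:
    """Taxonomy aligned with the latent blocks: taxa in one block share the
    same family and genus.  With ``fidelity`` < 1 a fraction of taxa get a
    genus label from a different block (label noise)."""
    if spec.block_sizes is None:
        raise DataError("spec has no block structure to map to taxonomy")
    if not 0 <= fidelity <= 1:
        raise DataError("fidelity must be in [0, 1]")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    block_of = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    nb = len(spec.block_sizes)
    taxa = [f"OTU{i:04d}" for i in range(spec.p)]
    rows = {r: [] for r in RANKS}
    for i, b in enumerate(block_of):
        g = int(b)
        if fidelity < 1 and rng.random() > fidelity and nb > 1:
            g = int(rng.choice([x for x in range(nb) if x != b]))
        rows["phylum"].append(_PHYLA[b % len(_PHYLA)])
        rows["class"].append(f"Class_{b}")
        rows["order"].append(f"Order_{b}")
        rows["family"].append(f"Family_{b}")
        rows["genus"].append(f"Genus_{g}")
    return TaxonomyTable.from_blocks(taxa, rows)
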