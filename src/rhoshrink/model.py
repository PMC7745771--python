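"""Model-style front end: build a :class:`MicrobialAssociation` from a count
table, ``fit()`` it, and work with the resulting association estimate.

This is the convenience surface over the functional modules: normalization
(:mod:`rhoshrink.normalize`), estimation (:mod:`rhoshrink.associate`) and
downstream analysis (:mod:`rhoshrink.downstream`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import associate, downstream
from .normalize import METHODS as _NORM_METHODS
from .normalize import NormalizedMatrix
from .normalize import normalize as _normalize
from .associate import AssociationMatrix, ShrinkageIntensities
from .compare import DISTANCES, MomentSummary, moment_summary
from .data import CountMatrix, DataError, TaxonomyTable

__all__ = ["MicrobialAssociation", "AssociationResults"]

_ESTIMATORS = ("correlation", "covariance", "rho")


class MicrobialAssociation:
    """Linear taxon-taxon association model for a microbial count table.

    Parameters
    ----------
    counts
        A :class:`~rhoshrink.data.CountMatrix` (or samples x taxa DataFrame
        of non-negative integers).
    normalization
        One of ``tss, css, com, rle, asinh, wren, vst, clr`` (default
        ``clr``).
    metric
        ``"correlation"``, ``"covariance"`` or ``"rho"`` (proportionality;
        requires clr normalization).
    shrink
        ``"auto"`` (default) estimates the two shrinkage intensities from
        the data; ``None`` disables shrinkage; a ``(lambda1, lambda2)``
        pair fixes them.
    taxonomy
        Optional :class:`~rhoshrink.data.TaxonomyTable` used by downstream
        purity/assortativity summaries.

    Examples
    --------
    >>> model = MicrobialAssociation(counts, normalization="clr", metric="rho")
    >>> res = model.fit()
    >>> res.intensities.lambda1  # doctest: +SKIP
    """

    def __init__(self, counts, normalization: str = "clr",
                 metric: str = "rho", shrink="auto",
                 taxonomy: TaxonomyTable | None = None, **norm_params):
        if isinstance(counts, pd.DataFrame):
            counts = CountMatrix.from_dataframe(counts)
        if not isinstance(counts, CountMatrix):
            counts = CountMatrix(np.asarray(counts),
                                 [f"S{j}" for j in range(np.asarray(counts).shape[0])],
                                 [f"T{i}" for i in range(np.asarray(counts).shape[1])])
        if metric not in _ESTIMATORS:
            raise DataError(f"metric must be one of {_ESTIMATORS}")
        if metric == "rho" and normalization != "clr":
            raise DataError("proportionality (rho) requires clr normalization")
        if normalization not in _NORM_METHODS:
            raise DataError(f"unknown normalization {normalization!r}")
        self.counts = counts
        self.normalization = normalization
        self.metric = metric
        self.shrink = shrink
        self.taxonomy = taxonomy
        self.norm_params = norm_params

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MicrobialAssociation":
        return cls(CountMatrix.from_dataframe(df), **kw)

    @property
    def nobs(self) -> int:
        return self.counts.n_samples

    def fit(self) -> "AssociationResults":
        """Normalize, (optionally) estimate shrinkage intensities, and
        estimate the association matrix."""
        X = _normalize(self.counts, self.normalization, **self.norm_params)
        shrink = self.shrink
        if shrink is None:
            lam = None
            if self.metric == "correlation":
                assoc = associate.sample_correlation(X)
            elif self.metric == "covariance":
                assoc = associate.sample_covariance(X)
            else:
                assoc = associate.proportionality_rho(X)
        else:
            lam = (associate.estimate_shrinkage_intensities(X)
                   if (shrink == "auto") else
                   shrink if isinstance(shrink, ShrinkageIntensities)
                   else ShrinkageIntensities(*shrink))
            if self.metric == "correlation":
                assoc = associate.shrinkage_correlation(X, lam)
            elif self.metric == "covariance":
                assoc = associate.shrinkage_covariance(X, lam)
            else:
                assoc = associate.shrinkage_proportionality(X, lam)
        return AssociationResults(self, X, assoc, lam)


@dataclass
class AssociationResults:
    """Fitted association estimate with diagnostics and downstream hooks."""

    model: MicrobialAssociation
    normalized: NormalizedMatrix
    association: AssociationMatrix
    intensities: ShrinkageIntensities | None

    @property
    def values(self) -> np.ndarray:
        return self.association.values

    @property
    def taxon_ids(self) -> list[str]:
        return self.association.taxon_ids

    @property
    def moments(self) -> MomentSummary:
        """Moments of the off-diagonal association values."""
        return moment_summary(self.association)

    def compare(self, other, metric: str = "frobenius") -> float:
        """Distance to another fitted result or association matrix."""
        if isinstance(other, AssociationResults):
            other = other.association
        return DISTANCES[metric](self.association, other)

    def relevance_network(self, top_k: int = 2000) -> downstream.TaxonNetwork:
        net = downstream.relevance_network(self.association, top_k)
        if self.model.taxonomy is not None:
            net.annotate(self.model.taxonomy)
        return net

    def spectral_clusters(self, k: int | None = None, knn: int = 2,
                          seed: int = 0) -> downstream.ClusterAssignment:
        aff = downstream.spectral_affinity(self.association, knn=knn)
        return downstream.spectral_cluster(aff, k=k, taxon_ids=self.taxon_ids,
                                           seed=seed)

    def hierarchical_clusters(self, k: int = 10) -> downstream.ClusterAssignment:
        return downstream.hierarchical_cluster(self.association, k=k)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.model
        mo = self.moments
        lines = [
            "Microbial association estimate",
            "=" * 46,
            f"{'No. samples:':<28}{m.counts.n_samples}",
            f"{'No. taxa:':<28}{m.counts.n_taxa}",
            f"{'Normalization:':<28}{m.normalization}",
            f"{'Association metric:':<28}{self.association.metric}",
            f"{'Shrinkage:':<28}{'none' if self.intensities is None else 'Schafer-Strimmer'}",
        ]
        if self.intensities is not None:
            lines += [
                f"{'  lambda1 (correlation):':<28}{self.intensities.lambda1:.4f}",
                f"{'  lambda2 (variance):':<28}{self.intensities.lambda2:.4f}",
            ]
        lines += [
            "-" * 46,
            "Off-diagonal association values",
            f"{'  mean:':<28}{mo.mean:.4f}",
            f"{'  variance:':<28}{mo.variance:.4f}",
            f"{'  skewness:':<28}{mo.skewness:.4f}",
            f"{'  kurtosis:':<28}{mo.kurtosis:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_density(self, ax=None, **kw):
        """Density histogram of off-diagonal association values
        (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.association.offdiag(), bins=kw.pop("bins", 60),
                density=True, **kw)
        ax.set_xlabel(f"{self.association.metric} value")
        ax.set_ylabel("density")
        return ax
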