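"""Orchestration of the sample-size consistency experiment.

The experiment crosses normalization methods with association estimators over
a grid of subsample sizes (with replicates), measures every estimate's
distance to a large-sample reference, tracks shrinkage intensities and
moment summaries (including a shuffled-null arm), and optionally writes the
whole bundle as tidy TSV files bound by a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import associate, compare, downstream
from .associate import AssociationMatrix
from .data import CountMatrix, DataError, SubsampleGrid, TaxonomyTable, shuffle_null, subsample
from .normalize import METHODS, normalize
from .synthdata import SimulationResult, SyntheticSpec, simulate_counts

__all__ = ["ExperimentConfig", "ExperimentResult", "run_consistency_experiment",
           "run_downstream", "DownstreamResult"]

log = logging.getLogger("rhoshrink.workflow")

ESTIMATORS = ("cor", "cor-shrink", "rho", "rho-shrink")


def _estimate(est: str, X) -> AssociationMatrix:
    if est == "cor":
        return associate.sample_correlation(X)
    if est == "cor-shrink":
        return associate.shrinkage_correlation(X)
    if est == "rho":
        return associate.proportionality_rho(X)
    if est == "rho-shrink":
        return associate.shrinkage_proportionality(X)
    raise DataError(f"unknown estimator {est!r}")


@dataclass
class ExperimentConfig:
    """Configuration of one consistency experiment.

    ``source`` is either a :class:`CountMatrix` or a :class:`SyntheticSpec`
    (simulated on demand).  Proportionality estimators pair only with clr
    normalization; requesting one without clr in ``normalizations`` is a
    configuration error.
    """

    source: CountMatrix | SyntheticSpec
    grid: SubsampleGrid
    reference_size: int
    normalizations: Sequence[str] = ("clr", "tss")
    estimators: Sequence[str] = ("cor", "cor-shrink")
    top_k: int = 2000
    shuffled_null: bool = True
    distance_metrics: Sequence[str] = ("frobenius",)
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.normalizations:
            if m not in METHODS:
                raise DataError(f"unknown normalization {m!r}")
        for e in self.estimators:
            if e not in ESTIMATORS:
                raise DataError(f"unknown estimator {e!r}; choose from {ESTIMATORS}")
        if any(e.startswith("rho") for e in self.estimators) and \
                "clr" not in self.normalizations:
            raise DataError("rho estimators require clr among the normalizations")
        if self.reference_size < max(self.grid.sizes):
            raise DataError("reference_size must be >= the largest subsample size")
        n_avail = (self.source.n if isinstance(self.source, SyntheticSpec)
                   else self.source.n_samples)
        if self.reference_size > n_avail:
            raise DataError(f"reference_size {self.reference_size} exceeds "
                            f"available n={n_avail}")

    def cells(self) -> list[tuple[str, str]]:
        """Valid (normalization, estimator) combinations."""
        out = []
        for est in self.estimators:
            for nm in self.normalizations:
                if est.startswith("rho") and nm != "clr":
                    continue
                out.append((nm, est))
        return out


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    references: dict          # (norm, est) -> AssociationMatrix
    estimates: dict           # (norm, est, size, rep) -> AssociationMatrix
    distances: pd.DataFrame   # to-reference distances, all metrics
    pairwise_same_size: pd.DataFrame
    intensities: pd.DataFrame
    moments: pd.DataFrame     # observed and shuffled-null arms
    mds: pd.DataFrame
    manifest: dict

    def mean_distance(self, metric: str = "frobenius") -> pd.DataFrame:
        """Mean and sd of the distance-to-reference per (method, size)."""
        d = self.distances[self.distances["metric"] == metric]
        return (d.groupby(["normalization", "estimator", "size"])["value"]
                 .agg(["mean", "std"]).reset_index())


def _base_counts(cfg: ExperimentConfig, rng: np.random.Generator) -> CountMatrix:
    if isinstance(cfg.source, SyntheticSpec):
        sim = simulate_counts(cfg.source, seed=int(rng.integers(2 ** 31)))
        return sim.counts
    return cfg.source


def run_consistency_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full normalization x estimator x sample-size experiment."""
    t0 = time.time()
    root = np.random.default_rng(cfg.seed)
    base = _base_counts(cfg, root)
    cells = cfg.cells()

    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        for sub in ("associations", "distances", "moments"):
            (out_dir / sub).mkdir(parents=True, exist_ok=True)

    # reference: one fixed subsample at reference_size
    ref_idx = root.choice(base.n_samples, size=cfg.reference_size, replace=False)
    ref_cm = CountMatrix(base.values[ref_idx],
                         [base.sample_ids[j] for j in ref_idx],
                         list(base.taxon_ids))
    references, failures = {}, []
    norm_cache: dict[tuple[int, str], object] = {}

    def _norm(cm: CountMatrix, key, method: str):
        if (key, method) not in norm_cache:
            norm_cache[(key, method)] = normalize(cm, method)
        return norm_cache[(key, method)]

    for nm, est in cells:
        references[(nm, est)] = _estimate(est, _norm(ref_cm, "ref", nm))

    grid = SubsampleGrid(cfg.grid.sizes, cfg.grid.replicates,
                         seed=int(root.integers(2 ** 31)))
    null_rng = np.random.default_rng(int(root.integers(2 ** 31)))

    estimates, dist_rows, lam_rows, mom_rows = {}, [], [], []
    for size, rep, sub_cm in subsample(base, grid):
        null_cm = (shuffle_null(sub_cm, int(null_rng.integers(2 ** 31)))
                   if cfg.shuffled_null else None)
        for nm, est in cells:
            label = (nm, est, size, rep)
            try:
                A = _load_cell(out_dir, nm, est, size, rep)
                if A is None:
                    X = _norm(sub_cm, (size, rep), nm)
                    A = _estimate(est, X)
                else:
                    log.info("cell %s loaded from completed run", label)
            except Exception as exc:  # keep going; record the failed cell
                log.warning("cell %s failed: %s", label, exc)
                failures.append({"cell": list(map(str, label)), "error": str(exc)})
                continue
            estimates[label] = A
            if A.intensities is not None:
                lam_rows.append(dict(normalization=nm, estimator=est, size=size,
                                     replicate=rep,
                                     lambda1=A.intensities.lambda1,
                                     lambda2=A.intensities.lambda2))
            for metric in cfg.distance_metrics:
                dist_rows.append(dict(normalization=nm, estimator=est, size=size,
                                      replicate=rep, metric=metric,
                                      value=compare.DISTANCES[metric](
                                          A, references[(nm, est)])))
            mo = compare.moment_summary(A)
            mom_rows.append(dict(normalization=nm, estimator=est, size=size,
                                 replicate=rep, arm="observed", mean=mo.mean,
                                 variance=mo.variance, skewness=mo.skewness,
                                 kurtosis=mo.kurtosis))
            if null_cm is not None:
                try:
                    mo0 = compare.moment_summary(
                        _estimate(est, _norm(null_cm, ("null", size, rep), nm)))
                    mom_rows.append(dict(normalization=nm, estimator=est,
                                         size=size, replicate=rep, arm="shuffled",
                                         mean=mo0.mean, variance=mo0.variance,
                                         skewness=mo0.skewness, kurtosis=mo0.kurtosis))
                except Exception as exc:
                    failures.append({"cell": [nm, est, str(size), str(rep), "null"],
                                     "error": str(exc)})
        # normalized subsample matrices are not reused across sizes
        norm_cache.clear()

    distances = pd.DataFrame(dist_rows)
    intensities = pd.DataFrame(lam_rows)
    moments = pd.DataFrame(mom_rows)

    # same-size pairwise distances (the alternative aggregation)
    pw_rows = []
    for metric in cfg.distance_metrics:
        for nm, est in cells:
            for size in grid.sizes:
                group = {r: estimates[(nm, est, size, r)]
                         for r in range(grid.replicates)
                         if (nm, est, size, r) in estimates}
                if len(group) < 2:
                    continue
                tab = compare.pairwise_distance_table(group, metric)
                pw_rows.append(dict(normalization=nm, estimator=est, size=size,
                                    metric=metric, mean=float(tab["value"].mean()),
                                    std=float(tab["value"].std(ddof=1))))
    pairwise = pd.DataFrame(pw_rows)

    # MDS of all estimates + references under the first metric
    labeled = {f"{nm}-{est}|n={size}|r={rep}": A
               for (nm, est, size, rep), A in estimates.items()}
    labeled.update({f"{nm}-{est}|reference": A for (nm, est), A in references.items()})
    labels = list(labeled)
    D = np.zeros((len(labels), len(labels)))
    fn = compare.DISTANCES[cfg.distance_metrics[0]]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            D[i, j] = D[j, i] = fn(labeled[labels[i]], labeled[labels[j]])
    coords = compare.mds_embed(D, dims=2) if len(labels) >= 2 else np.zeros((len(labels), 2))
    mds = pd.DataFrame({"estimate": labels, "mds1": coords[:, 0], "mds2": coords[:, 1]})

    manifest = {
        "seed": cfg.seed,
        "normalizations": list(cfg.normalizations),
        "estimators": list(cfg.estimators),
        "cells": [list(c) for c in cells],
        "grid": {"sizes": list(grid.sizes), "replicates": grid.replicates,
                 "seed": grid.seed},
        "reference_size": cfg.reference_size,
        "n_estimates": len(estimates),
        "failures": failures,
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = ExperimentResult(cfg, references, estimates, distances, pairwise,
                              intensities, moments, mds, manifest)
    if out_dir:
        _write_bundle(result, out_dir)
    return result


def _cell_paths(out_dir: Path, nm: str, est: str, size, rep) -> tuple[Path, Path]:
    stem = out_dir / "associations" / f"{nm}-{est}_n{size}_r{rep}"
    return stem.with_suffix(".tsv"), stem.with_suffix(".json")


def _load_cell(out_dir: Path | None, nm: str, est: str, size, rep
               ) -> AssociationMatrix | None:
    """Reload a completed grid cell from a previous run, if present."""
    if out_dir is None:
        return None
    tsv, meta_path = _cell_paths(out_dir, nm, est, size, rep)
    if not (tsv.exists() and meta_path.exists()):
        return None
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    meta = json.loads(meta_path.read_text())
    lam = (associate.ShrinkageIntensities(meta["lambda1"], meta["lambda2"])
           if meta.get("lambda1") is not None else None)
    return AssociationMatrix(df.to_numpy(), meta["metric"],
                             list(df.columns), normalization=meta["normalization"],
                             intensities=lam, n=meta["n"])


def _write_bundle(res: ExperimentResult, out_dir: Path) -> None:
    fmt = "%.10g"
    res.distances.to_csv(out_dir / "distances" / "to_reference.tsv", sep="\t",
                         index=False, float_format=fmt)
    res.pairwise_same_size.to_csv(out_dir / "distances" / "same_size.tsv",
                                  sep="\t", index=False, float_format=fmt)
    res.moments.to_csv(out_dir / "moments" / "moments.tsv", sep="\t",
                       index=False, float_format=fmt)
    res.intensities.to_csv(out_dir / "intensities.tsv", sep="\t", index=False,
                           float_format=fmt)
    res.mds.to_csv(out_dir / "mds.tsv", sep="\t", index=False, float_format=fmt)
    for (nm, est, size, rep), A in res.estimates.items():
        tsv, meta_path = _cell_paths(out_dir, nm, est, size, rep)
        A.to_dataframe().to_csv(tsv, sep="\t", float_format=fmt)
        meta_path.write_text(json.dumps({
            "metric": A.metric, "normalization": A.normalization, "n": A.n,
            "lambda1": A.intensities.lambda1 if A.intensities else None,
            "lambda2": A.intensities.lambda2 if A.intensities else None,
        }))
    for (nm, est), A in res.references.items():
        A.to_dataframe().to_csv(out_dir / "associations" / f"{nm}-{est}_reference.tsv",
                                sep="\t", float_format=fmt)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2)


@dataclass
class DownstreamResult:
    clusters: dict            # (norm, est, size, rep, method) -> ClusterAssignment
    purity: pd.DataFrame
    network_stats: pd.DataFrame
    consensus: downstream.TaxonNetwork | None
    overlap: pd.DataFrame | None


def run_downstream(res: ExperimentResult, taxonomy: TaxonomyTable | None = None,
                   which: Sequence[str] = ("spectral", "hierarchical",
                                           "network", "consensus"),
                   top_k: int | None = None, hier_k: int = 10,
                   purity_rank: str = "family",
                   assort_rank: str = "genus") -> DownstreamResult:
    """Clustering, relevance networks and the consensus network over the
    estimates of a consistency experiment."""
    which = set(which)
    if which & {"spectral", "hierarchical"} and taxonomy is None:
        raise DataError("clustering purity requires a taxonomy table")
    if "network" in which and taxonomy is None:
        raise DataError("network assortativity requires a taxonomy table")
    top_k = top_k or res.config.top_k
    all_items = {(*k,): v for k, v in res.estimates.items()}
    all_items.update({(nm, est, "reference", 0): A
                      for (nm, est), A in res.references.items()})

    clusters, purity_rows, net_rows = {}, [], []
    ref_nets = {}
    for (nm, est, size, rep), A in all_items.items():
        if "spectral" in which:
            aff = downstream.spectral_affinity(A)
            ca = downstream.spectral_cluster(aff, taxon_ids=A.taxon_ids,
                                             seed=res.config.seed)
            per, mean_p = downstream.cluster_purity(ca, taxonomy, purity_rank)
            clusters[(nm, est, size, rep, "spectral")] = ca
            purity_rows.append(dict(normalization=nm, estimator=est, size=size,
                                    replicate=rep, method="spectral", k=ca.k,
                                    mean_purity=mean_p))
        if "hierarchical" in which:
            ca = downstream.hierarchical_cluster(A, k=min(hier_k, A.p))
            per, mean_p = downstream.cluster_purity(ca, taxonomy, purity_rank)
            clusters[(nm, est, size, rep, "hierarchical")] = ca
            purity_rows.append(dict(normalization=nm, estimator=est, size=size,
                                    replicate=rep, method="hierarchical", k=ca.k,
                                    mean_purity=mean_p))
        if "network" in which or "consensus" in which:
            kk = min(top_k, A.p * (A.p - 1) // 2)
            net = downstream.relevance_network(A, top_k=kk)
            if size == "reference":
                ref_nets[f"{nm}-{est}"] = net
            if "network" in which:
                _, q = downstream.modularity_communities(net)
                net_rows.append(dict(
                    normalization=nm, estimator=est, size=size, replicate=rep,
                    assortativity=downstream.assortativity_categorical(
                        net, taxonomy, assort_rank),
                    modularity=q, n_edges=net.graph.number_of_edges()))

    consensus = overlap = None
    if "consensus" in which and ref_nets:
        consensus, overlap = downstream.consensus_network(ref_nets)
    return DownstreamResult(clusters, pd.DataFrame(purity_rows),
                            pd.DataFrame(net_rows), consensus, overlap)
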