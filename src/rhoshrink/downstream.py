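"""Downstream analysis of association matrices: taxon clustering with
taxonomy-based purity, and relevance / consensus networks with community
statistics (assortativity, modularity)."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .associate import AssociationMatrix
from .data import DataError, TaxonomyTable, UNCLASSIFIED

__all__ = [
    "ClusterAssignment",
    "TaxonNetwork",
    "spectral_affinity",
    "spectral_cluster",
    "hierarchical_cluster",
    "cluster_purity",
    "relevance_network",
    "assortativity_categorical",
    "modularity_communities",
    "consensus_network",
]


@dataclass
class ClusterAssignment:
    """Taxon -> cluster label mapping with method metadata."""

    labels: pd.Series  # index taxon_id, values int labels
    method: str
    k: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k = int(self.labels.nunique())

    def members(self) -> dict[int, list[str]]:
        return {int(c): list(idx) for c, idx in self.labels.groupby(self.labels).groups.items()}


@dataclass
class TaxonNetwork:
    """Undirected weighted taxon graph (relevance or consensus network)."""

    graph: nx.Graph
    taxon_ids: list[str]

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def annotate(self, tax: TaxonomyTable) -> None:
        for rank in tax.table.columns:
            lab = tax.labels(list(self.graph.nodes), rank)
            nx.set_node_attributes(self.graph, lab.to_dict(), rank)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _assoc_values(R) -> tuple[np.ndarray, list[str]]:
    if isinstance(R, AssociationMatrix):
        return R.values, list(R.taxon_ids)
    a = np.asarray(R, dtype=float)
    return a, [f"T{i}" for i in range(a.shape[0])]


def spectral_affinity(R, knn: int = 2, mutual: bool = False,
                      tol: float = 1e-8) -> np.ndarray:
    """Affinity A = 1 - sqrt((1 - R)/2), sparsified to a symmetric k-nearest
    neighbor graph (union rule by default: an edge survives if either
    endpoint ranks the other within its k nearest)."""
    a, _ = _assoc_values(R)
    if np.any(np.abs(a) > 1 + tol):
        raise DataError("association entries outside [-1, 1]")
    aff = 1.0 - np.sqrt(np.clip((1.0 - a) / 2.0, 0.0, 1.0))
    np.fill_diagonal(aff, 0.0)
    p = aff.shape[0]
    knn = min(int(knn), p - 1)
    keep = np.zeros_like(aff, dtype=bool)
    order = np.argsort(-aff, axis=1)
    for j in range(p):
        nbrs = [i for i in order[j] if i != j][:knn]
        keep[j, nbrs] = True
    keep = (keep & keep.T) if mutual else (keep | keep.T)
    out = np.where(keep, aff, 0.0)
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


def _components(aff: np.ndarray) -> tuple[int, np.ndarray]:
    ncomp, labels = connected_components((aff > 0).astype(int), directed=False)
    return int(ncomp), labels


def spectral_cluster(A, k: int | None = None, taxon_ids: Sequence[str] | None = None,
                     seed: int = 0, n_init: int = 25,
                     normalize_rows: bool = False) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering of an affinity matrix.

    Eigenvectors of the ``k`` smallest eigenvalues of the symmetric
    normalized Laplacian L = I - D^{-1/2} A D^{-1/2} are clustered with
    seeded k-means.  When ``k`` is None it is set to the number of connected
    components of the affinity graph.  Zero-degree nodes become singleton
    clusters.  Spectral-gap diagnostics are attached.
    """
    from sklearn.cluster import KMeans

    aff = np.asarray(A, dtype=float)
    p = aff.shape[0]
    if taxon_ids is None:
        taxon_ids = [f"T{i}" for i in range(p)]
    ncomp, comp_labels = _components(aff)
    if k is None:
        k = ncomp
    if not 1 <= k <= p:
        raise DataError(f"k={k} outside [1, {p}]")
    deg = aff.sum(axis=1)
    isolated = np.where(deg == 0)[0]
    active = np.where(deg > 0)[0]
    labels = np.full(p, -1, dtype=int)
    k_eff = max(k - len(isolated), 1) if len(active) else 0
    eigvals = np.array([])
    if len(active):
        sub = aff[np.ix_(active, active)]
        dsub = sub.sum(axis=1)
        dinv = 1.0 / np.sqrt(dsub)
        lap = np.eye(len(active)) - dinv[:, None] * sub * dinv[None, :]
        vals, vecs = np.linalg.eigh(lap)
        eigvals = vals
        k_eff = min(k_eff, len(active))
        emb = vecs[:, :k_eff]
        if normalize_rows:
            norms = np.linalg.norm(emb, axis=1, keepdims=True)
            emb = emb / np.where(norms > 0, norms, 1.0)
        km = KMeans(n_clusters=k_eff, n_init=n_init, random_state=seed).fit(emb)
        labels[active] = km.labels_
    next_label = labels.max() + 1
    for i in isolated:
        labels[i] = next_label
        next_label += 1
    gaps = np.diff(eigvals) if eigvals.size else np.array([])
    return ClusterAssignment(
        pd.Series(labels, index=list(taxon_ids)), "spectral", int(len(set(labels))),
        diagnostics={
            "eigenvalues": eigvals, "spectral_gaps": gaps,
            "n_components": ncomp, "component_labels": comp_labels,
            "n_isolated": int(len(isolated)),
        },
    )


def hierarchical_cluster(R, k: int = 10) -> ClusterAssignment:
    """Ward hierarchical clustering of A_h = sqrt((1 - R)/2), cut into k
    flat clusters."""
    a, taxa = _assoc_values(R)
    p = a.shape[0]
    if k > p:
        raise DataError(f"k={k} exceeds p={p}")
    diss = np.sqrt(np.clip((1.0 - a) / 2.0, 0.0, 1.0))
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(pd.Series(labels, index=taxa), "hierarchical", k,
                             diagnostics={"linkage": Z})


def cluster_purity(assign: ClusterAssignment, tax: TaxonomyTable,
                   rank: str = "family") -> tuple[pd.Series, float]:
    """Taxonomic purity per cluster: exp(Shannon entropy of rank labels)
    divided by the number of distinct labels, plus the unweighted mean."""
    per = {}
    for cluster, taxa in assign.members().items():
        if not taxa:
            raise DataError(f"cluster {cluster} is empty")
        counts = tax.labels(taxa, rank).value_counts().to_numpy(dtype=float)
        freq = counts / counts.sum()
        H = float(-(freq * np.log(freq)).sum())
        per[cluster] = float(np.exp(H) / len(counts))
    series = pd.Series(per).sort_index()
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def relevance_network(R, top_k: int = 2000) -> TaxonNetwork:
    """Graph of the ``top_k`` strongest |association| pairs.

    Pairs are ranked by absolute value; exact ties at the boundary are broken
    deterministically by lexicographic (taxon_a, taxon_b) order.  Edge
    weights keep the signed association value.
    """
    a, taxa = _assoc_values(R)
    p = a.shape[0]
    npairs = p * (p - 1) // 2
    if not 1 <= top_k <= npairs:
        raise DataError(f"top_k={top_k} outside [1, {npairs}]")
    iu, ju = np.triu_indices(p, k=1)
    pairs = sorted(
        zip(iu, ju),
        key=lambda ij: (-abs(a[ij[0], ij[1]]), taxa[ij[0]], taxa[ij[1]]),
    )[:top_k]
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for i, j in pairs:
        w = float(a[i, j])
        g.add_edge(taxa[i], taxa[j], weight=w, sign=1 if w >= 0 else -1)
    return TaxonNetwork(g, taxa)


def assortativity_categorical(net: TaxonNetwork, tax: TaxonomyTable | None = None,
                              rank: str = "genus") -> float:
    """Newman categorical assortativity of a taxonomic rank over the edges.

    Returns NaN for an edgeless graph.  Unlabeled taxa count as their own
    'unclassified' category.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        return float("nan")
    if tax is not None:
        labels = tax.labels(list(g.nodes), rank).to_dict()
    else:
        labels = {v: g.nodes[v].get(rank, UNCLASSIFIED) for v in g.nodes}
    gg = g.copy()
    nx.set_node_attributes(gg, labels, rank)
    return float(nx.attribute_assortativity_coefficient(gg, rank))


def modularity_communities(net: TaxonNetwork, weighted: bool = False
                           ) -> tuple[pd.Series, float]:
    """Fast-greedy modularity maximization on the (by default unweighted)
    network skeleton; returns the module assignment and its modularity Q."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise DataError("modularity undefined for an empty graph")
    sub = nx.Graph()
    sub.add_nodes_from(n for n in g.nodes if g.degree(n) > 0)
    for u, v, d in g.edges(data=True):
        sub.add_edge(u, v, weight=abs(d.get("weight", 1.0)) if weighted else 1.0)
    comms = nx.community.greedy_modularity_communities(sub, weight="weight" if weighted else None)
    q = nx.community.modularity(sub, comms, weight="weight" if weighted else None)
    assign = {}
    for mod, members in enumerate(comms):
        for v in members:
            assign[v] = mod
    return pd.Series(assign).sort_index(), float(q)


def consensus_network(nets: Sequence[TaxonNetwork] | Mapping[str, TaxonNetwork]
                      ) -> tuple[TaxonNetwork, pd.DataFrame]:
    """Edge intersection across networks plus the full overlap (Venn) table.

    The overlap table has one row per non-empty subset of the input networks
    with the count of edges present in exactly that subset; per-network
    unique edges are the singleton rows.
    """
    if isinstance(nets, Mapping):
        names, nets = list(nets.keys()), list(nets.values())
    else:
        nets = list(nets)
        names = [f"net{i}" for i in range(len(nets))]
    if not nets:
        raise DataError("consensus_network needs at least one network")
    universes = [set(n.taxon_ids) for n in nets]
    if len(nets) > 1 and not set.intersection(*universes):
        raise DataError("networks have disjoint taxon universes")
    edge_sets = [n.edges for n in nets]
    consensus = set.intersection(*edge_sets)
    all_edges = set.union(*edge_sets)
    membership = {
        e: tuple(name for name, es in zip(names, edge_sets) if e in es)
        for e in all_edges
    }
    rows = []
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            count = sum(1 for m in membership.values() if m == subset)
            rows.append({"networks": subset, "exclusive_edges": count})
    table = pd.DataFrame(rows)
    union_taxa = sorted(set.union(*universes))
    g = nx.Graph()
    g.add_nodes_from(union_taxa)
    ref = nets[0].graph
    for u, v in sorted(consensus):
        data = ref.get_edge_data(u, v, default={})
        g.add_edge(u, v, **data)
    return TaxonNetwork(g, union_taxa), table
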