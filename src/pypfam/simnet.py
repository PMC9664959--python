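"""Sequence-similarity networks and Markov clustering (MCL).

Builds the unweighted similarity network from filtered all-vs-all hits
(coverage >= 80% on both sequences and E-value <= 0.05 by default), clusters
it with a from-scratch Markov cluster algorithm, summarizes the result as a
cluster graph whose node sizes are log10 of cluster membership and whose
edge weights are observed inter-cluster directed hits divided by all possible
mutual hits (2*|A|*|B|), and sweeps the inflation parameter.

MCL here follows the standard recipe: self-loops of weight 1 are added for
aperiodicity, columns are normalized to a stochastic matrix, and the process
alternates expansion (matrix power), inflation (entrywise power with column
renormalization), and pruning of tiny entries until the iterate stops
changing. Higher inflation gives finer granularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .align import AlignmentResult

#: A similarity hit is simply a filtered directed alignment result.
SimilarityHit = AlignmentResult


@dataclass
class Network:
    """Unweighted similarity network plus the surviving directed hits."""

    nodes: list[str]
    edges: set[frozenset]
    directed_hits: list[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
            if not e <= node_set:
                raise ValueError(f"edge endpoint outside node set: {set(e)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class MclParams:
    inflation: float = 1.4
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation < 1.0:
            raise ValueError("inflation must be >= 1.0")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if not 0 <= self.prune_threshold < 1:
            raise ValueError("prune_threshold must be a small probability")


@dataclass
class Clustering:
    """A partition of network nodes; cluster ids run 1..k by decreasing size."""

    assignment: dict[str, int]
    converged: bool
    n_iterations: int
    max_colsum_error: float  # worst |column sum - 1| seen after normalizations

    @property
    def n_clusters(self) -> int:
        return max(self.assignment.values()) if self.assignment else 0

    def members(self, cluster_id: int) -> list[str]:
        return [n for n, c in self.assignment.items() if c == cluster_id]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return dict(sorted(out.items()))


@dataclass
class ClusterGraph:
    """Summary graph over clusters with the display conventions used for
    similarity-network figures: node display size log10(cluster size), edge
    weight = observed directed inter-cluster hits / (2*|A|*|B|)."""

    sizes: dict[int, int]
    display_sizes: dict[int, float]
    weights: dict[frozenset, float]


# --------------------------------------------------------------------------
# Network construction
# --------------------------------------------------------------------------


def filter_hits(
    hits,
    min_coverage: float = 0.8,
    max_evalue: float = 0.05,
) -> list[SimilarityHit]:
    """Keep hits with BOTH coverages >= ``min_coverage`` and E-value <=
    ``max_evalue``; self-hits are dropped."""
    kept = []
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if (
            h.query_coverage >= min_coverage
            and h.subject_coverage >= min_coverage
            and h.e_value <= max_evalue
        ):
            kept.append(h)
    return kept


def build_network(hits, nodes=None) -> Network:
    """Undirected network with an edge for every pair hit in either direction.

    ``nodes`` may supply the full node universe (sequences without any
    surviving hit become isolated nodes); hit endpoints are always included.
    """
    node_list: list[str] = list(nodes) if nodes is not None else []
    seen = set(node_list)
    edges: set[frozenset] = set()
    directed: list[tuple[str, str]] = []
    for h in hits:
        for nid in (h.query_id, h.subject_id):
            if nid not in seen:
                seen.add(nid)
                node_list.append(nid)
        directed.append((h.query_id, h.subject_id))
        edges.add(frozenset((h.query_id, h.subject_id)))
    return Network(nodes=node_list, edges=edges, directed_hits=directed)


# --------------------------------------------------------------------------
# Markov clustering
# --------------------------------------------------------------------------


def _normalize_columns(M: np.ndarray) -> float:
    sums = M.sum(axis=0)
    nz = sums > 0
    M[:, nz] /= sums[nz]
    check = M.sum(axis=0)[nz]
    return float(np.max(np.abs(check - 1.0))) if nz.any() else 0.0


def _clusters_from_matrix(M: np.ndarray, eps: float) -> list[set[int]]:
    n = M.shape[0]
    diag = np.diag(M)
    attractors = [i for i in range(n) if diag[i] > eps]
    if not attractors:
        # fully degenerate iterate: every node on its own
        return [{i} for i in range(n)]
    # attractor systems: connected components of attractors linked by support
    g = nx.Graph()
    g.add_nodes_from(attractors)
    aset = set(attractors)
    for i in attractors:
        for k in np.nonzero(M[i] > eps)[0]:
            if int(k) in aset and int(k) != i:
                g.add_edge(i, int(k))
        for k in np.nonzero(M[:, i] > eps)[0]:
            if int(k) in aset and int(k) != i:
                g.add_edge(i, int(k))
    systems = [sorted(c) for c in nx.connected_components(g)]
    systems.sort(key=lambda c: c[0])
    # attract every node to the systems whose attractor rows give it support
    prelim: list[set[int]] = [set(c) for c in systems]
    attracted_by: dict[int, list[int]] = {}
    for si, system in enumerate(systems):
        for i in system:
            for j in np.nonzero(M[i] > eps)[0]:
                attracted_by.setdefault(int(j), [])
                if si not in attracted_by[int(j)]:
                    attracted_by[int(j)].append(si)
    for j, sis in attracted_by.items():
        if len(sis) == 1:
            prelim[sis[0]].add(j)
    # overlapping nodes go to the largest candidate cluster (tie: the one
    # whose smallest member index is lowest, i.e. the lowest cluster id)
    order = sorted(
        range(len(prelim)), key=lambda si: (-len(prelim[si]), min(prelim[si]))
    )
    rank = {si: r for r, si in enumerate(order)}
    for j, sis in attracted_by.items():
        if len(sis) > 1:
            prelim[min(sis, key=lambda si: rank[si])].add(j)
    assigned = set().union(*prelim) if prelim else set()
    for i in range(n):
        if i not in assigned:
            prelim.append({i})
    return prelim


def mcl(network: Network, params: MclParams | None = None) -> Clustering:
    """Markov clustering of an unweighted network.

    Returns a :class:`Clustering`; cluster ids are assigned 1..k by
    decreasing size (ties broken by smallest node index in input order).
    Non-convergence within ``max_iter`` raises a warning and flags the result.
    """
    params = params or MclParams()
    if network.n_nodes == 0:
        raise ValueError("empty network")
    n = network.n_nodes
    index = {nid: i for i, nid in enumerate(network.nodes)}
    M = np.zeros((n, n), dtype=np.float64)
    for e in network.edges:
        a, b = tuple(e)
        M[index[a], index[b]] = 1.0
        M[index[b], index[a]] = 1.0
    np.fill_diagonal(M, 1.0)  # self-loops for aperiodicity
    colsum_err = _normalize_columns(M)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        prev = M.copy()
        M = np.linalg.matrix_power(M, params.expansion)
        np.power(M, params.inflation, out=M)
        colsum_err = max(colsum_err, _normalize_columns(M))
        if params.prune_threshold > 0:
            M[M < params.prune_threshold] = 0.0
            colsum_err = max(colsum_err, _normalize_columns(M))
        if np.max(np.abs(M - prev)) < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iter} iterations "
            f"(inflation={params.inflation}); clustering the current iterate",
            stacklevel=2,
        )
    clusters = _clusters_from_matrix(M, max(params.prune_threshold, 1e-9))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    assignment = {}
    for cid, members in enumerate(clusters, start=1):
        for i in members:
            assignment[network.nodes[i]] = cid
    return Clustering(
        assignment=assignment,
        converged=converged,
        n_iterations=it,
        max_colsum_error=colsum_err,
    )


def cluster_graph(clustering: Clustering, network: Network) -> ClusterGraph:
    """Summarize a clustering over its network.

    Edge weight between clusters A != B is the number of surviving directed
    hits with one endpoint in each, divided by the number of all possible
    mutual hits, 2*|A|*|B| (ordered pairs in both directions).
    """
    missing = [n for n in network.nodes if n not in clustering.assignment]
    if missing:
        raise ValueError(f"clustering does not cover nodes: {missing[:5]}")
    sizes = clustering.sizes()
    inter: dict[frozenset, int] = {}
    for q, s in network.directed_hits:
        ca, cb = clustering.assignment[q], clustering.assignment[s]
        if ca != cb:
            key = frozenset((ca, cb))
            inter[key] = inter.get(key, 0) + 1
    weights = {
        key: count / (2 * sizes[tuple(key)[0]] * sizes[tuple(key)[1]])
        for key, count in inter.items()
    }
    display = {cid: float(np.log10(sz)) for cid, sz in sizes.items()}
    return ClusterGraph(sizes=sizes, display_sizes=display, weights=weights)


def scan_inflation(
    network: Network,
    values,
    base_params: MclParams | None = None,
) -> pd.DataFrame:
    """Cluster the network at each inflation value.

    Returns a table with one row per value: inflation, n_clusters,
    largest_cluster_fraction, converged. Inflation 1.0 is permitted; it makes
    the inflation step a no-op, so it typically fails to converge or collapses
    everything and comes back flagged.
    """
    params = base_params or MclParams()
    rows = []
    for inflation in values:
        p = MclParams(
            inflation=float(inflation),
            expansion=params.expansion,
            prune_threshold=params.prune_threshold,
            max_iter=params.max_iter,
            tol=params.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clustering = mcl(network, p)
        sizes = clustering.sizes()
        rows.append(
            {
                "inflation": float(inflation),
                "n_clusters": clustering.n_clusters,
                "largest_cluster_fraction": max(sizes.values()) / network.n_nodes,
                "converged": clustering.converged,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Synthetic benchmark graphs
# --------------------------------------------------------------------------


def planted_partition_network(
    sizes,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[Network, dict[str, int]]:
    """Planted-partition random graph as a :class:`Network` plus ground truth.

    Nodes are named ``b{block}_{i}``; within-block pairs are joined with
    probability ``p_in`` and between-block pairs with ``p_out``. Every edge
    contributes both directed hits.
    """
    rng = np.random.default_rng(seed)
    nodes = []
    labels: dict[str, int] = {}
    for b, size in enumerate(sizes):
        for i in range(size):
            nid = f"b{b}_{i}"
            nodes.append(nid)
            labels[nid] = b
    edges: set[frozenset] = set()
    directed: list[tuple[str, str]] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_in if labels[nodes[i]] == labels[nodes[j]] else p_out
            if rng.random() < p:
                edges.add(frozenset((nodes[i], nodes[j])))
                directed.append((nodes[i], nodes[j]))
                directed.append((nodes[j], nodes[i]))
    return Network(nodes=nodes, edges=edges, directed_hits=directed), labels


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------


def write_network(network: Network, edge_path) -> None:
    """Edge list as two-column TSV (sorted for reproducibility)."""
    rows = sorted(tuple(sorted(e)) for e in network.edges)
    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def write_clustering(clustering: Clustering, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_id\n")
        for nid, cid in sorted(clustering.assignment.items()):
            fh.write(f"{nid}\t{cid}\n")


def write_cluster_graph(cg: ClusterGraph, node_path, edge_path) -> None:
    with open(node_path, "w") as fh:
        fh.write("cluster_id\tsize\tdisplay_size\n")
        for cid in sorted(cg.sizes):
            fh.write(f"{cid}\t{cg.sizes[cid]}\t{cg.display_sizes[cid]:.6f}\n")
    with open(edge_path, "w") as fh:
        fh.write("cluster_a\tcluster_b\tweight\n")
        for key in sorted(cg.weights, key=lambda k: tuple(sorted(k))):
            a, b = sorted(key)
            fh.write(f"{a}\t{b}\t{cg.weights[key]:.6f}\n")
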