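"""Cross-species similarity graphs and Markov clustering of ortholog groups.

Edges are reciprocal similarity hits weighted by −log10 of the e-value
(capped at 200, averaged over the two directions). Markov clustering (MCL)
iterates expansion (matrix squaring) and inflation (elementwise power with
column renormalization) on the column-stochastic transition matrix until a
fixed point; attractor components are the clusters. Within a reported
cluster, cross-species pairs are orthologs and same-species pairs
co-orthologs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io import BlastHit

WEIGHT_CAP = 200.0
EVALUE_FLOOR = 1e-200
DEFAULT_MIN_CLUSTER = 4  # report clusters of at least four genes


def build_similarity_graph(
    hits: Iterable[BlastHit],
    species_map: Mapping[str, str],
    evalue_cutoff: float = 1e-5,
    reciprocal: bool = True,
) -> nx.Graph:
    """Weighted undirected similarity graph from all-vs-all protein hits.

    An edge is kept iff the hit passes the e-value cutoff and (when
    ``reciprocal``) the reverse hit passes too; its weight is
    −log10(max(e, 1e-200)) averaged over the two directions. Nodes carry a
    ``species`` attribute from ``species_map``.
    """
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query == h.subject or h.evalue > evalue_cutoff:
            continue
        key = (h.query, h.subject)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    graph = nx.Graph()
    for (q, s), e in best.items():
        rev = best.get((s, q))
        if reciprocal and rev is None:
            continue
        if graph.has_edge(q, s):
            continue
        w_fwd = _weight(e)
        w = (w_fwd + _weight(rev)) / 2.0 if rev is not None else w_fwd
        graph.add_edge(q, s, weight=w)
    for node in graph.nodes:
        graph.nodes[node]["species"] = species_map.get(node, "unknown")
    return graph


def _weight(evalue: float) -> float:
    return min(-np.log10(max(evalue, EVALUE_FLOOR)), WEIGHT_CAP)


@dataclass
class OrthologClusters:
    """MCL output: all clusters, plus the size-filtered set used for orthology."""

    clusters: list[list[str]]
    min_size: int = DEFAULT_MIN_CLUSTER
    species: dict[str, str] = field(default_factory=dict)

    @property
    def reported(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) >= self.min_size]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 200,
    prune: float = 1e-8,
    min_size: int = DEFAULT_MIN_CLUSTER,
) -> OrthologClusters:
    """Markov clustering of a weighted similarity graph.

    Self-loops are added with the node's maximum incident weight (1 for
    isolated nodes) before column normalization. Entries below ``prune`` are
    zeroed each iteration for numerical stability. Clusters are the connected
    components of the converged (attractor) matrix.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return OrthologClusters([], min_size)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[index[u], index[v]] = m[index[v], index[u]] = w
    loop = m.max(axis=0)
    loop[loop <= 0] = 1.0
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        col = inflated.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        inflated /= col
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations")

    attractor = nx.Graph()
    attractor.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > tol)
    attractor.add_edges_from(zip(rows, cols))
    clusters = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(attractor)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    species = {v: graph.nodes[v].get("species", "unknown") for v in nodes}
    return OrthologClusters(clusters, min_size, species)


def classify_pairs(
    clusters: OrthologClusters,
    species_map: Mapping[str, str] | None = None,
) -> list[tuple[str, str, str]]:
    """All within-cluster pairs of reported clusters, classed as ``ortholog``
    (cross-species) or ``co-ortholog`` (same species)."""
    species = dict(clusters.species)
    if species_map:
        species.update(species_map)
    pairs = []
    for cluster in clusters.reported:
        for a, b in itertools.combinations(sorted(cluster), 2):
            cls = "ortholog" if species.get(a) != species.get(b) else "co-ortholog"
            pairs.append((a, b, cls))
    return pairs


def pair_counts(pairs: Sequence[tuple[str, str, str]]) -> dict[str, int]:
    return {
        "ortholog": sum(1 for p in pairs if p[2] == "ortholog"),
        "co-ortholog": sum(1 for p in pairs if p[2] == "co-ortholog"),
    }


def write_clusters(clusters: OrthologClusters, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#cluster\tsize\treported\tmembers\n")
        for i, c in enumerate(clusters.clusters, 1):
            fh.write(f"{i}\t{len(c)}\t{int(len(c) >= clusters.min_size)}\t{','.join(c)}\n")


def write_network(
    graph: nx.Graph, pairs: Sequence[tuple[str, str, str]], path: str | Path
) -> None:
    """Edge list (source, target, weight, class) for generic graph viewers."""
    cls = {frozenset((a, b)): c for a, b, c in pairs}
    with open(path, "w") as fh:
        fh.write("#source\ttarget\tweight\tclass\n")
        for u, v, data in graph.edges(data=True):
            c = cls.get(frozenset((u, v)), "unclustered")
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.3f}\t{c}\n")
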