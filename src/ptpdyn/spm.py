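"""Shortest-path-map (SPM) allosteric networks.

Residues become nodes of a contact-gated graph: an edge joins residues i, j
when their mean Calpha-Calpha distance is below a contact cutoff (default
6 A) and their motions are correlated, with weight w_ij = -log|C_ij| so
strongly (anti-)correlated contacts are cheap to traverse.  The absolute
correlation feeds the weight because anti-correlated pairs still carry
communication; the sign is kept as edge metadata.

The SPM itself scores every edge by how many all-pairs shortest paths traverse
it.  When several equal-length shortest paths exist between a pair, *all* of
them are counted (a path-counting Dijkstra variant), which removes any
dependence on node iteration order and makes edge usage deterministic.  Edges
whose normalized usage reaches a threshold form the map; residues incident to
those edges are the SPM residues.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptpdyn.correlation import CorrelationMap
from ptpdyn.sequences import AlignmentMap


@dataclass(frozen=True)
class Edge:
    i: int
    j: int
    weight: float
    distance: float
    correlation: float = 0.0


@dataclass
class ResidueGraph:
    """Undirected weighted residue graph (no self-edges)."""

    nodes: list[int]
    edges: list[Edge]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.i == e.j:
                raise ValueError(f"self-edge on residue {e.i}")
            if not math.isfinite(e.weight) or e.weight < 0:
                raise ValueError(f"edge {e.i}-{e.j}: weight must be finite and >= 0")
            key = (min(e.i, e.j), max(e.i, e.j))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {n: [] for n in self.nodes}
        for e in self.edges:
            adj[e.i].append((e.j, e.weight))
            adj[e.j].append((e.i, e.weight))
        return adj


@dataclass
class SPMResult:
    graph: ResidueGraph
    edge_usage: dict[tuple[int, int], float]  # normalized to max 1
    spm_edges: list[tuple[int, int]]
    spm_residues: set[int]
    usage_threshold: float = 0.3

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        spm = set(self.spm_edges)
        for e in self.graph.edges:
            key = (min(e.i, e.j), max(e.i, e.j))
            rows.append(
                (e.i, e.j, e.weight, self.edge_usage.get(key, 0.0), key in spm)
            )
        return pd.DataFrame(rows, columns=["res_i", "res_j", "weight", "usage", "in_spm"])


def build_graph(
    dccm: CorrelationMap,
    mean_distances: np.ndarray,
    contact_cutoff: float = 6.0,
) -> ResidueGraph:
    """Contact-gated correlation graph.

    An edge (i, j) exists iff the mean Calpha distance is below
    ``contact_cutoff`` and C_ij is nonzero; its weight is -log|C_ij|.  Contact
    pairs with exactly zero correlation would carry infinite weight and are
    omitted (logged as a warning).
    """
    mean_distances = np.asarray(mean_distances, float)
    n = len(dccm.residue_ids)
    if mean_distances.shape != (n, n):
        raise ValueError("distance matrix must share the DCCM residue ordering")
    nodes = [int(r) for r in dccm.residue_ids]
    edges: list[Edge] = []
    dropped = 0
    for a in range(n):
        for b in range(a + 1, n):
            if mean_distances[a, b] >= contact_cutoff:
                continue
            c = float(dccm.matrix[a, b])
            if c == 0.0:
                dropped += 1
                continue
            edges.append(
                Edge(nodes[a], nodes[b], -math.log(abs(c)), float(mean_distances[a, b]), c)
            )
    if dropped:
        warnings.warn(
            f"{dropped} contact pair(s) with zero correlation omitted (infinite weight)",
            stacklevel=2,
        )
    return ResidueGraph(nodes, edges)


def _dijkstra_with_counts(
    adj: dict[int, list[tuple[int, float]]],
    source: int,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
) -> tuple[dict[int, float], dict[int, float]]:
    """Single-source shortest distances and shortest-path counts.

    Counts are accumulated over *all* shortest paths: when a relaxation ties
    the best known distance (within tolerance), path counts add instead of
    replacing.
    """
    dist = {source: 0.0}
    sigma = {source: 1.0}
    settled: set[int] = set()
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        for v, w in adj[u]:
            if v in settled:
                continue
            nd = d + w
            old = dist.get(v)
            if old is None or nd < old - max(abs_tol, rel_tol * max(old, nd)):
                dist[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - old) <= max(abs_tol, rel_tol * max(abs(old), abs(nd))):
                sigma[v] += sigma[u]
    return dist, sigma


def shortest_path_map(graph: ResidueGraph, usage_threshold: float = 0.3) -> SPMResult:
    """All-pairs shortest-path edge usage, pruned at a usage threshold.

    For every unordered node pair (s, t), every shortest s-t path contributes
    one count to each edge it traverses; the number of shortest s-t paths
    through edge (u, v) is sigma_s(u) * sigma_t(v) whenever
    d(s,u) + w(u,v) + d(v,t) = d(s,t).  Disconnected components are processed
    independently (unreachable pairs contribute nothing).  Edge counts are
    normalized by the maximum count; edges at or above ``usage_threshold``
    form the SPM.
    """
    nodes = list(graph.nodes)
    if not nodes or not graph.edges:
        return SPMResult(graph, {}, [], set(), usage_threshold)
    index = {n: k for k, n in enumerate(nodes)}
    nn = len(nodes)
    adj = graph.adjacency()
    dist = np.full((nn, nn), np.inf)
    sigma = np.zeros((nn, nn))
    for s in nodes:
        d, sg = _dijkstra_with_counts(adj, s)
        si = index[s]
        for v, dv in d.items():
            dist[si, index[v]] = dv
            sigma[si, index[v]] = sg[v]
    # unordered pairs s < t (by node index), both reachable, s != t
    pair_mask = np.triu(np.isfinite(dist), k=1)
    tol = np.maximum(1e-12, 1e-9 * np.maximum(np.abs(dist), 1.0))
    counts: dict[tuple[int, int], float] = {}
    for e in graph.edges:
        u, v = index[e.i], index[e.j]
        total = 0.0
        for a, b in ((u, v), (v, u)):
            # paths s -> t using the edge in direction a -> b; inf - inf for
            # unreachable pairs yields NaN, which never satisfies <= tol
            through = dist[:, a][:, None] + e.weight + dist[b][None, :]
            with np.errstate(invalid="ignore"):
                on_path = np.abs(through - dist) <= tol
            contrib = sigma[:, a][:, None] * sigma[b][None, :]
            total += contrib[on_path & pair_mask].sum()
        counts[(min(e.i, e.j), max(e.i, e.j))] = total
    max_count = max(counts.values())
    if max_count <= 0:
        return SPMResult(graph, {k: 0.0 for k in counts}, [], set(), usage_threshold)
    usage = {k: c / max_count for k, c in counts.items()}
    spm_edges = sorted(k for k, u in usage.items() if u >= usage_threshold)
    spm_residues = {r for pair in spm_edges for r in pair}
    return SPMResult(graph, usage, spm_edges, spm_residues, usage_threshold)


@dataclass
class ConservationReport:
    conserved: int
    size: int
    fraction: float
    unmapped: list[int]


def spm_conservation(
    spm_a: SPMResult,
    spm_b: SPMResult,
    alignment_map: AlignmentMap,
) -> dict[str, ConservationReport]:
    """SPM residue conservation between two proteins, both directions.

    A residue of SPM-A is conserved when its alignment partner is an SPM
    residue of B.  Residues without a partner count as non-conserved and are
    listed.  The measure is asymmetric, so the B-to-A direction is reported
    as well (using the reversed map).
    """

    def one_way(res_a: set[int], res_b: set[int], mapping: dict[int, int]) -> ConservationReport:
        unmapped = sorted(r for r in res_a if r not in mapping)
        conserved = sum(1 for r in res_a if mapping.get(r) in res_b)
        size = len(res_a)
        return ConservationReport(
            conserved, size, conserved / size if size else 0.0, unmapped
        )

    return {
        "a_to_b": one_way(spm_a.spm_residues, spm_b.spm_residues, alignment_map.a_to_b()),
        "b_to_a": one_way(spm_b.spm_residues, spm_a.spm_residues, alignment_map.b_to_a()),
    }


def mean_ca_distance_matrix(ensemble, residue_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Mean Calpha-Calpha distance matrix over frames (graph gating input)."""
    ca = ensemble.ca_indices()
    rids = ensemble.atoms["res_id"].to_numpy()[ca]
    if residue_ids is not None:
        wanted = set(int(r) for r in residue_ids)
        keep = np.array([int(r) in wanted for r in rids])
        ca, rids = ca[keep], rids[keep]
    coords = ensemble.coords[:, ca]
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    d = np.linalg.norm(diff, axis=3).mean(axis=0)
    return d, rids
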