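"""Degree census, mean degrees and geodesic (shortest-path) analysis.

The degree census records, separately for every interaction site, the number
of trajectory frames N(i) in which the site carries exactly i hydrogen-bond
edges.  Because the two hydrogens of a water count separately, a water
presenting both hydrogens to one site contributes degree two; the weighted
mean degree can be halved to convert to a per-water-molecule count.

Geodesic distances (number of edges in the shortest contiguous hydrogen-bond
path between two vertices) are computed per frame with the Floyd-Warshall
algorithm on the unweighted adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError
from .graphs import FrameGraph, SiteVertex

__all__ = [
    "DegreeCensus", "GeodesicMatrix", "GeodesicRun",
    "degree_census", "weighted_mean_degree", "geodesic_matrix",
    "geodesic_persistence", "write_geopath",
]

#: Sentinel for an unreachable vertex pair in a geodesic matrix.
UNREACHABLE = -1


@dataclass
class DegreeCensus:
    """Per-site histogram ``{site label: {degree i: frame count N(i)}}``."""

    counts: dict[str, dict[int, int]]
    total_frames: int

    def n(self, site: str, degree: int) -> int:
        return self.counts[site].get(degree, 0)

    def validate(self) -> None:
        for site, hist in self.counts.items():
            if sum(hist.values()) != self.total_frames:
                raise AnalysisError(
                    f"census conservation violated for site {site!r}")
            if any(i < 0 for i in hist):
                raise AnalysisError(f"negative degree for site {site!r}")


def degree_census(graphs: Sequence[FrameGraph],
                  sites: Iterable[str]) -> DegreeCensus:
    """Tally per-frame raw degrees of the named sites over a graph sequence."""
    sites = list(sites)
    counts: dict[str, dict[int, int]] = {s: {} for s in sites}
    vertex_of: dict[str, SiteVertex] = {}
    if graphs:
        for s in sites:
            vertex_of[s] = graphs[0].find_site(s)  # raises on unknown label
    for g in graphs:
        deg = g.degrees()
        for s in sites:
            d = deg.get(vertex_of[s], 0)
            counts[s][d] = counts[s].get(d, 0) + 1
    return DegreeCensus(counts, total_frames=len(graphs))


def weighted_mean_degree(census: DegreeCensus,
                         halve: bool = False) -> dict[str, float]:
    """Per-site mean degree sum_i i*N(i) / sum_i N(i), optionally divided by two.

    Halving converts the hydrogen-resolved count (each water hydrogen counted
    separately) to a per-water-molecule degree.
    """
    if census.total_frames == 0:
        raise AnalysisError("mean degree undefined for an empty census")
    out = {}
    for site, hist in census.counts.items():
        total = sum(hist.values())
        if total == 0:
            raise AnalysisError(f"no observations for site {site!r}")
        mean = sum(i * n for i, n in hist.items()) / total
        out[site] = mean / 2.0 if halve else mean
    return out


# ---------------------------------------------------------------------------
# Geodesics

@dataclass
class GeodesicMatrix:
    """All-pairs shortest edge counts of one frame graph.

    ``dist[i, j]`` is the geodesic distance between ``vertices[i]`` and
    ``vertices[j]`` (0 on the diagonal), or :data:`UNREACHABLE`.  ``pred``
    holds the predecessor of ``j`` on the canonical shortest path from ``i``
    (the path kept is deterministic; among equal-length paths an arbitrary
    but reproducible one is chosen).
    """

    vertices: list[SiteVertex]
    dist: np.ndarray
    pred: np.ndarray
    frame_index: int = 0
    _index: dict[SiteVertex, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.vertices)}

    def distance(self, u: SiteVertex, v: SiteVertex) -> int:
        return int(self.dist[self._index[u], self._index[v]])

    def path(self, u: SiteVertex, v: SiteVertex) -> list[SiteVertex]:
        """One canonical shortest path from u to v (inclusive); [] if unreachable."""
        i, j = self._index[u], self._index[v]
        if self.dist[i, j] == UNREACHABLE:
            return []
        seq = [j]
        while seq[-1] != i:
            seq.append(int(self.pred[i, seq[-1]]))
        return [self.vertices[k] for k in reversed(seq)]

    def finite_pairs(self) -> Iterable[tuple[SiteVertex, SiteVertex, int]]:
        """Unordered vertex pairs (u < v in index order) with finite distance."""
        n = len(self.vertices)
        for i in range(n):
            for j in range(i + 1, n):
                d = int(self.dist[i, j])
                if d != UNREACHABLE:
                    yield self.vertices[i], self.vertices[j], d


def geodesic_matrix(graph: FrameGraph) -> GeodesicMatrix:
    """All-pairs geodesic distances via Floyd-Warshall on the adjacency matrix.

    Updates are strict improvements with intermediates scanned in ascending
    vertex order, which makes the predecessor matrix, and hence the one
    reconstructed path per pair, deterministic.
    """
    verts = list(graph.vertices)
    index = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    pred = np.full((n, n), -1, dtype=np.int64)
    for e in graph.edges:
        i, j = index[e.u], index[e.v]
        if dist[i, j] > 1:
            dist[i, j] = dist[j, i] = 1.0
            pred[i, j] = i
            pred[j, i] = j
    for k in range(n):
        via = dist[:, k, None] + dist[None, k, :]
        better = via < dist
        if better.any():
            dist[better] = via[better]
            pred[better] = np.broadcast_to(pred[k, :], (n, n))[better]
    out = np.where(np.isinf(dist), UNREACHABLE, dist).astype(np.int64)
    return GeodesicMatrix(verts, out, pred, frame_index=graph.frame_index,
                          _index=index)


def _bfs_distance(graph: FrameGraph, source: SiteVertex,
                  target: SiteVertex) -> int:
    """Geodesic distance between two vertices by breadth-first search."""
    if source == target:
        return 0
    adj = graph.adjacency()
    seen = {source}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for w in adj.get(u, ()):
                if w in seen:
                    continue
                if w == target:
                    return d
                seen.add(w)
                nxt.append(w)
        frontier = nxt
    return UNREACHABLE


@dataclass
class GeodesicRun:
    """A maximal run of frames over which gd(u, v) is constant and finite."""

    gd: int
    start_frame: int
    length: int
    duration: float  # ps


def geodesic_persistence(graphs: Sequence[FrameGraph], u_label: str,
                         v_label: str, frame_interval: float = 0.5
                         ) -> tuple[np.ndarray, list[GeodesicRun]]:
    """Per-frame geodesic distance between two sites, plus its constant runs.

    Returns the gd time series (UNREACHABLE where disconnected) and the list
    of maximal runs of constant finite gd with durations in ps.
    """
    if not graphs:
        return np.empty(0, dtype=np.int64), []
    u = graphs[0].find_site(u_label)
    v = graphs[0].find_site(v_label)
    series = np.array([_bfs_distance(g, u, v) for g in graphs], dtype=np.int64)
    runs: list[GeodesicRun] = []
    start = 0
    for t in range(1, len(series) + 1):
        if t == len(series) or series[t] != series[start]:
            if series[start] != UNREACHABLE:
                runs.append(GeodesicRun(int(series[start]), start, t - start,
                                        (t - start) * frame_interval))
            start = t
    return series, runs


def write_geopath(matrix: GeodesicMatrix, path: str | Path) -> None:
    """Write one record per finite-distance vertex pair: endpoints, geodesic
    distance, and the vertex sequence of one canonical shortest path."""
    lines = ["# solvgraph geodesic paths: u gd v : path"]
    for u, v, d in matrix.finite_pairs():
        if u == v:
            continue
        seq = " -> ".join(f"{w.mol}:{w.site}:{w.serial}" for w in matrix.path(u, v))
        lines.append(f"{u.mol}:{u.site}:{u.serial} {d} "
                     f"{v.mol}:{v.site}:{v.serial} : {seq}")
    Path(path).write_text("\n".join(lines) + "\n")
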