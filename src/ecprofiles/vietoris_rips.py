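"""Distributed Euler characteristic contributions for Vietoris-Rips complexes.

The Vietoris-Rips complex on a pointcloud contains every vertex subset whose
diameter (longest pairwise distance) is at most a threshold, filtered by that
diameter.  Because it is a flag complex, listing its simplices amounts to
enumerating cliques of the threshold-neighborhood graph.  The engine here
does this *exactly once per simplex* and without materializing the complex:
fix a vertex ordering; for each vertex build the local graph of its
*subsequent* neighbors (neighbors later in the ordering); every clique of that
local graph containing the vertex is a simplex whose minimal vertex it is.
Each per-vertex task is independent and side-effect-free, so the work
distributes trivially across workers and the aggregated result is invariant
to scheduling and to the ordering strategy.

The filtration convention exposed to the user is the simplex *diameter*: the
threshold bounds the longest edge, and a simplex enters the filtration at its
diameter (0 for vertices).  This sidesteps the radius-versus-diameter factor
of two that haunts Vietoris-Rips parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .contributions import Contribution, EulerCurve, EulerProfile, aggregate, build_curve

__all__ = [
    "LocalGraph",
    "order_vertices",
    "build_local_graph",
    "local_contributions",
    "ecc_vr",
    "vr_multiparameter",
    "codensity",
]


@dataclass
class LocalGraph:
    """The unit of parallel work: a center vertex, its subsequent neighbors
    (original indices, in ordering position), and all pairwise distances among
    ``{center} | neighbors`` (row/column 0 is the center)."""

    center: int
    neighbors: np.ndarray  # original point indices, ordered by position in the ordering
    distances: np.ndarray  # (k+1, k+1) symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=np.intp)
        self.distances = np.asarray(self.distances, dtype=float)
        k = self.neighbors.size
        if self.distances.shape != (k + 1, k + 1):
            raise ValueError("distance matrix must cover center plus neighbors")


def _pairwise(points: np.ndarray, metric: Callable | str = "euclidean") -> np.ndarray:
    if callable(metric):
        n = len(points)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = metric(points[i], points[j])
        return d
    return cdist(points, points, metric=metric)


def order_vertices(
    points: np.ndarray,
    threshold: float,
    strategy: str = "given",
    metric: Callable | str = "euclidean",
) -> np.ndarray:
    """Choose the vertex ordering used for "subsequent neighbor" enumeration.

    ``given`` keeps the input order.  ``ascending_degree`` sorts by the number
    of neighbors within the threshold (ties broken by original index), which
    evens out the sizes of the per-vertex simplex trees: a hub processed early
    would own almost every simplex it touches.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if strategy == "given":
        return np.arange(n, dtype=np.intp)
    if strategy != "ascending_degree":
        raise ValueError(f"unknown ordering strategy: {strategy!r}")
    dist = _pairwise(points, metric)
    degrees = ((dist <= threshold).sum(axis=1) - 1).astype(np.intp)  # exclude self
    return np.lexsort((np.arange(n), degrees)).astype(np.intp)


def build_local_graph(
    points: np.ndarray,
    ordering: np.ndarray,
    i: int,
    threshold: float,
    metric: Callable | str = "euclidean",
) -> LocalGraph:
    """Local graph of the vertex at ordering position ``i``: the subsequent
    points within ``threshold`` of it, plus their pairwise distances."""
    points = np.asarray(points, dtype=float)
    ordering = np.asarray(ordering, dtype=np.intp)
    center = int(ordering[i])
    later = ordering[i + 1:]
    if later.size:
        if callable(metric):
            d_center = np.array([metric(points[center], points[j]) for j in later])
        else:
            d_center = cdist(points[[center]], points[later], metric=metric)[0]
        nbrs = later[d_center <= threshold]
    else:
        nbrs = np.empty(0, dtype=np.intp)
    members = np.concatenate([[center], nbrs]).astype(np.intp)
    dist = _pairwise(points[members], metric)
    np.fill_diagonal(dist, 0.0)
    return LocalGraph(center=center, neighbors=nbrs, distances=dist)


def local_contributions(
    g: LocalGraph,
    threshold: float,
    vertex_values: np.ndarray | None = None,
    extension_rule: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[Contribution]:
    """All contributions of simplices whose minimal vertex is ``g.center``.

    Breadth-first expansion: start from the singleton (filtration 0,
    extendables = all local neighbors); extend each simplex by one extendable
    vertex, updating the filtration to the new diameter and intersecting the
    extendables with the new vertex's subsequent in-threshold neighbors; stop
    when nothing extends.  With ``vertex_values`` given, each simplex also
    carries the rule-extended vertex values (default: coordinate-wise max) and
    the contribution location becomes ``(diameter, *extended values)``.
    """
    k = g.neighbors.size
    dist = g.distances
    multi = vertex_values is not None
    if multi:
        vv = np.asarray(vertex_values, dtype=float)
        if vv.ndim == 1:
            vv = vv[:, None]
        local_vv = vv[np.concatenate([[g.center], g.neighbors]).astype(np.intp)]
        rule = extension_rule or (lambda vals: vals.max(axis=0))

    def emit(local_idx: tuple[int, ...], filtration: float) -> Contribution:
        dim = len(local_idx) - 1
        delta = 1 if dim % 2 == 0 else -1
        if not multi:
            return ((filtration,), delta)
        ext = np.asarray(rule(local_vv[list(local_idx)]), dtype=float)
        # monotonicity: the simplex value may not fall below any vertex's value
        if np.any(ext + 1e-12 < local_vv[list(local_idx)]):
            raise ValueError(
                "extension rule is not monotone: simplex value below a face's value"
            )
        return ((filtration, *map(float, ext)), delta)

    out: list[Contribution] = [emit((0,), 0.0)]
    # frontier entries: (vertex tuple in local indices, filtration, extendables)
    root_ext = [j for j in range(1, k + 1) if dist[0, j] <= threshold]
    frontier = [((0,), 0.0, root_ext)]
    while frontier:
        nxt = []
        for verts, filt, ext in frontier:
            for pos, v in enumerate(ext):
                new_filt = max(filt, float(dist[v, list(verts)].max()))
                new_ext = [
                    w for w in ext[pos + 1:] if dist[v, w] <= threshold
                ]
                new_verts = verts + (v,)
                out.append(emit(new_verts, new_filt))
                if new_ext:
                    nxt.append((new_verts, new_filt, new_ext))
        frontier = nxt
    return out


def _vertex_task(points, ordering, i, threshold, metric, vertex_values, extension_rule):
    g = build_local_graph(points, ordering, i, threshold, metric)
    return local_contributions(g, threshold, vertex_values, extension_rule)


def _all_contributions(
    points: np.ndarray,
    threshold: float,
    workers: int = 1,
    strategy: str = "given",
    metric: Callable | str = "euclidean",
    vertex_values: np.ndarray | None = None,
    extension_rule: Callable | None = None,
) -> list[Contribution]:
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n == 0:
        return []
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    ordering = order_vertices(points, threshold, strategy, metric)
    if workers == 1:
        chunks = [
            _vertex_task(points, ordering, i, threshold, metric, vertex_values, extension_rule)
            for i in range(n)
        ]
    else:
        chunks = Parallel(n_jobs=workers)(
            delayed(_vertex_task)(
                points, ordering, i, threshold, metric, vertex_values, extension_rule
            )
            for i in range(n)
        )
    return [c for chunk in chunks for c in chunk]


def ecc_vr(
    points: np.ndarray,
    threshold: float,
    workers: int = 1,
    strategy: str = "given",
    metric: Callable | str = "euclidean",
) -> EulerCurve:
    """Euler characteristic curve of the Vietoris-Rips complex with simplex
    diameter at most ``threshold``.  The result is independent of the worker
    count and of the ordering strategy."""
    raw = _all_contributions(points, threshold, workers, strategy, metric)
    return build_curve(raw)


def vr_contributions(
    points: np.ndarray,
    threshold: float,
    workers: int = 1,
    strategy: str = "given",
    metric: Callable | str = "euclidean",
    aggregated: bool = True,
) -> list[Contribution]:
    """Contribution list of the Vietoris-Rips complex.

    With ``aggregated=False`` the raw per-simplex list is returned (one entry
    per simplex, delta in {-1, +1}), so its length is the simplex count.
    """
    raw = _all_contributions(points, threshold, workers, strategy, metric)
    return aggregate(raw) if aggregated else raw


def vr_multiparameter(
    points: np.ndarray,
    threshold: float,
    vertex_values: np.ndarray,
    extension_rule: Callable[[np.ndarray], np.ndarray] | None = None,
    workers: int = 1,
    strategy: str = "given",
    metric: Callable | str = "euclidean",
) -> EulerProfile:
    """Multiparameter profile of a bifiltered (or higher) Vietoris-Rips
    complex: axis 0 is the simplex diameter, the remaining axes come from
    per-vertex values extended to simplices by ``extension_rule`` (default
    coordinate-wise max, which keeps the filtration monotone)."""
    vv = np.asarray(vertex_values, dtype=float)
    if vv.ndim == 1:
        vv = vv[:, None]
    if len(vv) != len(np.atleast_2d(points)):
        raise ValueError("vertex_values must have one row per point")
    raw = _all_contributions(
        points, threshold, workers, strategy, metric, vertex_values=vv,
        extension_rule=extension_rule,
    )
    return EulerProfile.from_contributions(raw)


def codensity(points: np.ndarray, k: int = 10) -> np.ndarray:
    """Codensity filtration value per point: the mean Euclidean distance to
    the k nearest neighbors (excluding the point itself).  Dense regions get
    low values, so sublevel sets grow from dense to sparse."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if k < 1:
        raise ValueError("k must be positive")
    if len(points) <= k:
        raise ValueError(f"codensity with k={k} needs more than {k} points")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dists, _ = nn.kneighbors(points)
    return dists[:, 1:].mean(axis=1)
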