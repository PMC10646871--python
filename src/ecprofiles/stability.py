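"""Empirical test bench for the stability of Euler characteristic summaries.

Betti curves built from persistence diagrams are 1-Wasserstein stable: the L1
distance between the Betti curves of two diagrams is at most twice the
1-Wasserstein distance between the diagrams (sum of l-infinity matching
costs, with unmatched points sent to their nearest diagonal projection).
This module provides the three ingredients needed to check that bound — and
the analogous truncated-profile perturbation bound — by direct computation on
random instances: Betti curves from diagrams, an exact small-scale
1-Wasserstein distance, and the bound evaluators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .contributions import EulerCurve, EulerProfile, build_curve
from .distances import distance_curves, distance_profiles

__all__ = [
    "PersistenceDiagram",
    "betti_curve",
    "wasserstein1",
    "check_betti_stability",
    "check_ecp_perturbation",
    "stability_sweep",
]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Finite multiset of (birth, death) pairs with birth <= death; points on
    the diagonal are implicit with infinite multiplicity."""

    points: np.ndarray
    dimension: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if np.any(pts[:, 0] > pts[:, 1]):
            raise ValueError("every diagram point needs birth <= death")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])


def betti_curve(diagram: PersistenceDiagram) -> EulerCurve:
    """Betti curve of a diagram: the sum of half-open indicators [b, d)."""
    contribs = []
    for b, d in diagram.points:
        if d > b:  # diagonal points contribute nothing
            contribs.append(((float(b),), 1))
            contribs.append(((float(d),), -1))
    return build_curve(contribs)


def _diagonal_cost(points: np.ndarray) -> np.ndarray:
    # l-infinity distance to the nearest diagonal projection ((b+d)/2, (b+d)/2)
    return (points[:, 1] - points[:, 0]) / 2.0


def wasserstein1(a: PersistenceDiagram, b: PersistenceDiagram) -> float:
    """Exact 1-Wasserstein distance between two finite diagrams.

    Solved as a linear assignment on the diagonal-augmented cost matrix: each
    diagram is padded with one potential diagonal partner per point of the
    other, so every matching of the augmented problem corresponds to a partial
    matching with unmatched points paying their diagonal projection cost.
    """
    pa, pb = a.points, b.points
    na, nb = len(pa), len(pb)
    if na == 0 and nb == 0:
        return 0.0
    size = na + nb
    cost = np.zeros((size, size))
    if na and nb:
        cost[:na, :nb] = np.max(
            np.abs(pa[:, None, :] - pb[None, :, :]), axis=2
        )
    cost[:na, nb:] = _diagonal_cost(pa)[:, None]
    cost[na:, :nb] = _diagonal_cost(pb)[None, :]
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def check_betti_stability(
    a: PersistenceDiagram, b: PersistenceDiagram
) -> tuple[float, float]:
    """(lhs, rhs) of the Betti-curve stability bound: lhs is the L1 distance
    between the Betti curves, rhs twice the 1-Wasserstein distance."""
    lhs = distance_curves(betti_curve(a), betti_curve(b))
    rhs = 2.0 * wasserstein1(a, b)
    return lhs, rhs


def check_ecp_perturbation(
    locations: np.ndarray,
    deltas: np.ndarray,
    epsilon: float,
    f_inf: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(lhs, rhs) of the truncated-profile perturbation bound.

    ``locations``/``deltas`` describe the raw cells of a profile (one row per
    cell, delta +-1).  Each cell's location is shifted by at most ``epsilon``
    in l-infinity norm (clamped to [0, f_inf]); lhs is the L1 profile distance
    on the [0, f_inf]^n box and rhs the bound
    ``cell_count * n * epsilon**(n-1) * f_inf``.
    """
    locations = np.asarray(locations, dtype=float)
    deltas = np.asarray(deltas, dtype=np.int64)
    n_cells, n = locations.shape
    shift = rng.uniform(-epsilon, epsilon, size=locations.shape)
    perturbed = np.clip(locations + shift, 0.0, f_inf)
    base = EulerProfile.from_contributions(zip(map(tuple, locations), deltas))
    pert = EulerProfile.from_contributions(zip(map(tuple, perturbed), deltas))
    # aggregation can cancel cells; pad arity if everything cancelled
    if base.arity != n:
        base = EulerProfile(np.empty((0, n)), np.empty(0, dtype=np.int64))
    if pert.arity != n:
        pert = EulerProfile(np.empty((0, n)), np.empty(0, dtype=np.int64))
    lhs = distance_profiles(base, pert, truncation=(f_inf,) * n)
    rhs = n_cells * n * epsilon ** (n - 1) * f_inf
    return lhs, rhs


def stability_sweep(
    pairs: int = 500,
    max_points: int = 6,
    seed: int = 0,
    birth_range: tuple[float, float] = (0.0, 5.0),
    persistence_range: tuple[float, float] = (0.0, 5.0),
) -> dict:
    """Monte-Carlo check of the Betti-curve stability bound over random
    diagram pairs.  Returns the per-pair maximum ratio lhs / W1 and whether
    every pair satisfied lhs <= 2 * W1 (up to 1e-9)."""
    from .fixtures import random_diagram

    rng = np.random.default_rng(seed)
    max_ratio = 0.0
    violations = 0
    for _ in range(pairs):
        na, nb = rng.integers(0, max_points + 1, size=2)
        seeds = rng.integers(0, 2**31 - 1, size=2)
        a = random_diagram(int(na), birth_range, persistence_range, int(seeds[0]))
        b = random_diagram(int(nb), birth_range, persistence_range, int(seeds[1]))
        lhs, rhs = check_betti_stability(a, b)
        if lhs > rhs + 1e-9:
            violations += 1
        w1 = rhs / 2.0
        if w1 > 0:
            max_ratio = max(max_ratio, lhs / w1)
    return {"pairs": pairs, "max_ratio": max_ratio, "violations": violations}
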