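"""L1 distances between Euler characteristic curves and profiles.

The distance between two curves is the integral of the absolute difference of
the two step functions.  It is computed exactly by merging the two jump lists
(signs flipped on the second curve) and summing ``|EC(f_i)| * (f_{i+1}-f_i)``
over the merged breakpoints — note the absolute value: without it the sum
telescopes to a signed area rather than the L1 norm.  The distance is finite
only when the curves eventually coincide; otherwise an explicit integration
bound must be supplied.

For n-parameter profiles the merged, sign-flipped contribution list induces an
irregular grid with at most (N+1) breakpoints per axis; the Euler
characteristic is constant inside each cuboid and equal to its value at the
lower corner, so the distance is the sum of |EC| times cuboid volume.
Profiles must be truncated per axis to keep every cuboid volume finite.
Integration starts at the smallest merged breakpoint per axis (the difference
is zero below it).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .contributions import EulerCurve, EulerProfile

__all__ = ["distance_curves", "distance_profiles"]


def distance_curves(a: EulerCurve, b: EulerCurve, upper: float | None = None) -> float:
    """Exact L1 distance between two Euler characteristic curves.

    If ``upper`` is given, integration is truncated at ``upper``; otherwise
    the curves must agree from their last jump onward (same terminal value),
    or the distance is infinite and a ValueError is raised.
    """
    if len(a) == 0 and len(b) == 0:
        return 0.0
    jumps = np.concatenate([a.jumps, b.jumps])
    deltas = np.concatenate([a.deltas, -b.deltas]).astype(np.int64)
    order = np.argsort(jumps, kind="stable")
    jumps, deltas = jumps[order], deltas[order]
    if upper is not None:
        keep = jumps <= upper
        jumps, deltas = jumps[keep], deltas[keep]
        if jumps.size == 0:
            return 0.0
        bounds = np.append(jumps, upper)
    else:
        final_a = int(a.values[-1]) if len(a) else 0
        final_b = int(b.values[-1]) if len(b) else 0
        if final_a != final_b:
            raise ValueError(
                "curves do not eventually coincide; the L1 distance is "
                "unbounded — pass an explicit integration upper bound"
            )
        bounds = np.append(jumps, jumps[-1])
    diff = np.cumsum(deltas)  # EC difference on [jumps[i], bounds[i+1])
    widths = np.diff(bounds)
    return float(np.sum(np.abs(diff) * widths))


def distance_profiles(
    a: EulerProfile, b: EulerProfile, truncation: Sequence[float]
) -> float:
    """Exact L1 distance between two n-parameter profiles on the truncation
    box.  Cost is O(prod_i N_i) for N_i merged breakpoints per axis via a
    scatter-and-prefix-sum over the irregular grid."""
    if truncation is None:
        raise ValueError(
            "profiles must be truncated per axis: cuboid volumes are "
            "otherwise infinite"
        )
    if a.arity != b.arity:
        raise ValueError(f"profile arity mismatch: {a.arity} vs {b.arity}")
    trunc = np.asarray(truncation, dtype=float)
    if trunc.shape != (a.arity,):
        raise ValueError(f"truncation must have arity {a.arity}")

    locs = np.concatenate([a.locations, b.locations], axis=0)
    deltas = np.concatenate([a.deltas, -b.deltas]).astype(np.int64)
    if locs.shape[0] == 0:
        return 0.0
    # contributions at or beyond the truncation along any axis never intersect
    # the integration box
    inside = np.all(locs < trunc, axis=1)
    locs, deltas = locs[inside], deltas[inside]
    if locs.shape[0] == 0:
        return 0.0

    axes = [np.unique(locs[:, i]) for i in range(locs.shape[1])]
    widths = [np.diff(np.append(ax, t)) for ax, t in zip(axes, trunc)]
    grid = np.zeros([ax.size for ax in axes], dtype=np.int64)
    idx = tuple(
        np.searchsorted(ax, locs[:, i]) for i, ax in enumerate(axes)
    )
    np.add.at(grid, idx, deltas)
    for axis in range(grid.ndim):
        np.cumsum(grid, axis=axis, out=grid)
    vol = np.abs(grid).astype(float)
    for axis, w in enumerate(widths):
        shape = [1] * grid.ndim
        shape[axis] = w.size
        vol *= w.reshape(shape)
    return float(vol.sum())
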