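"""Contributions of cells entering a multifiltration at several points.

In a 1-critical filtration each cell has a unique minimal entry point and
contributes ``(-1)**dim`` on the cone above it.  In the general multicritical
case a cell enters at a finite antichain ``p_1, ..., p_k`` of pairwise
incomparable points, and its contribution must equal ``(-1)**dim`` on the
*union* of the cones above the ``p_i`` — the cones overlap, so naive summation
would multiply-count.  The correcting contributions are supported on joins
(coordinate-wise maxima) of subsets of entry points; they are found by
seeding ``(-1)**dim`` at each entry point and then sweeping the join lattice
in a linear extension of the product order, adding a correction wherever the
accumulated value deviates from the target indicator.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .contributions import Contribution

__all__ = ["join", "is_antichain", "cell_contributions"]


def join(p: Sequence[float], q: Sequence[float]) -> tuple[float, ...]:
    """Coordinate-wise maximum of two equal-arity tuples."""
    if len(p) != len(q):
        raise ValueError(f"arity mismatch: {len(p)} vs {len(q)}")
    return tuple(max(float(a), float(b)) for a, b in zip(p, q))


def _leq(p: Sequence[float], q: Sequence[float]) -> bool:
    return all(a <= b for a, b in zip(p, q))


def is_antichain(points: Sequence[Sequence[float]]) -> bool:
    """True when the points are pairwise incomparable in the product order."""
    for a, b in combinations(points, 2):
        if _leq(a, b) or _leq(b, a):
            return False
    return True


def cell_contributions(
    dim: int, entry_points: Sequence[Sequence[float]]
) -> list[Contribution]:
    """Contribution list of a single ``dim``-cell with multicritical entry set.

    The returned contributions, accumulated below any query point x, sum to
    ``(-1)**dim`` exactly when x dominates some entry point and to 0 otherwise.
    Entry points must form an antichain; comparable inputs are rejected so
    that filtration bugs surface at the caller.
    """
    pts = [tuple(float(x) for x in p) for p in entry_points]
    if not pts:
        raise ValueError("at least one entry point is required")
    arity = len(pts[0])
    if any(len(p) != arity for p in pts):
        raise ValueError("entry points must share one arity")
    if not is_antichain(pts):
        raise ValueError(
            "entry points must be pairwise incomparable; reduce comparable "
            "inputs to the minimal antichain first"
        )
    sign = 1 if dim % 2 == 0 else -1
    if len(pts) == 1:
        return [(pts[0], sign)]

    # Candidate support: joins of all non-empty subsets of entry points,
    # swept in a linear extension of the product order (sum, then lex).
    candidates = set()
    for r in range(1, len(pts) + 1):
        for sub in combinations(pts, r):
            j = sub[0]
            for q in sub[1:]:
                j = join(j, q)
            candidates.add(j)
    ordered = sorted(candidates, key=lambda c: (sum(c), c))

    out: dict[tuple[float, ...], int] = {}
    for c in ordered:
        target = sign if any(_leq(p, c) for p in pts) else 0
        current = sum(d for loc, d in out.items() if _leq(loc, c))
        if current != target:
            out[c] = out.get(c, 0) + (target - current)
    return sorted((loc, d) for loc, d in out.items() if d != 0)
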