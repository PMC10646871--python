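"""Deliberately naive reference implementations used only for testing.

These oracles materialize entire filtered complexes by exhaustive enumeration
and share no code with the engines, so engine-versus-oracle equality is a
genuinely independent check.  They are exponential-time and guarded against
anything but tiny inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .contributions import Contribution, EulerCurve, EulerProfile, aggregate, build_curve

__all__ = ["FullComplex", "brute_vr", "brute_cubical", "complex_to_curve"]


@dataclass
class FullComplex:
    """Explicit cell list: (identifier, dimension, filtration tuple)."""

    cells: list[tuple[tuple, int, tuple[float, ...]]]

    def __len__(self) -> int:
        return len(self.cells)


def brute_vr(points: np.ndarray, threshold: float) -> FullComplex:
    """Every vertex subset with diameter <= threshold, filtered by diameter."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n > 15:
        raise ValueError("brute-force enumeration is limited to 15 points")
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    cells = []
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            if k == 1:
                diam = 0.0
            else:
                diam = max(dist[i, j] for i, j in combinations(subset, 2))
            if diam <= threshold:
                cells.append((subset, k - 1, (float(diam),)))
    return FullComplex(cells)


def brute_vr_multiparameter(
    points: np.ndarray, threshold: float, vertex_values: np.ndarray
) -> FullComplex:
    """Subset enumeration with (diameter, coordinate-wise max of vertex
    values) filtrations, the default bifiltration extension."""
    vv = np.asarray(vertex_values, dtype=float)
    if vv.ndim == 1:
        vv = vv[:, None]
    base = brute_vr(points, threshold)
    cells = []
    for subset, dim, (diam,) in base.cells:
        ext = vv[list(subset)].max(axis=0)
        cells.append((subset, dim, (diam, *map(float, ext))))
    return FullComplex(cells)


def brute_cubical(image: np.ndarray, channels: int | None = None) -> FullComplex:
    """Every elementary cube of the doubled grid of an image, each filtered at
    the (coordinate-wise) min over the voxels containing it."""
    arr = np.asarray(image, dtype=float)
    if channels is None:
        arr = arr[..., None]
    shape = arr.shape[:-1]
    if int(np.prod([2 * m + 1 for m in shape])) > 200_000:
        raise ValueError("brute-force cubical oracle is limited to small images")
    cells = []
    for coords in product(*(range(2 * m + 1) for m in shape)):
        owner_ranges = []
        for c, m in zip(coords, shape):
            if c % 2 == 1:
                owner_ranges.append([(c - 1) // 2])
            else:
                owner_ranges.append(
                    [x for x in ((c // 2) - 1, c // 2) if 0 <= x < m]
                )
        owners = list(product(*owner_ranges))
        filt = np.stack([arr[o] for o in owners]).min(axis=0)
        dim = sum(1 for c in coords if c % 2 == 1)
        cells.append((coords, dim, tuple(map(float, filt))))
    return FullComplex(cells)


def complex_to_curve(c: FullComplex) -> EulerCurve | EulerProfile:
    """Alternating-sum contributions of an explicit complex, aggregated into a
    curve (arity-1 filtrations) or a profile."""
    raw: list[Contribution] = [
        (filt, 1 if dim % 2 == 0 else -1) for _, dim, filt in c.cells
    ]
    if raw and len(raw[0][0]) == 1:
        return build_curve(raw)
    return EulerProfile.from_contributions(raw)


def complex_contributions(c: FullComplex) -> list[Contribution]:
    """Aggregated contribution list of an explicit complex."""
    return aggregate(
        (filt, 1 if dim % 2 == 0 else -1) for _, dim, filt in c.cells
    )
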