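"""Core data model for Euler characteristic curves and profiles.

Every engine in this package reduces a filtered complex to a *contribution
list*: one pair ``(f(cell), (-1)**dim(cell))`` per cell, where ``f(cell)`` is
the (possibly vector-valued) filtration value at which the cell enters the
filtration.  The Euler characteristic of any sublevel set is then the sum of
the deltas of the contributions located at or below the query point, so the
whole curve (one filtration parameter) or profile (several parameters) is
recovered by aggregation and prefix summation.

Locations are grouped under exact floating-point equality: duplicate values
arise from identical arithmetic (the same pairwise distance computed once),
and a tolerance would make aggregation order-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Contribution",
    "EulerCurve",
    "EulerProfile",
    "aggregate",
    "build_curve",
    "ec_at",
    "ecp_at",
    "read_contributions",
    "write_contributions",
]

#: A contribution is a plain ``(location, delta)`` pair where ``location`` is a
#: tuple of filtration values and ``delta`` an integer.  Raw single-cell
#: contributions carry delta in {-1, +1}; aggregated ones carry any integer.
Contribution = tuple[tuple[float, ...], int]


def _check_arity(contribs: Iterable[Contribution]) -> int | None:
    arity = None
    for loc, _ in contribs:
        if arity is None:
            arity = len(loc)
        elif len(loc) != arity:
            raise ValueError(
                f"mixed location arities in contribution list: {len(loc)} != {arity}"
            )
    return arity


def aggregate(raw: Iterable[Contribution]) -> list[Contribution]:
    """Canonicalize a raw contribution list.

    Deltas are summed per exact location, zero-sum locations are dropped, and
    the result is sorted lexicographically by location so that serialized
    output does not depend on worker scheduling.
    """
    raw = list(raw)
    _check_arity(raw)
    acc: dict[tuple[float, ...], int] = {}
    for loc, delta in raw:
        key = tuple(float(x) for x in loc)
        acc[key] = acc.get(key, 0) + int(delta)
    return sorted((loc, d) for loc, d in acc.items() if d != 0)


@dataclass(frozen=True)
class EulerCurve:
    """A 1-parameter Euler characteristic curve as a right-continuous step
    function: ``jumps`` are the strictly increasing filtration values where the
    curve changes and ``values[i]`` the Euler characteristic attained at and
    after ``jumps[i]``.  Before the first jump the complex is empty and the
    curve is 0."""

    jumps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "jumps", np.asarray(self.jumps, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        if self.jumps.shape != self.values.shape or self.jumps.ndim != 1:
            raise ValueError("jumps and values must be 1-d arrays of equal length")
        if self.jumps.size > 1 and not np.all(np.diff(self.jumps) > 0):
            raise ValueError("jumps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.jumps.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EulerCurve):
            return NotImplemented
        return np.array_equal(self.jumps, other.jumps) and np.array_equal(
            self.values, other.values
        )

    @property
    def deltas(self) -> np.ndarray:
        """Per-jump changes of the Euler characteristic (inverse of prefix sum)."""
        return np.diff(self.values, prepend=0)

    def contributions(self) -> list[Contribution]:
        return [((float(f),), int(d)) for f, d in zip(self.jumps, self.deltas)]

    def __call__(self, t: float) -> int:
        return ec_at(self, t)

    def plot(self, ax=None, **kwargs):
        """Step plot of the curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if len(self) > 0:
            span = self.jumps[-1] - self.jumps[0]
            pad = 0.05 * span if span > 0 else 1.0
            xs = np.concatenate([[self.jumps[0] - pad], self.jumps, [self.jumps[-1] + pad]])
            ys = np.concatenate([[0], self.values, [self.values[-1]]])
            ax.step(xs, ys, where="post", **kwargs)
        ax.set_xlabel("filtration")
        ax.set_ylabel("Euler characteristic")
        return ax


@dataclass(frozen=True)
class EulerProfile:
    """An n-parameter Euler characteristic profile stored as an aggregated
    contribution list: ``locations`` is an (N, n) array and ``deltas`` the
    integer changes.  ``truncation`` optionally records the per-axis upper
    bound used when the profile was built (cells beyond it were discarded)."""

    locations: np.ndarray
    deltas: np.ndarray
    truncation: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        locs = np.asarray(self.locations, dtype=float)
        if locs.ndim != 2:
            raise ValueError("locations must be an (N, n) array")
        object.__setattr__(self, "locations", locs)
        object.__setattr__(self, "deltas", np.asarray(self.deltas, dtype=np.int64))
        if self.locations.shape[0] != self.deltas.shape[0]:
            raise ValueError("locations and deltas length mismatch")

    @classmethod
    def from_contributions(
        cls, contribs: Iterable[Contribution], truncation: Sequence[float] | None = None
    ) -> "EulerProfile":
        agg = aggregate(contribs)
        if not agg:
            n = 1 if truncation is None else len(truncation)
            return cls(np.empty((0, n)), np.empty(0, dtype=np.int64),
                       None if truncation is None else tuple(truncation))
        locs = np.array([loc for loc, _ in agg], dtype=float)
        deltas = np.array([d for _, d in agg], dtype=np.int64)
        return cls(locs, deltas, None if truncation is None else tuple(truncation))

    @property
    def arity(self) -> int:
        return int(self.locations.shape[1])

    def __len__(self) -> int:
        return int(self.locations.shape[0])

    def contributions(self) -> list[Contribution]:
        return [(tuple(map(float, loc)), int(d)) for loc, d in zip(self.locations, self.deltas)]

    def __call__(self, p: Sequence[float]) -> int:
        return ecp_at(self, p)

    def plot(self, ax=None, resolution: int = 128, **kwargs):
        """Heatmap of a 2-parameter profile sampled on a regular grid."""
        import matplotlib.pyplot as plt

        if self.arity != 2:
            raise ValueError("plotting is implemented for 2-parameter profiles only")
        if ax is None:
            _, ax = plt.subplots()
        hi = self.truncation if self.truncation is not None else tuple(
            self.locations.max(axis=0)
        )
        lo = self.locations.min(axis=0)
        xs = np.linspace(lo[0], hi[0], resolution)
        ys = np.linspace(lo[1], hi[1], resolution)
        grid = np.empty((resolution, resolution), dtype=np.int64)
        for i, x in enumerate(xs):
            mask_x = self.locations[:, 0] <= x
            for j, y in enumerate(ys):
                grid[j, i] = self.deltas[mask_x & (self.locations[:, 1] <= y)].sum()
        im = ax.imshow(grid, origin="lower", aspect="auto",
                       extent=(lo[0], hi[0], lo[1], hi[1]), **kwargs)
        ax.figure.colorbar(im, ax=ax, label="Euler characteristic")
        return ax


def build_curve(contribs: Iterable[Contribution]) -> EulerCurve:
    """Aggregate arity-1 contributions and prefix-sum them into a curve."""
    agg = aggregate(contribs)
    if agg and len(agg[0][0]) != 1:
        raise ValueError(
            "build_curve requires arity-1 contributions; use EulerProfile for "
            "multiparameter filtrations"
        )
    jumps = np.array([loc[0] for loc, _ in agg], dtype=float)
    values = np.cumsum([d for _, d in agg]).astype(np.int64) if agg else np.empty(0, np.int64)
    return EulerCurve(jumps, values)


def ec_at(curve: EulerCurve, t: float) -> int:
    """Euler characteristic at filtration ``t`` (right-continuous lookup).

    Binary search for the largest jump <= t; 0 if ``t`` precedes every jump.
    """
    idx = int(np.searchsorted(curve.jumps, t, side="right")) - 1
    return 0 if idx < 0 else int(curve.values[idx])


def ecp_at(profile: EulerProfile, p: Sequence[float]) -> int:
    """Euler characteristic of the profile at ``p``: the sum of deltas over
    locations <= p coordinate-wise (linear in the contribution count)."""
    p = np.asarray(p, dtype=float)
    if p.shape != (profile.arity,):
        raise ValueError(f"query arity {p.shape} does not match profile arity {profile.arity}")
    if len(profile) == 0:
        return 0
    mask = np.all(profile.locations <= p, axis=1)
    return int(profile.deltas[mask].sum())


def write_contributions(path, contribs: Iterable[Contribution]) -> None:
    """Serialize a contribution list as CSV with columns f_1..f_n, delta.

    Floats use the shortest round-trip representation, so output is bit-exact
    across platforms.
    """
    contribs = list(contribs)
    arity = _check_arity(contribs) or 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join([f"f_{i + 1}" for i in range(arity)] + ["delta"]) + "\n")
        for loc, delta in contribs:
            fh.write(",".join([repr(float(x)) for x in loc] + [str(int(delta))]) + "\n")


def read_contributions(path) -> list[Contribution]:
    """Read a contribution CSV written by :func:`write_contributions`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "delta" not in df.columns:
        raise ValueError(f"{path}: not a contribution CSV (missing 'delta' column)")
    loc_cols = [c for c in df.columns if c != "delta"]
    return [
        (tuple(float(row[c]) for c in loc_cols), int(row["delta"]))
        for _, row in df.iterrows()
    ]
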