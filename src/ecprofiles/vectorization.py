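"""Fixed-length vector and tensor summaries of curves and profiles.

A curve is vectorized by sampling the Euler characteristic at N evenly spaced
points from 0 to f_max inclusive (resolution ``delta = f_max / (N - 1)``);
right-continuity means a jump exactly at a sample point is included.  The L1
error of the reconstruction (a step function holding each sample for one
resolution step) is bounded by ``delta * (|K|/2 + F)``, with |K| the number of
cells and F the total variation of the sample vector.  No analogous bound
exists for profiles: pairs of cancelling cells between grid nodes can change
the profile on an arbitrarily large region without moving any sample, and two
curves may be L1-close yet have very different vectors (and vice versa) — the
vectorization is a feature map, not an isometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .contributions import (
    EulerCurve,
    EulerProfile,
    build_curve,
    ec_at,
    ecp_at,
)

__all__ = [
    "VectorizedCurve",
    "VectorizedProfile",
    "vectorize_curve",
    "vectorization_bound",
    "vectorize_profile",
    "EulerCurveVectorizer",
]


@dataclass(frozen=True)
class VectorizedCurve:
    """Samples ``EC(i * delta)`` for i = 0..N-1, with ``delta = f_max/(N-1)``."""

    samples: np.ndarray
    f_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.int64))

    @property
    def resolution(self) -> float:
        return self.f_max / (len(self.samples) - 1)

    def as_curve(self) -> EulerCurve:
        """Reconstruct the step function: each sample held on a left-closed,
        right-open interval of one resolution step starting at its node."""
        delta = self.resolution
        contribs = []
        prev = 0
        for i, v in enumerate(self.samples):
            if int(v) != prev:
                contribs.append(((i * delta,), int(v) - prev))
                prev = int(v)
        return build_curve(contribs)


@dataclass(frozen=True)
class VectorizedProfile:
    """Tensor of profile samples on the inclusive regular grid
    ``(i_1 * delta_1, ..., i_n * delta_n)``."""

    tensor: np.ndarray
    maxima: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tensor", np.asarray(self.tensor, dtype=np.int64))

    @property
    def resolutions(self) -> tuple[float, ...]:
        return tuple(m / (n - 1) for m, n in zip(self.maxima, self.tensor.shape))

    def ravel(self) -> np.ndarray:
        """Row-major flattening for use as a feature vector."""
        return self.tensor.ravel()


def vectorize_curve(curve: EulerCurve, f_max: float, N: int) -> VectorizedCurve:
    """Sample the curve at N evenly spaced points on [0, f_max]."""
    if N < 2:
        raise ValueError("N must be at least 2 (both endpoints are sampled)")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    nodes = np.linspace(0.0, f_max, N)
    samples = np.array([ec_at(curve, t) for t in nodes], dtype=np.int64)
    return VectorizedCurve(samples, float(f_max))


def vectorization_bound(vec: VectorizedCurve, cell_count: int) -> float:
    """Upper bound on the L1 reconstruction error of ``vec``:
    ``delta * (cell_count / 2 + F)`` where F is the sum of absolute
    differences between consecutive samples."""
    F = float(np.abs(np.diff(vec.samples)).sum())
    return vec.resolution * (cell_count / 2.0 + F)


def vectorize_profile(
    profile: EulerProfile, maxima: Sequence[float], Ns: Sequence[int]
) -> VectorizedProfile:
    """Sample the profile on the inclusive regular grid of shape Ns."""
    maxima = tuple(float(m) for m in maxima)
    Ns = tuple(int(n) for n in Ns)
    if len(maxima) != profile.arity or len(Ns) != profile.arity:
        raise ValueError(f"maxima and Ns must have arity {profile.arity}")
    if any(n < 2 for n in Ns):
        raise ValueError("every N must be at least 2")
    axes = [np.linspace(0.0, m, n) for m, n in zip(maxima, Ns)]
    tensor = np.zeros(Ns, dtype=np.int64)
    if len(profile) > 0:
        # prefix-sum over per-axis bucketed deltas instead of N^n ecp_at calls
        idx = []
        keep = np.ones(len(profile), dtype=bool)
        for ax, coords in zip(axes, profile.locations.T):
            pos = np.searchsorted(ax, coords, side="left")
            keep &= pos < len(ax)
            idx.append(pos)
        if np.any(keep):
            np.add.at(tensor, tuple(i[keep] for i in idx), profile.deltas[keep])
            for axis in range(tensor.ndim):
                np.cumsum(tensor, axis=axis, out=tensor)
    return VectorizedProfile(tensor, maxima)


class EulerCurveVectorizer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer mapping contribution lists (or curves) to
    fixed-length vectors.  ``fit`` is a no-op; ``transform`` samples each
    input at N points on [0, f_max]."""

    def __init__(self, f_max: float = 1.0, N: int = 100):
        self.f_max = f_max
        self.N = N

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            curve = item if isinstance(item, EulerCurve) else build_curve(item)
            rows.append(vectorize_curve(curve, self.f_max, self.N).samples)
        return np.asarray(rows, dtype=np.int64)
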