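"""Synthetic data generators: every test and experiment in this package runs
on data produced here, so nothing needs downloading.

All generators are pure functions of their seed (bit-identical repeats).  The
texture generator emulates a classic two-factor image population — a spatial
pattern (stripes or checks) rendered in one RGB channel with i.i.d. Gaussian
pixel noise — whose pairwise Euler-profile distances separate style and color.
Pattern period (size/8) and noise sigma (10 on the 0-255 scale) are defaults
chosen to look like mildly noisy 8-bit textures; the qualitative distance
ordering is robust to reasonable alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .stability import PersistenceDiagram

__all__ = [
    "sample_sphere",
    "TextureSpec",
    "texture_image",
    "texture_batch",
    "random_diagram",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}
_STYLES = ("stripes", "checks")


def sample_sphere(
    n: int, dim: int, noise: float = 0.0, seed: int = 0
) -> np.ndarray:
    """``n`` points uniform on the unit ``dim``-sphere (embedded in
    R^(dim+1)) plus isotropic Gaussian noise of scale ``noise``."""
    if n < 1 or dim < 1:
        raise ValueError("n and dim must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, dim + 1))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if noise > 0:
        x = x + noise * rng.standard_normal(x.shape)
    return x


@dataclass(frozen=True)
class TextureSpec:
    """One synthetic RGB texture: a pure pattern in one channel plus noise."""

    style: str = "stripes"
    color: str = "red"
    size: int = 64
    noise_sigma: float = 10.0
    seed: int = 0
    period: int | None = None

    def __post_init__(self) -> None:
        if self.style not in _STYLES:
            raise ValueError(f"style must be one of {_STYLES}")
        if self.color not in _CHANNELS:
            raise ValueError(f"color must be one of {tuple(_CHANNELS)}")
        if self.size < 4:
            raise ValueError("size must be at least 4")


def texture_image(spec: TextureSpec) -> np.ndarray:
    """Render the texture as a (size, size, 3) array of integers in [0, 255].

    Stripes alternate 0/255 bands along axis 0; checks use the parity of the
    band indices along both axes.  The named channel carries the pattern, the
    other two are zero before noise.  Noise is i.i.d. Gaussian per pixel per
    channel, then rounded and clamped to [0, 255].
    """
    period = spec.period if spec.period is not None else max(1, spec.size // 8)
    idx = np.arange(spec.size) // period
    if spec.style == "stripes":
        pattern = (idx[:, None] % 2) * np.ones(spec.size, dtype=int)[None, :]
    else:
        pattern = (idx[:, None] + idx[None, :]) % 2
    img = np.zeros((spec.size, spec.size, 3), dtype=float)
    img[:, :, _CHANNELS[spec.color]] = pattern * 255.0
    rng = np.random.default_rng(spec.seed)
    img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.float64)


def texture_batch(
    samples_per_class: int = 10,
    size: int = 64,
    noise_sigma: float = 10.0,
    seed: int = 0,
) -> list[tuple[TextureSpec, np.ndarray]]:
    """The full texture population: ``samples_per_class`` noisy samples of
    each (style, color) combination — 60 images at the default 10 per class.
    Sample seeds are derived deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    out = []
    for style, color in product(_STYLES, _CHANNELS):
        for _ in range(samples_per_class):
            spec = TextureSpec(
                style=style,
                color=color,
                size=size,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append((spec, texture_image(spec)))
    return out


def random_diagram(
    n_points: int,
    birth_range: tuple[float, float] = (0.0, 5.0),
    persistence_range: tuple[float, float] = (0.0, 5.0),
    seed: int = 0,
) -> PersistenceDiagram:
    """Random finite diagram: births uniform in ``birth_range``, deaths at
    birth plus a uniform positive persistence (no points at infinity)."""
    if n_points < 0:
        raise ValueError("n_points must be non-negative")
    rng = np.random.default_rng(seed)
    births = rng.uniform(*birth_range, size=n_points)
    pers = rng.uniform(*persistence_range, size=n_points)
    return PersistenceDiagram(np.column_stack([births, births + pers]))
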