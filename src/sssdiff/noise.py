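"""Corruption fields for the diffusion process: multi-octave simplex and Gaussian.

Simplex noise (Perlin's skewed-lattice gradient noise) is spatially smooth and
concentrates power at low spatial frequencies; summing N frequency-doubled
octaves with amplitudes decaying by gamma^k pushes its amplitude distribution
toward Gaussian while keeping the low-frequency dominance that lets the
diffusion model corrupt — and later repair — large coherent regions.

Fields are standardised to zero mean / unit variance per sample so they can
stand in for the unit-variance eps of the forward diffusion equation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "SimplexSpec",
    "NoiseField",
    "simplex_octaves",
    "gaussian_field",
    "sample_noise",
    "octave_amplitudes",
]

# Skew/unskew constants of 2D simplex noise.
_F2 = 0.5 * (math.sqrt(3.0) - 1.0)
_G2 = (3.0 - math.sqrt(3.0)) / 6.0

_GRAD2 = np.array(
    [(1, 1), (-1, 1), (1, -1), (-1, -1), (1, 0), (-1, 0), (0, 1), (0, -1)],
    dtype=np.float64,
)


@dataclasses.dataclass(frozen=True)
class SimplexSpec:
    """Multi-octave simplex parameters.

    ``base_frequency`` is in cycles per pixel: the default 2**-6 gives a
    64-pixel characteristic feature scale. Octave k runs at frequency
    ``base_frequency * 2**k`` with amplitude ``decay**k``.
    """

    base_frequency: float = 2.0 ** -6
    octaves: int = 6
    decay: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError(f"octaves must be >= 1, got {self.octaves}")
        if not self.base_frequency > 0:
            raise ValueError("base_frequency must be positive")
        if not 0 < self.decay <= 1:
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")


@dataclasses.dataclass(frozen=True)
class NoiseField:
    """A standardised H×W corruption sample and how it was made."""

    values: np.ndarray
    kind: str  # "simplex" or "gaussian"
    spec: SimplexSpec | None = None

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def shape(self):
        return self.values.shape


def octave_amplitudes(spec: SimplexSpec) -> np.ndarray:
    """Pre-normalisation amplitude of each octave: decay**k for k = 0..N-1."""
    return spec.decay ** np.arange(spec.octaves, dtype=np.float64)


def _perm_table(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    p = rng.permutation(256)
    return np.concatenate([p, p]).astype(np.int64)


def _simplex2d(x: np.ndarray, y: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Raw 2D simplex noise at real coordinates (x, y), vectorised."""
    s = (x + y) * _F2
    i = np.floor(x + s).astype(np.int64)
    j = np.floor(y + s).astype(np.int64)
    t = (i + j) * _G2
    x0 = x - (i - t)
    y0 = y - (j - t)
    upper = x0 > y0  # which of the two simplices of the skewed cell
    i1 = np.where(upper, 1, 0)
    j1 = 1 - i1
    x1 = x0 - i1 + _G2
    y1 = y0 - j1 + _G2
    x2 = x0 - 1.0 + 2.0 * _G2
    y2 = y0 - 1.0 + 2.0 * _G2
    ii = i & 255
    jj = j & 255
    gi0 = perm[ii + perm[jj]] & 7
    gi1 = perm[ii + i1 + perm[jj + j1]] & 7
    gi2 = perm[ii + 1 + perm[jj + 1]] & 7

    total = np.zeros_like(x0)
    for gi, xs, ys in ((gi0, x0, y0), (gi1, x1, y1), (gi2, x2, y2)):
        att = 0.5 - xs * xs - ys * ys
        att = np.maximum(att, 0.0)
        g = _GRAD2[gi]
        total += att ** 4 * (g[..., 0] * xs + g[..., 1] * ys)
    return 70.0 * total


def simplex_octaves(height: int, width: int, spec: SimplexSpec,
                    rng: np.random.Generator | None = None) -> NoiseField:
    """Sum N octaves of simplex noise and standardise the result.

    The gradient lattice is fixed by ``spec.seed``; per-sample variation comes
    from a random lattice translation per octave. With ``rng=None`` the
    translations are drawn from a generator freshly seeded with ``spec.seed``,
    so repeated calls with the same spec return the identical field; pass a
    persistent ``rng`` to draw a fresh field per call (as the training loop
    does).
    """
    if height < 8 or width < 8:
        raise ValueError("field must be at least 8x8")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    perm = _perm_table(spec.seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    field = np.zeros((height, width))
    amps = octave_amplitudes(spec)
    for k in range(spec.octaves):
        freq = spec.base_frequency * 2.0 ** k
        ox, oy = rng.uniform(0.0, 1e5, size=2)
        field += amps[k] * _simplex2d(xx * freq + ox, yy * freq + oy, perm)
    sd = field.std()
    if sd < 1e-12:
        raise ValueError("degenerate simplex field (zero variance); "
                         "increase the field size or base_frequency")
    values = (field - field.mean()) / sd
    return NoiseField(values=values, kind="simplex", spec=spec)


def gaussian_field(height: int, width: int,
                   seed: int | np.random.Generator = 0) -> NoiseField:
    """I.i.d. standard-normal field — the baseline DDPM corruption."""
    if height < 1 or width < 1:
        raise ValueError("field dimensions must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return NoiseField(values=rng.standard_normal((height, width)), kind="gaussian")


def sample_noise(shape: tuple[int, int], spec,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw one eps field of the requested kind for the diffusion equations."""
    h, w = shape
    if isinstance(spec, SimplexSpec):
        return simplex_octaves(h, w, spec, rng).values
    if spec == "gaussian":
        return gaussian_field(h, w, rng).values
    raise ValueError(f"unknown noise spec {spec!r}")
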