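"""Single-channel image container and intensity-range conventions.

Two intensity conventions coexist in the pipeline:

* ``"unit"`` — [0, 1]; used for display, file I/O and reconstruction-error
  maps (the 0.3 error threshold lives on this scale);
* ``"symmetric"`` — [-1, 1]; used by the diffusion equations, which assume a
  roughly zero-centred signal.

:class:`GrayImage` carries its convention explicitly so the conversion happens
exactly once, at the diffusion boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["GrayImage", "unit_to_symmetric", "symmetric_to_unit"]

_RANGES = {"unit": (0.0, 1.0), "symmetric": (-1.0, 1.0)}
_TOL = 1e-6


def unit_to_symmetric(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr, dtype=np.float64) * 2.0 - 1.0


def symmetric_to_unit(arr: np.ndarray) -> np.ndarray:
    return (np.asarray(arr, dtype=np.float64) + 1.0) / 2.0


@dataclasses.dataclass
class GrayImage:
    """An H×W grayscale image with a declared intensity convention."""

    pixels: np.ndarray
    range_tag: str = "unit"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.pixels.shape}")
        if self.range_tag not in _RANGES:
            raise ValueError(f"unknown range_tag {self.range_tag!r}")
        lo, hi = _RANGES[self.range_tag]
        if self.pixels.min() < lo - _TOL or self.pixels.max() > hi + _TOL:
            raise ValueError(
                f"pixel values [{self.pixels.min():.4g}, {self.pixels.max():.4g}] "
                f"outside declared {self.range_tag} range [{lo}, {hi}]")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pixels, dtype=dtype)

    @property
    def shape(self):
        return self.pixels.shape

    def to_symmetric(self) -> "GrayImage":
        if self.range_tag == "symmetric":
            return self
        return GrayImage(unit_to_symmetric(self.pixels), "symmetric")

    def to_unit(self) -> "GrayImage":
        if self.range_tag == "unit":
            return self
        return GrayImage(symmetric_to_unit(self.pixels), "unit")
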