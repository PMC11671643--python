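"""Synthetic single-class phantoms with exact ground-truth anomalies.

The generator emulates the statistical shape of a skull-stripped axial brain
slice population at desk scale: every sample is the same soft-edged elliptical
"anatomy" with small per-sample jitter in position, size and orientation, a
smooth low-amplitude internal texture, and an exactly-zero background.
Anomalies are soft-edged disks of configurable intensity offset painted inside
the shape, so the ground-truth mask is exact by construction — the oracle for
every end-to-end test.
"""

from __future__ import annotations

import dataclasses
import math

import nibabel as nib
import numpy as np
from pathlib import Path
from scipy import ndimage

from .images import GrayImage

__all__ = ["PhantomSpec", "gen_healthy", "inject_anomaly", "write_nifti_fixture"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom population and its anomalies.

    Intensities: the shape interior sits around ``base_level`` with a gentle
    radial falloff and smooth texture of amplitude ``texture_amplitude``; with
    the defaults the interior stays below ~0.6, so the default +0.4 anomaly
    offset never clips against the unit range.
    """

    size: int = 64
    n_healthy: int = 200
    axis_fraction: tuple[float, float] = (0.30, 0.38)  # semi-axes / size
    center_jitter: float = 0.03  # fraction of size
    base_level: float = 0.50
    radial_falloff: float = 0.15
    texture_amplitude: float = 0.05
    texture_scale: float = 4.0  # gaussian smoothing sigma, pixels
    edge_softness: float = 0.12  # fraction of the elliptical radius
    anomaly_radius: tuple[int, int] = (4, 8)
    anomaly_offset: float = 0.4
    anomaly_count: int = 1
    anomaly_edge: float = 1.5  # taper width in pixels
    seed: int = 0


def _one_phantom(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cx = s / 2 + rng.uniform(-1, 1) * spec.center_jitter * s
    cy = s / 2 + rng.uniform(-1, 1) * spec.center_jitter * s
    ax = rng.uniform(*spec.axis_fraction) * s
    ay = rng.uniform(*spec.axis_fraction) * s
    theta = rng.uniform(-0.25, 0.25)
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r = np.sqrt((u / ax) ** 2 + (v / ay) ** 2)
    texture = ndimage.gaussian_filter(rng.standard_normal((s, s)),
                                      spec.texture_scale)
    tex_sd = texture.std()
    if tex_sd > 1e-12:
        texture = texture / tex_sd * spec.texture_amplitude
    body = spec.base_level - spec.radial_falloff * r ** 2 + texture
    # smoothstep ramp from the boundary inward; exactly zero outside r >= 1
    w = np.clip((1.0 - r) / spec.edge_softness, 0.0, 1.0)
    w = w * w * (3.0 - 2.0 * w)
    return np.clip(body * w, 0.0, 1.0)


def gen_healthy(spec: PhantomSpec) -> list[GrayImage]:
    """Seeded population of healthy phantoms with consistent global structure."""
    if spec.n_healthy < 1:
        raise ValueError("n_healthy must be >= 1")
    rng = np.random.default_rng(spec.seed)
    return [GrayImage(_one_phantom(spec, rng), "unit")
            for _ in range(spec.n_healthy)]


def inject_anomaly(healthy: GrayImage, spec: PhantomSpec,
                   seed: int | np.random.Generator = 0,
                   max_retries: int = 50):
    """Paint anomalous disk(s) inside the phantom; return (image, exact mask).

    The disk centre is drawn among interior pixels far enough from the shape
    boundary to contain the disk; if no such pixel exists the radius is
    halved, erroring out after ``max_retries`` shrink attempts. Pixels outside
    the painted region are bit-identical to the input; the mask is exactly the
    set of painted (nonzero-offset) pixels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(healthy.to_unit().pixels).copy()
    mask = np.zeros(img.shape, dtype=bool)
    lo, hi = spec.anomaly_radius
    if hi <= 0 or spec.anomaly_offset == 0.0 or spec.anomaly_count == 0:
        return GrayImage(img, "unit"), mask
    interior = img > 0
    dist = ndimage.distance_transform_edt(interior)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    for _ in range(spec.anomaly_count):
        radius = float(rng.integers(lo, hi + 1))
        for attempt in range(max_retries + 1):
            cand = np.flatnonzero((dist >= radius + 1) & ~mask)
            if cand.size:
                break
            radius = max(radius / 2.0, 1.0)
            if attempt == max_retries:
                raise RuntimeError("could not fit an anomaly inside the phantom")
        pick = cand[rng.integers(cand.size)]
        cy, cx = np.unravel_index(pick, img.shape)
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        taper = np.clip((radius - d) / spec.anomaly_edge, 0.0, 1.0)
        delta = spec.anomaly_offset * taper
        img = np.clip(img + delta, 0.0, 1.0)
        mask |= delta != 0.0
    return GrayImage(img, "unit"), mask


def write_nifti_fixture(images, masks, out_dir,
                        name: str = "phantom") -> dict[str, Path]:
    """Stack 2D phantoms into a small NIfTI volume (+ mask volume).

    Slices are stacked along the third (axial) axis with an identity affine,
    producing files consumable by :mod:`sssdiff.data_io` — this exercises the
    same I/O path the real MRI volumes would take.
    """
    images = list(images)
    if not images:
        raise ValueError("no images to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol = np.stack([np.asarray(GrayImage(np.asarray(im), "unit").pixels)
                    if not isinstance(im, GrayImage) else np.asarray(im.pixels)
                    for im in images], axis=2).astype(np.float32)
    img_path = out_dir / f"{name}.nii.gz"
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(img_path))
    paths = {"image": img_path}
    if masks is not None:
        mvol = np.stack([np.asarray(m).astype(np.uint8) for m in masks], axis=2)
        if mvol.shape != vol.shape:
            raise ValueError("mask stack shape does not match image stack")
        mask_path = out_dir / f"{name}_mask.nii.gz"
        nib.save(nib.Nifti1Image(mvol, np.eye(4)), str(mask_path))
        paths["mask"] = mask_path
    return paths
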