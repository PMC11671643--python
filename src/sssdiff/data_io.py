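"""NIfTI volume loading, slice extraction, contrast stretching and caching.

Volumes arrive skull-stripped and registered; this module only identifies the
axial axis from the NIfTI header, trims the top/bottom slices that carry no
anatomy, percentile-stretches each slice into [0, 1], resizes to the network's
square input size (bilinear for intensities, nearest-neighbour for masks) and
optionally persists the preprocessed slices as a NumPy cache keyed by the
preprocessing configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .images import GrayImage

__all__ = [
    "VolumeRecord",
    "PreprocessConfig",
    "load_volume",
    "contrast_stretch",
    "get_slice",
    "cache_dataset",
    "load_cached",
]


@dataclasses.dataclass
class VolumeRecord:
    """A 3D volume, its axial axis, trainable slice range and optional mask."""

    voxels: np.ndarray
    slice_axis: int
    trainable_range: tuple[int, int]  # inclusive slice indices
    mask: np.ndarray | None = None
    path: str | None = None

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]

    def anomalous_range(self) -> tuple[int, int]:
        """Inclusive index range of slices whose mask is non-empty."""
        if self.mask is None:
            raise ValueError("volume has no ground-truth mask")
        flags = np.moveaxis(self.mask, self.slice_axis, 0).reshape(self.n_slices, -1).any(axis=1)
        idx = np.flatnonzero(flags)
        if idx.size == 0:
            raise ValueError("mask is empty: no anomalous slices")
        return int(idx[0]), int(idx[-1])


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    size: int = 256
    p_lo: float = 1.0
    p_hi: float = 99.0
    n_trainable: int = 60

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(dataclasses.asdict(self),
                                         sort_keys=True).encode()).hexdigest()[:16]


def _axial_axis(img) -> int:
    """Axis running inferior<->superior, from the affine orientation codes."""
    codes = nib.orientations.aff2axcodes(img.affine)
    for ax, code in enumerate(codes):
        if code in ("S", "I"):
            return ax
    return 2  # fall back to the conventional third axis


def load_volume(path, mask_path=None, n_trainable: int = 60) -> VolumeRecord:
    """Read a NIfTI volume (and optional mask) into a :class:`VolumeRecord`.

    The trainable range defaults to the central ``n_trainable`` axial slices
    (clipped to the volume), dropping the top and bottom slices that carry
    little anatomy.
    """
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float64)
    axis = _axial_axis(img)
    n = voxels.shape[axis]
    span = min(n_trainable, n)
    lo = (n - span) // 2
    rec = VolumeRecord(voxels=voxels, slice_axis=axis,
                       trainable_range=(lo, lo + span - 1), path=str(path))
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0.5
        if mask.shape != voxels.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {voxels.shape}")
        rec.mask = mask
    return rec


def contrast_stretch(arr, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Map the [p_lo, p_hi] percentile window linearly onto [0, 1], clipped.

    A constant image maps to all zeros (no contrast to stretch).
    """
    if not 0 <= p_lo < p_hi <= 100:
        raise ValueError(f"invalid percentile window ({p_lo}, {p_hi})")
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = np.percentile(arr, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def get_slice(vol: VolumeRecord, index: int | None = None,
              seed: int | np.random.Generator = 0,
              cfg: PreprocessConfig = PreprocessConfig(),
              anomalous: bool = False):
    """Extract one preprocessed axial slice (and its mask slice, if present).

    With ``index=None`` a random slice is drawn from the trainable range (or
    from the annotated anomalous range when ``anomalous=True``). The intensity
    slice is contrast-stretched and bilinearly resized to ``cfg.size`` square;
    the mask is resized nearest-neighbour so it stays strictly binary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = vol.anomalous_range() if anomalous else vol.trainable_range
    if index is None:
        index = int(rng.integers(lo, hi + 1))
    if not lo <= index <= hi:
        raise ValueError(f"slice index {index} outside range [{lo}, {hi}]")
    sl = np.moveaxis(vol.voxels, vol.slice_axis, 0)[index]
    pixels = contrast_stretch(sl, cfg.p_lo, cfg.p_hi)
    pixels = resize(pixels, (cfg.size, cfg.size), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    image = GrayImage(np.clip(pixels, 0.0, 1.0), "unit")
    mask_img = None
    if vol.mask is not None:
        msl = np.moveaxis(vol.mask, vol.slice_axis, 0)[index]
        msl = resize(msl.astype(np.float64), (cfg.size, cfg.size), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
        mask_img = msl > 0.5
    return image, mask_img


def cache_dataset(volume_paths, out_prefix,
                  cfg: PreprocessConfig = PreprocessConfig()) -> Path:
    """Preprocess every trainable slice of every volume and persist them.

    Writes ``<out_prefix>.npz`` (the slice stack) and ``<out_prefix>.json``
    (a manifest keyed by the preprocessing-config digest). A later call with
    the same config returns the cached file untouched; a changed config
    rebuilds it.
    """
    out_prefix = Path(out_prefix)
    npz_path = out_prefix.with_suffix(".npz")
    manifest_path = out_prefix.with_suffix(".json")
    digest = cfg.digest()
    paths = sorted(str(p) for p in volume_paths)
    if npz_path.exists() and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("digest") == digest and manifest.get("volumes") == paths:
            return npz_path
    slices = []
    for vp in paths:
        vol = load_volume(vp, n_trainable=cfg.n_trainable)
        lo, hi = vol.trainable_range
        for idx in range(lo, hi + 1):
            image, _ = get_slice(vol, index=idx, cfg=cfg)
            slices.append(image.pixels.astype(np.float32))
    if not slices:
        raise ValueError("no slices found in the given volumes")
    np.savez_compressed(npz_path, slices=np.stack(slices))
    manifest_path.write_text(json.dumps(
        {"digest": digest, "volumes": paths, "n_slices": len(slices),
         "config": dataclasses.asdict(cfg)}, indent=2))
    return npz_path


def load_cached(npz_path) -> list[GrayImage]:
    with np.load(npz_path) as z:
        return [GrayImage(np.clip(s.astype(np.float64), 0, 1), "unit")
                for s in z["slices"]]
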