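"""Anomaly segmentation by healthy-image reconstruction.

The pipeline: partially noise the input to timestep lambda (so global
structure survives), reconstruct a "healthy" version with the trained noise
predictor — in one network call (single-step) or by the full DDPM reverse
chain (iterative) — then square the per-pixel difference, threshold it, and
clean the mask up with dilation and largest-component filtering. A
multi-timestep ensemble reruns the single-step sampler at several lambdas and
keeps the pixels flagged most often.

Intensity conventions: inputs and error maps live in [0, 1]; the threshold
tau (default 0.3, i.e. an amplitude difference of sqrt(0.3) ~ 0.55) applies to
the squared error of unit-range images. The diffusion math happens in the
symmetric [-1, 1] range internally.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import ndimage

from .diffusion import ScheduleTable, forward_diffuse, iterative_sample, single_step_denoise
from .images import GrayImage, symmetric_to_unit
from .noise import SimplexSpec, sample_noise

__all__ = [
    "AnomalyMap",
    "BinaryMask",
    "PostConfig",
    "anomaly_map",
    "threshold_mask",
    "postprocess",
    "segment_single",
    "segment_iterative",
    "ensemble_segment",
    "combine_votes",
    "tune_threshold",
    "DEFAULT_LAMBDA_WINDOW",
]

DEFAULT_LAMBDA_WINDOW = (250, 400)


@dataclasses.dataclass
class AnomalyMap:
    """Per-pixel squared reconstruction error E_sq, with provenance."""

    values: np.ndarray
    source: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("anomaly map must be non-negative")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def shape(self):
        return self.values.shape


@dataclasses.dataclass
class BinaryMask:
    """A boolean segmentation mask with provenance."""

    values: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def shape(self):
        return self.values.shape

    def area(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass(frozen=True)
class PostConfig:
    """Mask postprocessing: dilate, then keep the largest components."""

    kernel: int = 3
    keep_k: int = 1
    min_area: int = 5

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")


def anomaly_map(x0, x0_hat) -> AnomalyMap:
    """E_sq = (x0 - x0_hat)^2, both images in the unit range."""
    a = _unit_pixels(x0)
    b = _unit_pixels(x0_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return AnomalyMap(values=(a - b) ** 2)


def _unit_pixels(x) -> np.ndarray:
    if isinstance(x, GrayImage):
        return np.asarray(x.to_unit().pixels)
    arr = np.asarray(x, dtype=np.float64)
    if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
        raise ValueError("expected a unit-range image")
    return arr


def threshold_mask(m, tau: float) -> BinaryMask:
    """Pixels with squared error strictly above tau are anomalous."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    vals = np.asarray(m, dtype=np.float64)
    return BinaryMask(values=vals > tau, provenance={"tau": tau})


# 8-connectivity for component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)


def postprocess(mask, kernel: int = 3, keep_k: int = 1,
                min_area: int = 5) -> BinaryMask:
    """Binary dilation with a kernel x kernel square, then keep only the
    ``keep_k`` largest 8-connected components with area >= ``min_area``."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    vals = np.asarray(mask).astype(bool)
    if kernel > 1:
        vals = ndimage.binary_dilation(vals, structure=np.ones((kernel, kernel), bool))
    labels, n = ndimage.label(vals, structure=_STRUCT8)
    if n:
        areas = np.bincount(labels.ravel())[1:]
        order = np.argsort(areas)[::-1]
        keep = [lab + 1 for lab in order[:keep_k] if areas[lab] >= min_area]
        vals = np.isin(labels, keep) if keep else np.zeros_like(vals)
    prov = dict(getattr(mask, "provenance", {}))
    prov.update({"kernel": kernel, "keep_k": keep_k, "min_area": min_area})
    return BinaryMask(values=vals, provenance=prov)


def _apply_post(mask: BinaryMask, postcfg: PostConfig | None) -> BinaryMask:
    if postcfg is None:
        postcfg = PostConfig()
    return postprocess(mask, postcfg.kernel, postcfg.keep_k, postcfg.min_area)


def _resolve_lambda(lam, rng, window) -> int:
    if lam is None:
        lam = int(rng.integers(window[0], window[1] + 1))
    elif not window[0] <= lam <= window[1]:
        warnings.warn(
            f"lambda={lam} outside the recommended window {window}; "
            "reconstruction quality may degrade", stacklevel=3)
    return int(lam)


def segment_single(x0, lam, handle, sched: ScheduleTable, noise_spec=None,
                   tau: float = 0.3, postcfg: PostConfig | None = None,
                   seed: int | np.random.Generator = 0,
                   window=DEFAULT_LAMBDA_WINDOW):
    """Single-step segmentation: noise to lambda, reconstruct in ONE network
    call, threshold the squared error, postprocess.

    ``lam=None`` draws lambda uniformly from ``window``. Returns
    ``(mask, anomaly_map, reconstruction)`` where the reconstruction is a
    unit-range :class:`GrayImage`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_spec is None:
        noise_spec = SimplexSpec()
    lam = _resolve_lambda(lam, rng, window)
    x_unit = _unit_pixels(x0)
    x_sym = x_unit * 2.0 - 1.0
    eps = sample_noise(x_sym.shape, noise_spec, rng)
    sample = forward_diffuse(x_sym, eps, lam, sched)
    eps_hat = handle.predict(sample.x_t, lam)
    x0_hat_sym = single_step_denoise(sample.x_t, eps_hat, lam, sched, clip=1.0)
    recon = GrayImage(symmetric_to_unit(x0_hat_sym), "unit")
    amap = anomaly_map(x_unit, recon)
    amap.source = {"lambda": lam, "sampler": "single", "noise": noise_spec}
    mask = _apply_post(threshold_mask(amap, tau), postcfg)
    mask.provenance.update(amap.source)
    return mask, amap, recon


def segment_iterative(x0, lam, handle, sched: ScheduleTable, noise_spec=None,
                      tau: float = 0.3, postcfg: PostConfig | None = None,
                      seed: int | np.random.Generator = 0,
                      deterministic: bool = False,
                      window=DEFAULT_LAMBDA_WINDOW):
    """Baseline DDPM segmentation: as :func:`segment_single` but running the
    full reverse chain — exactly lambda network calls."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_spec is None:
        noise_spec = SimplexSpec()
    lam = _resolve_lambda(lam, rng, window)
    x_unit = _unit_pixels(x0)
    x_sym = x_unit * 2.0 - 1.0
    eps = sample_noise(x_sym.shape, noise_spec, rng)
    sample = forward_diffuse(x_sym, eps, lam, sched)
    x0_hat_sym = iterative_sample(sample.x_t, lam, handle, sched,
                                  deterministic=deterministic, rng=rng, clip=1.0)
    recon = GrayImage(symmetric_to_unit(x0_hat_sym), "unit")
    amap = anomaly_map(x_unit, recon)
    amap.source = {"lambda": lam, "sampler": "iterative", "noise": noise_spec}
    mask = _apply_post(threshold_mask(amap, tau), postcfg)
    mask.provenance.update(amap.source)
    return mask, amap, recon


def combine_votes(masks, min_votes: int) -> BinaryMask:
    """Keep pixels flagged by at least ``min_votes`` of the given masks."""
    if not masks:
        raise ValueError("no masks to combine")
    if min_votes > len(masks):
        raise ValueError(f"min_votes={min_votes} exceeds {len(masks)} masks")
    votes = np.sum([np.asarray(m, dtype=int) for m in masks], axis=0)
    return BinaryMask(values=votes >= min_votes,
                      provenance={"min_votes": min_votes, "n_masks": len(masks)})


def ensemble_segment(x0, lambdas, handle, sched: ScheduleTable, noise_spec=None,
                     tau: float = 0.3, min_votes: int | None = None,
                     postcfg: PostConfig | None = None,
                     seed: int | np.random.Generator = 0,
                     window=DEFAULT_LAMBDA_WINDOW) -> BinaryMask:
    """Multi-timestep ensemble: run the single-step sampler once per lambda
    (fresh noise each time), vote on the pre-postprocessing masks, keep pixels
    with at least ``min_votes`` (default: majority), then postprocess once."""
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("lambdas must be non-empty")
    if min_votes is None:
        min_votes = math.ceil(len(lambdas) / 2)
    if min_votes > len(lambdas):
        raise ValueError(f"min_votes={min_votes} exceeds {len(lambdas)} runs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw_masks = []
    for lam in lambdas:
        _, amap, _ = segment_single(x0, lam, handle, sched, noise_spec,
                                    tau=tau, postcfg=PostConfig(kernel=1, keep_k=10 ** 9, min_area=0),
                                    seed=rng, window=window)
        raw_masks.append(threshold_mask(amap, tau))
    mask = _apply_post(combine_votes(raw_masks, min_votes), postcfg)
    mask.provenance.update({"lambdas": lambdas, "tau": tau, "sampler": "ensemble"})
    return mask


def tune_threshold(anomaly_maps, truth_masks, taus=None,
                   postcfg: PostConfig | None = None) -> float:
    """Pick the tau maximising mean IoU of the postprocessed masks against
    ground truth over a validation set of anomaly maps."""
    from .metrics import seg_scores

    if taus is None:
        taus = np.round(np.arange(0.01, 0.51, 0.01), 3)
    best_tau, best_iou = float(taus[0]), -1.0
    for tau in taus:
        ious = []
        for amap, truth in zip(anomaly_maps, truth_masks):
            mask = _apply_post(threshold_mask(amap, float(tau)), postcfg)
            ious.append(seg_scores(mask, truth).iou)
        mean_iou = float(np.mean(ious))
        if mean_iou > best_iou:
            best_tau, best_iou = float(tau), mean_iou
    return best_tau
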