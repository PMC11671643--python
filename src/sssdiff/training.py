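"""DDPM training on healthy images.

Each iteration: draw a healthy image, a uniform timestep t in {1..T} and a
fresh noise field; jump to x_t with the closed-form forward equation; predict
the noise; take one AdamW step on the plain L2 loss ``mean((eps - eps_hat)^2)``
and update the exponential moving average of the parameters. Inference uses
the EMA weights.
"""

from __future__ import annotations

import csv
import dataclasses
import math

import numpy as np

from . import nn
from .denoiser import Checkpoint, DenoiserConfig, build_denoiser, save_checkpoint
from .diffusion import ScheduleTable, make_linear_schedule
from .images import GrayImage
from .noise import SimplexSpec, sample_noise

__all__ = ["TrainConfig", "AdamW", "training_step", "ema_update", "train"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    iterations: int = 2000
    batch_size: int = 1
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    adam_betas: tuple[float, float] = (0.9, 0.999)
    ema_decay: float = 0.9999
    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    seed: int = 0
    checkpoint_every: int = 0  # 0: only at the end

    def __post_init__(self) -> None:
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ValueError("ema_decay must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 0 or self.batch_size < 1:
            raise ValueError("invalid iterations/batch_size")


class AdamW(object):
    """AdamW: Adam moments plus decoupled weight decay."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999),
                 weight_decay: float = 0.0, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= (self.lr * update).astype(p.data.dtype)


def ema_update(ema_params: list[np.ndarray], params, decay: float) -> list[np.ndarray]:
    """In-place ``ema <- decay*ema + (1-decay)*param`` for each array pair."""
    for e, p in zip(ema_params, params):
        arr = p.data if isinstance(p, nn.Parameter) else np.asarray(p)
        if e.shape != arr.shape:
            raise ValueError("EMA/parameter shape mismatch")
        e *= decay
        e += (1.0 - decay) * arr
    return ema_params


def _as_symmetric(x0) -> np.ndarray:
    if isinstance(x0, GrayImage):
        return np.asarray(x0.to_symmetric().pixels)
    return np.asarray(x0, dtype=np.float64)


def training_step(handle, x0, rng: np.random.Generator,
                  sched: ScheduleTable, noise_spec=None,
                  opt: AdamW | None = None,
                  ema_params: list[np.ndarray] | None = None,
                  ema_decay: float = 0.9999) -> float:
    """One training iteration on one image; returns the scalar L2 loss.

    ``x0`` must be in the symmetric [-1, 1] range (a unit-range
    :class:`GrayImage` is converted). With ``opt=None`` the loss is computed
    without touching the parameters (useful for evaluating oracle or frozen
    predictors, which need not support backprop).
    """
    if noise_spec is None:
        noise_spec = SimplexSpec()
    x0 = _as_symmetric(x0)
    t = int(rng.integers(1, sched.T + 1))
    eps = sample_noise(x0.shape, noise_spec, rng)
    abar = sched.abar(t)
    x_t = math.sqrt(abar) * x0 + math.sqrt(1.0 - abar) * eps
    eps_hat = handle.predict(x_t, t)
    resid = eps_hat - eps
    loss = float(np.mean(resid ** 2))
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite training loss at t={t} "
            f"(|eps_hat| max {np.abs(eps_hat).max():.3g}); aborting")
    if opt is not None:
        dtype = handle.unet.in_conv.w.data.dtype
        dy = (2.0 * resid / resid.size).astype(dtype)[None, None]
        handle.unet.zero_grad()
        handle.unet.backward(dy)
        opt.step()
        if ema_params is not None:
            ema_update(ema_params, handle.unet.parameters(), ema_decay)
    return loss


def train(dataset, train_cfg: TrainConfig, denoiser_cfg: DenoiserConfig,
          noise_spec=None, out_path=None, log_path=None, resume=None,
          progress: bool = False) -> Checkpoint:
    """Full seeded training loop over a sequence of healthy images.

    ``dataset`` is a sequence of unit-range :class:`GrayImage` (or arrays in
    [0, 1]). Returns the final :class:`Checkpoint`; optionally saves it to
    ``out_path`` and a (step, loss, lr) CSV to ``log_path``. The whole run is
    a deterministic function of ``train_cfg.seed``. Passing a
    :class:`Checkpoint` as ``resume`` continues from its parameters and EMA
    for ``train_cfg.iterations`` further steps (optimizer moments restart).
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if noise_spec is None:
        noise_spec = SimplexSpec()
    images = [np.asarray(GrayImage(np.asarray(im), "unit").to_symmetric().pixels)
              if not isinstance(im, GrayImage) else np.asarray(im.to_symmetric().pixels)
              for im in dataset]
    sched = make_linear_schedule(train_cfg.T, train_cfg.beta_start, train_cfg.beta_end)
    rng = np.random.default_rng(train_cfg.seed)
    handle = build_denoiser(denoiser_cfg, seed=int(rng.integers(2 ** 31)))
    step0 = 0
    if resume is not None:
        if resume.cfg != denoiser_cfg:
            raise ValueError("resume checkpoint config does not match")
        for p, arr in zip(handle.unet.parameters(), resume.params):
            p.data[...] = arr.astype(p.data.dtype)
        step0 = resume.step
    opt = AdamW(handle.unet.parameters(), lr=train_cfg.learning_rate,
                betas=train_cfg.adam_betas, weight_decay=train_cfg.weight_decay)
    ema = ([e.copy() for e in resume.ema_params] if resume is not None
           else [p.data.copy() for p in handle.unet.parameters()])
    log_rows = []
    iterator = range(train_cfg.iterations)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train")
    for step in iterator:
        losses = []
        for _ in range(train_cfg.batch_size):
            idx = int(rng.integers(len(images)))
            loss = training_step(handle, images[idx], rng, sched, noise_spec,
                                 opt=opt, ema_params=ema,
                                 ema_decay=train_cfg.ema_decay)
            losses.append(loss)
        log_rows.append((step0 + step + 1, float(np.mean(losses)),
                         train_cfg.learning_rate))
        if (out_path is not None and train_cfg.checkpoint_every
                and (step + 1) % train_cfg.checkpoint_every == 0):
            ck = Checkpoint(denoiser_cfg,
                            [p.data.copy() for p in handle.unet.parameters()],
                            [e.copy() for e in ema], step0 + step + 1)
            save_checkpoint(out_path, ck)
    ckpt = Checkpoint(cfg=denoiser_cfg,
                      params=[p.data.copy() for p in handle.unet.parameters()],
                      ema_params=[e.copy() for e in ema],
                      step=step0 + train_cfg.iterations)
    if out_path is not None:
        save_checkpoint(out_path, ckpt)
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "loss", "lr"])
            w.writerows(log_rows)
    ckpt.loss_log = log_rows  # type: ignore[attr-defined]
    return ckpt
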