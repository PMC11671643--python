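"""Variance schedules and the forward/reverse diffusion processes.

The forward (noising) process corrupts an image x0 with a scheduled mixture of
signal and noise,

    x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * eps,

where abar_t is the cumulative product of alpha_t = 1 - beta_t. Two ways back
are provided:

* ``reverse_step`` / ``iterative_sample`` — the classic DDPM ancestral
  sampler, one learned denoising step per timestep (O(lambda) network calls);
* ``single_step_denoise`` — the single-step reconstruction: the closed-form
  forward equation solved for x0 using one noise prediction (O(1) network
  calls).

All functions operate on plain ``numpy`` arrays in the symmetric [-1, 1]
intensity convention; conversion from the unit display range is owned by
:mod:`sssdiff.images`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ScheduleTable",
    "DiffusionSample",
    "make_linear_schedule",
    "make_schedule",
    "forward_diffuse",
    "single_step_denoise",
    "reverse_step",
    "iterative_sample",
]


@dataclasses.dataclass(frozen=True)
class ScheduleTable:
    """Per-timestep noise variances of a diffusion chain of length T.

    ``beta[t-1]``, ``alpha[t-1]`` and ``alpha_bar[t-1]`` hold the values for
    timestep ``t`` (timesteps are 1-based, matching the chain convention).
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"chain length T must be >= 1, got {self.T}")
        for name in ("beta", "alpha", "alpha_bar"):
            if len(getattr(self, name)) != self.T:
                raise ValueError(f"{name} must have length T={self.T}")
        if not (np.all(self.beta > 0) and np.all(self.beta < 1)):
            raise ValueError("all beta_t must lie in (0, 1)")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")

    def abar(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha_bar[t - 1])

    def _check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep t={t} outside [1, {self.T}]")


@dataclasses.dataclass(frozen=True)
class DiffusionSample:
    """A partially noised image together with its provenance."""

    x_t: np.ndarray
    t: int
    eps: np.ndarray


def make_linear_schedule(T: int, beta_start: float = 1e-4,
                         beta_end: float = 0.02) -> ScheduleTable:
    """Linear beta schedule from ``beta_start`` at t=1 to ``beta_end`` at t=T."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError(
            f"require 0 < beta_start <= beta_end < 1, got {beta_start}, {beta_end}")
    beta = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return ScheduleTable(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar)


def make_schedule(name: str, T: int, beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> ScheduleTable:
    """Build a named schedule. Only ``"linear"`` is supported; ``"cosine"`` is
    recognised but deliberately rejected (not part of this method)."""
    if name == "linear":
        return make_linear_schedule(T, beta_start, beta_end)
    if name == "cosine":
        raise NotImplementedError("cosine schedule is reserved and not supported")
    raise ValueError(f"unknown schedule {name!r}")


def _as_array(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "pixels", x), dtype=np.float64)
    return arr


def forward_diffuse(x0, eps, t: int, sched: ScheduleTable) -> DiffusionSample:
    """Closed-form jump from x0 to x_t: sqrt(abar)*x0 + sqrt(1-abar)*eps."""
    x0 = _as_array(x0)
    eps = _as_array(eps)
    if x0.shape != eps.shape:
        raise ValueError(f"shape mismatch: x0 {x0.shape} vs eps {eps.shape}")
    abar = sched.abar(t)
    x_t = np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps
    return DiffusionSample(x_t=x_t, t=t, eps=eps)


def single_step_denoise(x_t, eps_hat, t: int, sched: ScheduleTable,
                        clip: float | None = 1.0) -> np.ndarray:
    """Single-step reconstruction: invert the closed-form forward equation.

    x0_hat = (x_t - sqrt(1 - abar_t) * eps_hat) / sqrt(abar_t)

    One predicted-noise field in, one clean-image estimate out — this is the
    whole reverse pass of the single-step sampler. When ``clip`` is given the
    estimate is clipped to [-clip, clip] (the symmetric display range); pass
    ``clip=None`` for the raw estimate.
    """
    x_t = _as_array(x_t)
    eps_hat = _as_array(eps_hat)
    if x_t.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch: x_t {x_t.shape} vs eps_hat {eps_hat.shape}")
    abar = sched.abar(t)
    x0_hat = (x_t - np.sqrt(1.0 - abar) * eps_hat) / np.sqrt(abar)
    if clip is not None:
        x0_hat = np.clip(x0_hat, -clip, clip)
    return x0_hat


def reverse_step(x_t, eps_hat, z, t: int, sched: ScheduleTable) -> np.ndarray:
    """One DDPM ancestral step from x_t to x_{t-1}.

    x_{t-1} = (x_t - beta_t/sqrt(1-abar_t) * eps_hat) / sqrt(alpha_t) + sigma_t z

    with the fixed-variance choice sigma_t^2 = beta_t. Pass ``z`` of zeros for
    a deterministic step (always done at t=1).
    """
    x_t = _as_array(x_t)
    eps_hat = _as_array(eps_hat)
    z = _as_array(z)
    sched._check_t(t)
    if not (x_t.shape == eps_hat.shape == z.shape):
        raise ValueError("x_t, eps_hat and z must share a shape")
    beta = float(sched.beta[t - 1])
    alpha = float(sched.alpha[t - 1])
    abar = float(sched.alpha_bar[t - 1])
    mean = (x_t - beta / np.sqrt(1.0 - abar) * eps_hat) / np.sqrt(alpha)
    return mean + np.sqrt(beta) * z


def iterative_sample(x_lambda, lam: int, denoiser, sched: ScheduleTable,
                     deterministic: bool = False,
                     rng: np.random.Generator | None = None,
                     clip: float | None = 1.0) -> np.ndarray:
    """Full DDPM reverse chain from timestep ``lam`` down to 0.

    Runs ``reverse_step`` for t = lam, ..., 1 — exactly ``lam`` denoiser
    evaluations. ``denoiser`` must expose ``predict(x_t, t) -> eps_hat``
    (see :class:`sssdiff.denoiser.DenoiserHandle`). Noise injection z is drawn
    from ``rng`` unless ``deterministic``; the final step (t=1) is always
    noise-free.
    """
    x = _as_array(x_lambda)
    if lam < 0 or lam > sched.T:
        raise ValueError(f"lambda={lam} outside [0, {sched.T}]")
    if lam == 0:
        return x.copy()
    if rng is None:
        rng = np.random.default_rng(0)
    for t in range(lam, 0, -1):
        eps_hat = _as_array(denoiser.predict(x, t))
        if deterministic or t == 1:
            z = np.zeros_like(x)
        else:
            z = rng.standard_normal(x.shape)
        x = reverse_step(x, eps_hat, z, t, sched)
    if clip is not None:
        x = np.clip(x, -clip, clip)
    return x
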