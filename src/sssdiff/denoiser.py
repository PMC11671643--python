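"""The trainable noise-prediction network.

A UNet in the DDPM lineage: residual blocks with group normalisation and SiLU,
sinusoidal timestep embeddings injected into every residual block, multi-head
self-attention at configured spatial resolutions, stride-2 convolution
downsampling and nearest-neighbour upsampling. The encoder halves the spatial
resolution per level while widening channels; the decoder mirrors it, with a
pass-through skip connection concatenated at each resolution.

The network is exposed behind :class:`DenoiserHandle`, whose only contract is
``predict(x_t, t) -> eps_hat`` with an evaluation counter — which is what lets
the single-step sampler's O(1) claim be asserted as a call count.
"""

from __future__ import annotations

import dataclasses

import json
import math

import numpy as np

from . import nn

__all__ = [
    "DenoiserConfig",
    "DenoiserHandle",
    "FunctionHandle",
    "Checkpoint",
    "build_denoiser",
    "time_embedding",
    "predict_noise",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class DenoiserConfig:
    """UNet hyperparameters.

    ``channel_multipliers`` defines one resolution level per entry; level i
    runs at ``image_size / 2**i`` with ``base_channels * multiplier[i]``
    channels. Attention is applied at every level whose resolution is listed
    in ``attention_resolutions``.
    """

    image_size: int = 256
    in_channels: int = 1
    base_channels: int = 128
    channel_multipliers: tuple[int, ...] = (1, 1, 2, 3, 4)
    res_blocks_per_level: int = 2
    attention_resolutions: frozenset[int] = frozenset({32, 16})
    attention_heads: int = 2
    dropout: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_multipliers",
                           tuple(self.channel_multipliers))
        object.__setattr__(self, "attention_resolutions",
                           frozenset(self.attention_resolutions))
        levels = len(self.channel_multipliers)
        if self.image_size % (2 ** (levels - 1)):
            raise ValueError(
                f"image_size {self.image_size} not divisible by "
                f"2^{levels - 1} (levels={levels})")
        extra = self.attention_resolutions - set(self.level_resolutions)
        if extra:
            raise ValueError(
                f"attention resolutions {sorted(extra)} not among level "
                f"resolutions {self.level_resolutions}")
        if self.dropout != 0.0:
            raise NotImplementedError("only dropout=0 is supported")

    @property
    def level_resolutions(self) -> tuple[int, ...]:
        return tuple(self.image_size // 2 ** i
                     for i in range(len(self.channel_multipliers)))

    @property
    def level_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * m for m in self.channel_multipliers)

    @property
    def bottleneck_resolution(self) -> int:
        return self.level_resolutions[-1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_multipliers"] = list(self.channel_multipliers)
        d["attention_resolutions"] = sorted(self.attention_resolutions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        d = dict(d)
        d["channel_multipliers"] = tuple(d["channel_multipliers"])
        d["attention_resolutions"] = frozenset(d["attention_resolutions"])
        return cls(**d)


def time_embedding(t, dim: int) -> np.ndarray:
    """Transformer sinusoidal embedding of timestep(s) ``t`` at width ``dim``.

    Wavelengths form a geometric series from 2*pi to 10000*2*pi; the first
    half of the vector holds sines, the second half cosines, so t=0 maps to
    (0,...,0,1,...,1). Accepts a scalar or a 1D array of timesteps.
    """
    if dim % 2:
        raise ValueError(f"embedding dim must be even, got {dim}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t_arr < 0):
        raise ValueError("timesteps must be non-negative")
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t_arr[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    return emb[0] if np.isscalar(t) or np.ndim(t) == 0 else emb


class ResBlock(nn.Module):
    """GroupNorm/SiLU/conv twice, timestep embedding added between, residual skip."""

    def __init__(self, c_in: int, c_out: int, emb_dim: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.gn1 = nn.GroupNorm(c_in, dtype=dtype)
        self.act1 = nn.SiLU()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, dtype=dtype)
        self.emb_act = nn.SiLU()
        self.emb_lin = nn.Linear(emb_dim, c_out, rng, dtype=dtype)
        self.gn2 = nn.GroupNorm(c_out, dtype=dtype)
        self.act2 = nn.SiLU()
        self.conv2 = nn.Conv2d(c_in=c_out, c_out=c_out, k=3, rng=rng,
                               dtype=dtype, zero_init=True)
        self.skip = (nn.Conv2d(c_in, c_out, 1, rng, dtype=dtype)
                     if c_in != c_out else None)

    def forward(self, x: np.ndarray, emb: np.ndarray) -> np.ndarray:
        h = self.conv1.forward(self.act1.forward(self.gn1.forward(x)))
        e = self.emb_lin.forward(self.emb_act.forward(emb))
        h = h + e[:, :, None, None]
        h = self.conv2.forward(self.act2.forward(self.gn2.forward(h)))
        sk = x if self.skip is None else self.skip.forward(x)
        return h + sk

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dh = self.gn2.backward(self.act2.backward(self.conv2.backward(dy)))
        demb = self.emb_act.backward(self.emb_lin.backward(dh.sum(axis=(2, 3))))
        dx = self.gn1.backward(self.act1.backward(self.conv1.backward(dh)))
        dx = dx + (dy if self.skip is None else self.skip.backward(dy))
        return dx, demb


class UNet(nn.Module):
    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.cfg = cfg
        chs = cfg.level_channels
        ress = cfg.level_resolutions
        emb_dim = 4 * cfg.base_channels
        self.emb_dim = emb_dim
        self.emb_lin1 = nn.Linear(cfg.base_channels, emb_dim, rng, dtype=dtype)
        self.emb_act = nn.SiLU()
        self.emb_lin2 = nn.Linear(emb_dim, emb_dim, rng, dtype=dtype)

        self.in_conv = nn.Conv2d(cfg.in_channels, chs[0], 3, rng, dtype=dtype)
        n_levels = len(chs)
        self.down_res = nn.ModuleList()
        self.down_attn = nn.ModuleList()
        self.downs = nn.ModuleList()
        for i in range(n_levels - 1):
            blocks = nn.ModuleList(
                ResBlock(chs[i], chs[i], emb_dim, rng, dtype)
                for _ in range(cfg.res_blocks_per_level))
            self.down_res.append(blocks)
            self.down_attn.append(self._maybe_attn(ress[i], chs[i], rng, dtype))
            self.downs.append(nn.Conv2d(chs[i], chs[i + 1], 3, rng, stride=2,
                                        dtype=dtype))
        self.mid1 = ResBlock(chs[-1], chs[-1], emb_dim, rng, dtype)
        self.mid_attn = self._maybe_attn(ress[-1], chs[-1], rng, dtype)
        self.mid2 = ResBlock(chs[-1], chs[-1], emb_dim, rng, dtype)

        self.up_convs = nn.ModuleList()
        self.up_res = nn.ModuleList()
        self.up_attn = nn.ModuleList()
        for i in reversed(range(n_levels - 1)):
            self.up_convs.append(nn.Conv2d(chs[i + 1], chs[i], 3, rng, dtype=dtype))
            blocks = nn.ModuleList()
            for r in range(cfg.res_blocks_per_level):
                c_in = 2 * chs[i] if r == 0 else chs[i]
                blocks.append(ResBlock(c_in, chs[i], emb_dim, rng, dtype))
            self.up_res.append(blocks)
            self.up_attn.append(self._maybe_attn(ress[i], chs[i], rng, dtype))

        self.out_gn = nn.GroupNorm(chs[0], dtype=dtype)
        self.out_act = nn.SiLU()
        self.out_conv = nn.Conv2d(chs[0], cfg.in_channels, 3, rng, dtype=dtype,
                                  zero_init=True)

    def _maybe_attn(self, res: int, ch: int, rng, dtype):
        if res in self.cfg.attention_resolutions:
            return nn.SelfAttention2d(ch, self.cfg.attention_heads, rng, dtype)
        return _Identity()

    def forward(self, x: np.ndarray, t) -> np.ndarray:
        n = x.shape[0]
        t_vec = np.full(n, t, dtype=np.float64) if np.ndim(t) == 0 else np.asarray(t)
        base = time_embedding(t_vec, self.cfg.base_channels).astype(x.dtype)
        emb = self.emb_lin2.forward(self.emb_act.forward(self.emb_lin1.forward(base)))

        h = self.in_conv.forward(x)
        skips = []
        for blocks, attn, down in zip(self.down_res, self.down_attn, self.downs):
            for blk in blocks:
                h = blk.forward(h, emb)
            h = attn.forward(h)
            skips.append(h)
            h = down.forward(h)
        h = self.mid1.forward(h, emb)
        h = self.mid_attn.forward(h)
        h = self.mid2.forward(h, emb)
        self._skip_channels = []
        for upc, blocks, attn in zip(self.up_convs, self.up_res, self.up_attn):
            h = upc.forward(nn.upsample_nearest2(h))
            sk = skips.pop()
            self._skip_channels.append(sk.shape[1])
            h = np.concatenate([h, sk], axis=1)
            for blk in blocks:
                h = blk.forward(h, emb)
            h = attn.forward(h)
        return self.out_conv.forward(self.out_act.forward(self.out_gn.forward(h)))

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate from the output gradient; accumulates parameter grads."""
        demb_total = 0.0
        dh = self.out_gn.backward(self.out_act.backward(self.out_conv.backward(dy)))
        dskips = []
        for upc, blocks, attn, skc in zip(
                reversed(list(self.up_convs)), reversed(list(self.up_res)),
                reversed(list(self.up_attn)), reversed(self._skip_channels)):
            dh = attn.backward(dh)
            for blk in reversed(list(blocks)):
                dh, demb = blk.backward(dh)
                demb_total = demb_total + demb
            dsk = dh[:, dh.shape[1] - skc:]
            dh = dh[:, :dh.shape[1] - skc]
            dskips.append(dsk)
            dh = nn.upsample_nearest2_grad(upc.backward(dh))
        dh_, demb = self.mid2.backward(dh)
        demb_total = demb_total + demb
        dh_ = self.mid_attn.backward(dh_)
        dh_, demb = self.mid1.backward(dh_)
        demb_total = demb_total + demb
        dh = dh_
        for blocks, attn, down in zip(
                reversed(list(self.down_res)), reversed(list(self.down_attn)),
                reversed(list(self.downs))):
            dh = down.backward(dh)
            dh = dh + dskips.pop()
            dh = attn.backward(dh)
            for blk in reversed(list(blocks)):
                dh, demb = blk.backward(dh)
                demb_total = demb_total + demb
        self.in_conv.backward(dh)
        self.emb_lin1.backward(self.emb_act.backward(self.emb_lin2.backward(demb_total)))


class _Identity(nn.Module):
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class DenoiserHandle:
    """Opaque noise predictor: ``predict(x_t, t) -> eps_hat`` plus a call counter."""

    def __init__(self, unet: UNet, cfg: DenoiserConfig, seed: int | None = None) -> None:
        self.unet = unet
        self.cfg = cfg
        self.seed = seed
        self.eval_counter = 0

    @property
    def levels(self) -> list[tuple[int, int]]:
        """(resolution, channels) per level, encoder order."""
        return list(zip(self.cfg.level_resolutions, self.cfg.level_channels))

    @property
    def bottleneck_resolution(self) -> int:
        return self.cfg.bottleneck_resolution

    def predict(self, x_t, t: int) -> np.ndarray:
        x = np.asarray(x_t, dtype=self.unet.in_conv.w.data.dtype)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != self.cfg.image_size or x.shape[-2] != self.cfg.image_size:
            raise ValueError(
                f"input {x.shape[-2]}x{x.shape[-1]} does not match configured "
                f"image_size {self.cfg.image_size}")
        out = self.unet.forward(x, t)
        self.eval_counter += 1
        if squeeze:
            return out[0, 0].astype(np.float64)
        return out[:, 0].astype(np.float64)


class FunctionHandle:
    """Wraps a plain ``f(x_t, t) -> eps_hat`` as a denoiser handle.

    Used for analytic oracles (e.g. a predictor that returns the true eps) in
    tests and diagnostics; counts evaluations like the real handle.
    """

    def __init__(self, fn) -> None:
        self.fn = fn
        self.eval_counter = 0

    def predict(self, x_t, t: int) -> np.ndarray:
        self.eval_counter += 1
        return np.asarray(self.fn(np.asarray(x_t, dtype=np.float64), t))


def build_denoiser(cfg: DenoiserConfig, seed: int,
                   dtype=np.float32) -> DenoiserHandle:
    """Construct a freshly initialised denoiser; identical seeds give identical
    parameters."""
    rng = np.random.default_rng(seed)
    return DenoiserHandle(UNet(cfg, rng, dtype=dtype), cfg, seed=seed)


def predict_noise(handle, x_t, t: int) -> np.ndarray:
    """Functional form of ``handle.predict`` (spec-level operation)."""
    return handle.predict(x_t, t)


@dataclasses.dataclass
class Checkpoint:
    """Serialized training state: config, raw and EMA parameters, step."""

    cfg: DenoiserConfig
    params: list[np.ndarray]
    ema_params: list[np.ndarray]
    step: int

    def to_handle(self, ema: bool = True) -> DenoiserHandle:
        handle = build_denoiser(self.cfg, seed=0)
        source = self.ema_params if ema else self.params
        targets = handle.unet.parameters()
        if len(source) != len(targets):
            raise ValueError("checkpoint does not match the configured network")
        for p, arr in zip(targets, source):
            if p.data.shape != arr.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data[...] = arr.astype(p.data.dtype)
        return handle


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(ckpt.params)}
    arrays.update({f"e{i}": a for i, a in enumerate(ckpt.ema_params)})
    np.savez(path, n=len(ckpt.params), step=ckpt.step,
             cfg=json.dumps(ckpt.cfg.to_dict()), **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path, allow_pickle=False) as z:
        n = int(z["n"])
        cfg = DenoiserConfig.from_dict(json.loads(str(z["cfg"])))
        params = [z[f"p{i}"] for i in range(n)]
        ema = [z[f"e{i}"] for i in range(n)]
        step = int(z["step"])
    return Checkpoint(cfg=cfg, params=params, ema_params=ema, step=step)
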