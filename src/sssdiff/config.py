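"""YAML configuration and the two shipped profiles.

``paper``: the full-scale hyperparameters (256x256 images, base 128, five
resolution levels, attention at 32 and 16, T=1000, AdamW lr 1e-4, EMA 0.9999).

``mini``: a desk-scale profile that trains in minutes on one CPU (64x64
phantoms, base 16, three levels, attention at 16 — the paper's attention
resolutions scaled by the 256->64 image-size ratio — T=1000, lr 3e-4, EMA
0.995, 2000 iterations).
"""

from __future__ import annotations


import yaml

from .denoiser import DenoiserConfig
from .diffusion import ScheduleTable, make_schedule
from .noise import SimplexSpec
from .training import TrainConfig

__all__ = ["PROFILES", "load_config", "profile_config", "schedule_from_config",
           "denoiser_from_config", "train_from_config", "noise_from_config"]

PROFILES: dict[str, dict] = {
    "paper": {
        "schedule": {"name": "linear", "T": 1000,
                     "beta_start": 1e-4, "beta_end": 0.02},
        "noise": {"kind": "simplex", "base_frequency": 2 ** -6,
                  "octaves": 6, "decay": 0.8},
        "denoiser": {"image_size": 256, "base_channels": 128,
                     "channel_multipliers": [1, 1, 2, 3, 4],
                     "res_blocks_per_level": 2,
                     "attention_resolutions": [32, 16],
                     "attention_heads": 2, "dropout": 0.0},
        "train": {"iterations": 100000, "batch_size": 1,
                  "learning_rate": 1e-4, "weight_decay": 0.0,
                  "adam_betas": [0.9, 0.999], "ema_decay": 0.9999},
        "segment": {"lambda": 300, "window": [250, 400], "tau": 0.3,
                    "ensemble_lambdas": [250, 300, 350, 400]},
    },
    "mini": {
        "schedule": {"name": "linear", "T": 1000,
                     "beta_start": 1e-4, "beta_end": 0.02},
        "noise": {"kind": "simplex", "base_frequency": 2 ** -6,
                  "octaves": 6, "decay": 0.8},
        "denoiser": {"image_size": 64, "base_channels": 16,
                     "channel_multipliers": [1, 2, 2],
                     "res_blocks_per_level": 1,
                     "attention_resolutions": [16],
                     "attention_heads": 2, "dropout": 0.0},
        "train": {"iterations": 2000, "batch_size": 1,
                  "learning_rate": 3e-4, "weight_decay": 0.0,
                  "adam_betas": [0.9, 0.999], "ema_decay": 0.995},
        "segment": {"lambda": 300, "window": [250, 400], "tau": 0.3,
                    "ensemble_lambdas": [250, 300, 350, 400]},
    },
}


def profile_config(name: str) -> dict:
    if name not in PROFILES:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    return _deepcopy(PROFILES[name])


def _deepcopy(d):
    import copy
    return copy.deepcopy(d)


def load_config(path=None, profile: str = "mini", overrides: dict | None = None) -> dict:
    """Profile defaults, optionally overlaid with a YAML file and overrides."""
    cfg = profile_config(profile)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val


def schedule_from_config(cfg: dict) -> ScheduleTable:
    s = cfg["schedule"]
    return make_schedule(s.get("name", "linear"), s["T"],
                         s.get("beta_start", 1e-4), s.get("beta_end", 0.02))


def denoiser_from_config(cfg: dict) -> DenoiserConfig:
    d = dict(cfg["denoiser"])
    d["channel_multipliers"] = tuple(d["channel_multipliers"])
    d["attention_resolutions"] = frozenset(d["attention_resolutions"])
    return DenoiserConfig(**d)


def train_from_config(cfg: dict, seed: int = 0) -> TrainConfig:
    t = dict(cfg["train"])
    t["adam_betas"] = tuple(t.get("adam_betas", (0.9, 0.999)))
    s = cfg["schedule"]
    return TrainConfig(seed=seed, T=s["T"], beta_start=s.get("beta_start", 1e-4),
                       beta_end=s.get("beta_end", 0.02), **t)


def noise_from_config(cfg: dict, seed: int = 0):
    n = cfg["noise"]
    if n.get("kind", "simplex") == "gaussian":
        return "gaussian"
    return SimplexSpec(base_frequency=n.get("base_frequency", 2 ** -6),
                       octaves=n.get("octaves", 6), decay=n.get("decay", 0.8),
                       seed=seed)
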