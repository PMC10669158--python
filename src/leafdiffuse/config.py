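"""Run configuration: nested defaults, strict validation, seed derivation.

The default profile is the "tiny" desk-scale configuration that the whole
pipeline can execute on one CPU in well under a minute; the documented
full-scale settings (4000 diffusion steps, 128 channels, 256 px images,
attention at 32/16/8; translation batch 1, 64 filters, lr 2e-4 with decay
after 100 iterations, load 220 / fine 200) are recorded in
``FULL_SCALE_SETTINGS`` for reference.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from .schedule import ConfigurationError

__all__ = ["DEFAULT_CONFIG", "FULL_SCALE_SETTINGS", "load_config", "merge_config", "stage_rng"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_root": "runs/demo",
    "synth": {
        "size": 16,
        "healthy_count": 8,
        "disease_count": 8,
        "disease_style": "dark-spot",
        "intensity": 0.8,
        "edge_bias": 0.0,
    },
    "masks": {
        "method": "otsu",
        "dilate_frac": 0.03,
        "use_split_masks": True,
    },
    "diffusion": {
        "steps": 25,
        "schedule": "linear",
        "beta_min": 1e-4,
        "beta_max": 0.25,
    },
    "model": {
        "channels": 32,
        "attention_resolutions": [32, 16, 8],
        "train_steps": 400,
        "batch_size": 16,
        "lr": 2e-3,
    },
    "repaint": {
        "jump_length": 2,
        "resamples": 2,
        "n_images": 4,
    },
    "metrics": {
        "extractor": "toy",
        "n_subsets": 50,
        "subset_size": 4,
        "is_splits": 2,
    },
    "instagan": {
        "lambda_cyc": 10.0,
        "lambda_idt": 10.0,
        "lambda_ctx": 10.0,
        "filters": 64,
        "load_size": 220,
        "fine_size": 200,
        "lr": 2e-4,
        "batch_size": 1,
    },
}

# Documented full-scale experiment settings (reference only; not a profile
# this package can train).  "learning_rate_kernel_std: 2" is recorded
# verbatim from the upstream configuration; its semantics are undefined
# here and it is not interpreted.
FULL_SCALE_SETTINGS: dict = {
    "diffusion": {"steps": 4000, "image_size": 256},
    "model": {"channels": 128, "attention_resolutions": [32, 16, 8],
              "use_fp16": True, "learning_rate_kernel_std": 2},
    "instagan": {"batch_size": 1, "filters": 64, "lr": 2e-4,
                 "lr_decay_after": 100, "load_size": 220, "fine_size": 200,
                 "dropout": False, "norm": "instance",
                 "augment": ["flip", "resize-crop"]},
}


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``, rejecting unknown keys."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {here} must be a mapping")
            out[key] = merge_config(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve a run config from defaults, an optional YAML file and overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = merge_config(cfg, loaded)
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg


_STAGES = ("simulate", "masks", "train", "inpaint", "evaluate")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from the single run seed.

    Stage ``i`` draws from SeedSequence(seed, spawn_key=(i,)), so changing
    only the seed changes every stage and repeating a seed reproduces all
    of them.
    """
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)
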