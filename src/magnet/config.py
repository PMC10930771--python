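"""YAML configuration: one file with model/attention/train/data sections."""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import MagNetConfig
from .train import TrainConfig

__all__ = [
    "default_config",
    "load_config",
    "make_model_config",
    "make_train_config",
    "save_config",
]


def default_config() -> dict:
    return {
        "model": {
            "layers": 3,
            "patches": [3, 2, 3],
            "frozen_patch": True,
            "backbone": "small-cnn",
            "branch_channels": 16,
            "backbone_channels": [16, 32, 64, 128],
            "gru_hidden": 256,
            "head_sizes": [512, 256],
        },
        "attention": {"k_aux": 8, "noise_sd": None, "grey_tau": 15},
        "train": {
            "lr": 3.0e-5,  # initial learning rate, cosine-annealed
            "epochs": 200,
            "batch_size": 16,  # use 8 for four-layer networks
            "seed": 0,
            "augment": True,
            "head_finetune_epochs": 0,  # desk-scale two-phase option
        },
        "data": {},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


def save_config(cfg: dict, path):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def make_model_config(cfg: dict) -> MagNetConfig:
    model = dict(cfg.get("model", {}))
    attention = cfg.get("attention", {})
    model["patches"] = tuple(model.get("patches", (3, 2, 3)))
    model["backbone_channels"] = tuple(
        model.get("backbone_channels", (16, 32, 64, 128))
    )
    model["head_sizes"] = tuple(model.get("head_sizes", (512, 256)))
    if model.get("aux_channels"):
        model["aux_channels"] = tuple(model["aux_channels"])
    for key in ("k_aux", "noise_sd", "grey_tau"):
        if key in attention:
            model[key] = attention[key]
    return MagNetConfig(**model)


def make_train_config(cfg: dict) -> TrainConfig:
    return TrainConfig(**cfg.get("train", {}))
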