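"""Configuration: built-in defaults < YAML file < explicit overrides."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Any

import yaml

from ..energy_select import EnergyParams, PredictConfig

DEFAULTS: dict[str, Any] = {
    "engine": "bruteforce",
    "max_dd": 2,
    "min_window": 6,
    "allow_gu": False,
    "min_loop": 0,
    "workers": os.cpu_count() or 1,
    "beta1": 9.6,
    "beta2": 0.1,
    "beta3": 0.1,
    "bp_mode": "core_stems",
}


def load_config(path: str | Path | None = None, **overrides: Any) -> dict[str, Any]:
    """Merge defaults, an optional YAML file and keyword overrides.

    Overrides with value ``None`` are ignored, so CLI options that were
    not given fall through to the file or the defaults.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg.update(loaded)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def to_predict_config(cfg: dict[str, Any]) -> PredictConfig:
    return PredictConfig(
        engine=cfg["engine"],
        max_dd=cfg["max_dd"],
        min_window=cfg["min_window"],
        allow_gu=cfg["allow_gu"],
        min_loop=cfg["min_loop"],
        workers=cfg["workers"],
        energy=EnergyParams(
            beta1=cfg["beta1"], beta2=cfg["beta2"], beta3=cfg["beta3"],
            bp_mode=cfg["bp_mode"],
        ),
    )
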