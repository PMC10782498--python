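"""Run configuration: a nested dict of every tunable parameter.

The YAML config file is the single source of parameters for a pipeline
run; CLI flags override individual keys and the effective configuration
is echoed into the run log so every threshold is auditable.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


DEFAULTS: dict[str, Any] = {
    "preprocess": {
        "bandpass": {"lo": 0.2, "hi": 200.0},
        "notch": {"enabled": True, "search_lo": 45.0, "search_hi": 65.0,
                  "threshold_ratio": 10.0, "q": 30.0},
        "artifact": {"enabled": True, "epoch_s": 2.0, "z_mult": 5.0},
    },
    "taper": {
        "f_lo": 11.0, "f_hi": 16.0, "f_step": 1.0,
        "min_cycles": 3.0, "max_cycles": 10.0, "support_s": 2.0,
    },
    "sde": {
        "collapse": "max",            # max | mean over taper frequencies
        "power": "root",              # root (p = sqrt|SDE|) | square
        "taper_norm": "amplitude",    # amplitude (L1 per taper) | none
        "norm_scope": "recording",    # recording | epoch
        "epoch_s": 30.0,
    },
    "detect": {
        "threshold": 0.5,
        "min_dur_s": 0.4,             # 0.5-s criterion with 0.1-s tolerance
        "max_dur_s": 2.0,
        "merge_gap_s": 0.10,
        "min_p2p_uv": 13.0,
        "boundary_peak_frac": 0.5,    # event spans its peak down to this fraction of it
        "boundary_floor_frac": 0.8,   # ... but never below this fraction of threshold
        "slow_fast_boundary_hz": 13.0,
    },
    "samc": {
        "min_channels": 2,
        "min_agreement": 0.25,
        "denominator": "each",        # each | shorter | longer
    },
    "metrics": {
        "min_overlap_s": 0.25,
        "pad_pre_s": 0.4,
        "pad_post_s": 1.2,
    },
}

#: Alternative duration window as tabulated in the spindle-parameter
#: definition (0.5–2.5 s) rather than the tolerance-adjusted window.
TABLE_DURATION_PRESET = {"min_dur_s": 0.5, "max_dur_s": 2.5}


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any] | None) -> dict[str, Any]:
    """Deep-merge *override* onto *base*, returning a new dict."""
    out = copy.deepcopy(dict(base))
    if not override:
        return out
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load YAML config over the defaults, then apply *overrides*."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = merge_config(cfg, loaded)
    cfg = merge_config(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: Mapping[str, Any]) -> None:
    det = cfg["detect"]
    if not (0.0 < det["threshold"] < 1.0):
        raise ConfigError("detect.threshold must be in (0, 1)")
    if det["min_dur_s"] >= det["max_dur_s"]:
        raise ConfigError("detect.min_dur_s must be below detect.max_dur_s")
    sm = cfg["samc"]
    if sm["min_channels"] < 2:
        raise ConfigError("samc.min_channels must be >= 2")
    if not (0.0 < sm["min_agreement"] <= 1.0):
        raise ConfigError("samc.min_agreement must be in (0, 1]")
    tp = cfg["taper"]
    if tp["f_lo"] >= tp["f_hi"]:
        raise ConfigError("taper.f_lo must be below taper.f_hi")
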