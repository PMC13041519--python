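"""Default run configuration and config-file handling.

The defaults embed the published goose/airliner application: escape speeds
1-17 m/s in 2 m/s steps, sensory-motor delays 0-1 s in 0.1 s steps, ten
evenly spaced distances-to-safety from 1 m to the 14.35-m stabilizer span,
fifteen approach speeds from 70.47 m/s (150 kt) to 270.97 m/s, ten light
temporal benefits from 0.5 to 8.5 s, three light scenarios and 500
Monte-Carlo iterations per parameter combination -- 222,750,000 predictions
in total.  A YAML config file overrides any subset of these keys.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "body_length": 1.15,  # goose beak-to-tail length, m
    "escape_speed": {"start": 1.0, "stop": 17.0, "count": 9},
    "delay": {"start": 0.0, "stop": 1.0, "count": 11},
    "d_min": {"start": 1.0, "stop": 14.35, "count": 10},
    "approach_speed": {"start": 70.47, "stop": 270.97, "count": 15},
    "beta": {"start": 0.5, "stop": 8.5, "count": 10},
    "iterations": 500,
    "scenarios": {
        "none": {"p_away": 0.42},
        "blue": {"p_away": 0.65},
        "red": {"p_away": 0.11},
    },
    "fid": {"mean": 56.2, "sd": 16.5},
    "mode": "expectation",  # or "bernoulli"
    "lateral_term": "sin",  # or "cos" (sensitivity variant)
    "alert_speed": "vehicle",  # or "animal"
    "silhouette": {"width_m": 14.35, "height_m": 4.3, "resolution": 1031},
}


def merge_config(base: dict, override: Optional[dict]) -> dict:
    """Deep-merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return merge_config(DEFAULT_CONFIG, override)
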