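"""YAML run configuration.

A single nested mapping drives every pipeline stage. Defaults reproduce
the canonical parameter set of the measures: 0.017 g count quantization,
+-0.068 g dead-band, 30 deg functional-space half-width, +-0.95
laterality thresholds, 0.25 s feature windows, 5-fold / 10-iteration
intra-subject cross-validation. Unknown keys are rejected so typos fail
loudly instead of silently running defaults.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "orientation": {
        "algorithm": "madgwick",
        "beta": 0.1,
        "kp": 1.0,
        "ki": 0.3,
        "rest_min_duration_s": 10.0,
        "rest_variance_threshold": 0.15,
    },
    "measures": {
        "deadband_g": 0.068,
        "count_step_g": 0.017,
        "gm_angle_threshold_deg": 30.0,
        "functional_pitch_deg": 30.0,
        "laterality_threshold": 0.95,
    },
    "ml": {
        "window_s": 0.25,
        "model": "rf",
        "scheme": "intra",
        "folds": 5,
        "iterations": 10,
        "entropy_bandwidth": 0.2,
        "include_gyro_features": False,
    },
    "evaluation": {
        "grid_rate_hz": 50.0,
    },
    "simulate": {
        "n_subjects": 15,
        "functional_share": None,
        "accel_noise_sd": 0.01,
        "gyro_noise_sd": 0.2,
        "annot_flip_prob": 0.02,
    },
}


def merge_config(overrides: dict | None) -> dict:
    """Merge user overrides onto the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULTS)
    if not overrides:
        return cfg
    _merge(cfg, overrides, path="")
    return cfg


def _merge(base: dict, overrides: dict, path: str) -> None:
    for key, value in overrides.items():
        here = f"{path}{key}"
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, path=f"{here}.")
        else:
            base[key] = value


def load_config(path=None) -> dict:
    """Load a YAML config file (or return defaults when path is None)."""
    if path is None:
        return merge_config(None)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return merge_config(data)
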