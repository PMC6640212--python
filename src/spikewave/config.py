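"""Declarative run configuration: one YAML file, CLI-overridable.

The configuration covers the synthetic dataset, the encoder, the network
preset and the training schedule, plus a single root seed from which all
randomness flows.  Unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "dataset": {
        "n_classes": 2,
        "samples_per_class": 100,
        "test_samples_per_class": 30,
        "image_size": 24,
        "noise_level": 0.05,
        "jitter": 2,
    },
    "encoder": {
        "window_size": 7,
        "clip_threshold": 0.01,
        "normalization_region": 9,
        "t_max": 15,
    },
    "network": {
        "in_features": 6,
        "features": [16, 32, 20],
        "thresholds": [40.0, 60.0],
    },
    "training": {
        "stdp_epochs": [2, 2],
        "rstdp_epochs": 20,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config on top of the defaults, then apply overrides."""
    config = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config
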