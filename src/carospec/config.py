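"""Default run configuration for the command-line interface.

One YAML document covers all stages; every method default that is a choice
of this package (rather than a physical constant) appears here so that a
deviation from the defaults is visible in the config file a run was started
with.
"""

from __future__ import annotations

import copy

import yaml

from .model import MLPConfig
from .preprocess import PreprocessParams

DEFAULTS: dict = {
    "simulate": {
        "maps_per_line": 4,
        "nx": 20,
        "ny": 20,
        "n_standards_per_class": [12, 11, 11],
    },
    "preprocess": {
        "arpls_lambda": 1e5,
        "arpls_ratio": 1e-6,
        "arpls_max_iter": 50,
        "spike_z_threshold": 6.0,
        "spike_window": 3,
        "outlier_method": "pearson_to_mean",
        "outlier_threshold": 0.9,
    },
    "peaks": {"k": 2, "tolerance": 5.0, "min_prominence": 0.05},
    "filter": {"despike_before_scoring": True},
    "representative": {"n_rep": 10, "fraction": 0.5},
    "model": {
        "n_features": 412,
        "hidden": [100, 10],
        "n_outputs": 3,
        "activation": "tanh",
        "optimizer": "lbfgs",
        "max_iter": None,
        "alpha": 0.1,
        "n_runs": 50,
        "k_folds": 5,
        "n_bins": 4,
    },
    "mapping": {"window": [1500.0, 1560.0], "statistic": "max"},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path=None) -> dict:
    """Defaults, deep-updated by an optional YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section in cfg and isinstance(values, dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def preprocess_params(cfg: dict) -> PreprocessParams:
    p = cfg["preprocess"]
    return PreprocessParams(
        arpls_lambda=p["arpls_lambda"],
        arpls_ratio=p["arpls_ratio"],
        arpls_max_iter=p["arpls_max_iter"],
        spike_z_threshold=p["spike_z_threshold"],
        spike_window=p["spike_window"],
        outlier_method=p["outlier_method"],
        outlier_threshold=p["outlier_threshold"],
    )


def mlp_config(cfg: dict, seed: int = 0) -> MLPConfig:
    m = cfg["model"]
    return MLPConfig(
        n_features=m["n_features"],
        hidden=tuple(m["hidden"]),
        n_outputs=m["n_outputs"],
        activation=m["activation"],
        optimizer=m["optimizer"],
        max_iter=m["max_iter"],
        alpha=m["alpha"],
        seed=seed,
    )


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)
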