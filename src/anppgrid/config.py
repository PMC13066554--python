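"""Run configuration: defaults, YAML/JSON loading, and seed derivation.

A run is driven by one nested mapping; every stage draws its randomness from
a per-stage stream derived from the single top-level seed, so reruns with the
same config are bit-identical.
"""

from __future__ import annotations

import copy
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "world": {
        "rows": 24,
        "cols": 24,
        "cell_size": 0.5,
        "year_start": 1958,
        "year_end": 2023,
        "baseline_start": 1970,
        "baseline_end": 2000,
        "mask_fraction": 0.85,
    },
    "sites": {"n_sites": 240, "obs_per_site": 1, "obs_noise_sd": 25.0},
    "cv": {"k": 5, "n_classes": 10},
    "compare": {
        "learners": ["linear", "svr", "random_forest", "ann", "bagged_trees", "xgboost"],
        "strategies": ["random", "spatial_block", "env_stratified"],
        "repeats": 3,
    },
    "tune": {"ntree": [200, 400], "mtry": [2, 4, 6], "repeats": 3},
    "train": {"n_models": 20},
    "scenario": {
        "models": ["MIROC6", "GFDL-ESM4", "MPI-ESM1-2-HR"],
        "scenarios": ["SSP245", "SSP585"],
        "future_start": 2015,
        "future_end": 2030,
        "coarsen": 2,
    },
    "validate": {"n_perm": 199, "reference_members": 3, "reference_noise_sd": 20.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Default config, optionally overlaid with a YAML/JSON file and a dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data:
            cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from the run seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
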