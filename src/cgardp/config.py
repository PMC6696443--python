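"""Layered run configuration: defaults < YAML file < command-line flags.

Every consumed key records where its value came from (``default``,
``file`` or ``flag``); unknown keys are rejected rather than ignored so a
typo in a config file fails loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "data": {"r": None, "d": None, "a": None},
    "cnn": {
        "filter_height": 3,
        "filter_width": 20,
        "n_filters": [16, 32],
        "padding_rows": 1,
        "padding_cols": 10,
        "pool_window": [2, 2],
        "fc_out_dim": 32,
        "mask_known": True,
    },
    "gru": {"hidden_dim": 32, "attention_dim": 32},
    "paths": {
        "path_max_len": 3,
        "path_cap": 8,
        "sim_threshold": 0.5,
        "exclude_direct": True,
    },
    "train": {
        "alpha1": 0.5,
        "dropout_rate": 0.5,
        "learning_rate": 1e-3,
        "epochs": 100,
        "batch_size": 32,
        "neg_ratio": 1.0,
        "seed": 0,
    },
    "eval": {
        "n_folds": 5,
        "seed": 0,
        "k_grid": [30, 60, 90, 120],
        "candidate_mode": "all_unknown",
    },
    "synth": {
        "n_drugs": 80,
        "n_diseases": 60,
        "n_blocks": 8,
        "within_block_sim": 0.7,
        "between_block_sim": 0.2,
        "sim_noise_sd": 0.1,
        "assoc_density_matched": 0.30,
        "assoc_density_unmatched": 0.02,
        "seed": 0,
    },
}


@dataclass
class RunConfig:
    values: dict[str, dict[str, Any]]
    provenance: dict[str, str] = field(default_factory=dict)

    def get(self, block: str, key: str) -> Any:
        return self.values[block][key]

    def block(self, name: str) -> dict[str, Any]:
        return dict(self.values[name])

    def hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def estimator_kwargs(self) -> dict[str, Any]:
        cnn, gru, paths, tr = (
            self.values["cnn"], self.values["gru"], self.values["paths"],
            self.values["train"],
        )
        return {
            "alpha1": tr["alpha1"],
            "dropout_rate": tr["dropout_rate"],
            "learning_rate": tr["learning_rate"],
            "epochs": tr["epochs"],
            "batch_size": tr["batch_size"],
            "filter_height": cnn["filter_height"],
            "filter_width": cnn["filter_width"],
            "n_filters": tuple(cnn["n_filters"]),
            "padding": (cnn["padding_rows"], cnn["padding_cols"]),
            "pool_window": tuple(cnn["pool_window"]),
            "fc_out_dim": cnn["fc_out_dim"],
            "mask_known": cnn["mask_known"],
            "hidden_dim": gru["hidden_dim"],
            "attention_dim": gru["attention_dim"],
            "path_max_len": paths["path_max_len"],
            "path_cap": paths["path_cap"],
            "sim_threshold": paths["sim_threshold"],
            "exclude_direct": paths["exclude_direct"],
            "random_state": tr["seed"],
        }


def load_config(
    path: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> RunConfig:
    """Merge defaults, an optional YAML file, and flat ``block.key`` overrides."""
    values = {b: dict(kv) for b, kv in DEFAULTS.items()}
    prov = {f"{b}.{k}": "default" for b, kv in DEFAULTS.items() for k in kv}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a mapping of blocks")
        for block, kv in loaded.items():
            if block not in values:
                raise KeyError(f"unknown config block {block!r}")
            if not isinstance(kv, dict):
                raise ValueError(f"config block {block!r} must be a mapping")
            for k, v in kv.items():
                if k not in values[block]:
                    raise KeyError(f"unknown config key {block}.{k}")
                values[block][k] = v
                prov[f"{block}.{k}"] = "file"
    for dotted, v in (overrides or {}).items():
        if v is None:
            continue
        block, _, k = dotted.partition(".")
        if block not in values or k not in values[block]:
            raise KeyError(f"unknown config key {dotted!r}")
        values[block][k] = v
        prov[dotted] = "flag"
    return RunConfig(values, prov)
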