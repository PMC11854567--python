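"""Dataset and configuration I/O.

Datasets are CSV files with a header; column roles (response / u_covariate /
instrument) are declared in the YAML run configuration.  Missing responses
are empty fields or "NA"; a missing value in any covariate column is an
error, since the covariates are assumed fully observed.

Configurations are YAML mappings validated against an explicit schema:
unknown keys are rejected before any computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .missing import MissingDataset

__all__ = ["ConfigError", "load_config", "read_dataset", "write_dataset", "write_json"]

_SCHEMA = {
    "model": {"family", "n_u", "n_z", "f", "h", "residual", "intercept_moment"},
    "missing": {"propensity", "d_function", "floor"},
    "penalty": {"family", "nu", "nu_beta", "nu_gamma", "scad_a", "grid_num", "grid_span", "strategy"},
    "inference": {"contrast", "value", "alpha", "method"},
    "simulate": {
        "experiment", "n", "p", "q", "f", "h", "mechanism", "reps", "estimator",
        "grid_num", "strategy", "ci_coord", "ci_method", "alpha", "n_jobs",
    },
    "data": {"path", "response", "u_covariates", "instruments"},
}
_TOP = set(_SCHEMA) | {"seed", "output"}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a YAML mapping")
    for key in cfg:
        if key not in _TOP:
            raise ConfigError(f"unknown configuration key: {key!r}")
        if key in _SCHEMA and isinstance(cfg[key], dict):
            for sub in cfg[key]:
                if sub not in _SCHEMA[key]:
                    raise ConfigError(f"unknown configuration key: {key}.{sub}")
    return cfg


_NA = {"", "NA", "NaN", "nan"}


def read_dataset(path: str | Path, config: dict) -> MissingDataset:
    """Read a CSV with declared column roles into a MissingDataset."""
    data_cfg = config.get("data", {})
    resp = data_cfg.get("response")
    u_cols = data_cfg.get("u_covariates", [])
    z_cols = data_cfg.get("instruments", [])
    if not resp or not u_cols or not z_cols:
        raise ConfigError("data.response, data.u_covariates and data.instruments are required")
    resp_cols = [resp] if isinstance(resp, str) else list(resp)
    df = pd.read_csv(path, na_values=list(_NA), keep_default_na=False)
    for col in resp_cols + list(u_cols) + list(z_cols):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} missing from {path}")
    for col in list(u_cols) + list(z_cols):
        if df[col].isna().any():
            raise ValueError(f"covariate column {col!r} has missing values; covariates must be fully observed")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"covariate column {col!r} is not numeric")
    Y = df[resp_cols].to_numpy(dtype=float)
    delta = np.all(np.isfinite(Y), axis=1).astype(int)
    if len(resp_cols) == 1:
        Y = Y[:, 0]
    U = df[list(u_cols)].to_numpy(dtype=float)
    Z = df[list(z_cols)].to_numpy(dtype=float)
    return MissingDataset(Y=Y, U=U, Z=Z, delta=delta)


def write_dataset(path: str | Path, dataset: MissingDataset, response_name: str = "y") -> None:
    Y = dataset.Y if dataset.Y.ndim == 2 else dataset.Y[:, None]
    cols = {}
    for j in range(Y.shape[1]):
        name = response_name if Y.shape[1] == 1 else f"{response_name}{j + 1}"
        cols[name] = Y[:, j]
    for j in range(dataset.U.shape[1]):
        cols[f"u{j + 1}"] = dataset.U[:, j]
    for j in range(dataset.Z.shape[1]):
        cols[f"z{j + 1}"] = dataset.Z[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="NA")


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
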