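"""Configuration, table and provenance input/output.

All tables are delimited text with header rows; every output directory
gets a ``provenance.json`` sidecar carrying the exact parameters, seed
and package version needed to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .params import RatchetParams
from .simulate import Trajectory

PACKAGE_VERSION = "0.1.0"

_PARAM_KEYS = {f.name for f in dataclasses.fields(RatchetParams)}


def load_config(path) -> dict:
    """Flat key-value YAML config; unknown ratchet keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    unknown = set(cfg) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def params_from_config(path, **overrides) -> RatchetParams:
    cfg = load_config(path)
    cfg.update(overrides)
    return RatchetParams(**cfg)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization table (CSV or TSV) with named columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"frame", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing localization columns {sorted(missing)}")
    return df


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": traj.t,
            "x": traj.x,
            "x_S": traj.x_S,
            "x_G": traj.x_G,
            "bound": traj.bound.astype(int),
        }
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Tabular trajectory plus a JSON sidecar of parameters and seed."""
    path = Path(path)
    write_table(trajectory_frame(traj), path)
    sidecar = path.with_suffix(".json")
    payload = {
        "params": dataclasses.asdict(traj.params),
        "scenario": dataclasses.asdict(traj.scenario),
        "seed": traj.seed,
        "first_escape": None if np.isnan(traj.first_escape) else traj.first_escape,
        "censored": traj.censored,
        "version": PACKAGE_VERSION,
    }
    sidecar.write_text(json.dumps(payload, indent=2))


def write_provenance(out_dir, subcommand: str, options: dict, seed: Optional[int]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "subcommand": subcommand,
        "options": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in options.items()},
        "seed": seed,
        "version": PACKAGE_VERSION,
    }
    (out_dir / "provenance.json").write_text(json.dumps(payload, indent=2, default=str))
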