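"""Cohort/config/result I/O and run manifests.

Cohorts travel as plain UTF-8 CSV with header ``Y,Tobs,X1..Xp`` and
optional ``T_true`` and ``validated`` columns (omitted, never blank, when
absent). Configs are YAML key-value files mirroring the dataclass field
names. Every CLI run writes a manifest (YAML) recording the command, the
config snapshot, the seeds, the package version, and the output paths, so
any result file is regenerable from its manifest alone.
"""

from __future__ import annotations

import datetime
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import ModelSpec, NNConfig
from .simdata import Cohort, ScenarioConfig, scenario_config

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_config",
    "scenario_from_config",
    "modelspec_from_config",
    "write_results",
    "RunManifest",
]

_REQUIRED = ("Y", "Tobs")


def _check_binary(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = df[col].to_numpy()
    bad = ~np.isin(vals, [0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"column {col!r} must be binary; found {vals[row]!r} at row {row}"
        )
    return vals.astype(int)


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    xcols = sorted(
        (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing or not xcols:
        raise ValueError(
            f"cohort file {path} is missing required columns: "
            f"{missing + ([] if xcols else ['X1..Xp'])}"
        )
    for c in list(_REQUIRED) + xcols:
        if df[c].isna().any():
            row = int(df[c].isna().idxmax())
            raise ValueError(f"missing value in required column {c!r} at row {row}")
    tobs = _check_binary(df, "Tobs")
    t_true = _check_binary(df, "T_true") if "T_true" in df.columns else None
    validated = _check_binary(df, "validated") if "validated" in df.columns else None
    return Cohort(
        Y=df["Y"].to_numpy(dtype=float),
        Tobs=tobs,
        X=df[xcols].to_numpy(dtype=float),
        T_true=t_true,
        validated=validated,
    )


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def scenario_from_config(cfg: dict, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from a config mapping's ``scenario`` section
    (or the top level), with keyword overrides winning."""
    section = dict(cfg.get("scenario", cfg))
    section.update({k: v for k, v in overrides.items() if v is not None})
    sid = section.pop("scenario_id", "custom")
    for key in ("me_eta", "ps_beta", "outcome_gamma"):
        if key in section:
            section[key] = tuple(section[key])
    return scenario_config(sid, **section)


def modelspec_from_config(cfg: dict, **overrides) -> ModelSpec:
    section = dict(cfg.get("model", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("x1_cols", "x2_cols", "x3_cols"):
        if section.get(key) is not None:
            section[key] = tuple(section[key])
    if "nn_config" in section and isinstance(section["nn_config"], dict):
        section["nn_config"] = NNConfig(**section["nn_config"])
    return ModelSpec(**section)


@dataclass
class RunManifest:
    command: str
    seed: Optional[int]
    config: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_results(df: pd.DataFrame, path, manifest: Optional[RunManifest] = None) -> None:
    """Write a result table as CSV with stable column order, plus an
    adjacent ``<name>.manifest.yaml`` when a manifest is given."""
    path = Path(path)
    df.to_csv(path, index=False)
    if manifest is not None:
        manifest.outputs = sorted(set(manifest.outputs + [str(path)]))
        manifest.write(path.with_suffix(".manifest.yaml"))
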