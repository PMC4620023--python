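"""CSV readers/writers and run configuration.

Dialects
--------
Concentration CSV: header ``time_h,conc_ug_ml[,replicate][,arm]``.  Rows
with a replicate column are grouped by (arm, time) and averaged; duplicate
(time, replicate) keys within an arm are an error.

Release CSV: header ``time_h,released_pct[,label]``; one profile per label.

All validation errors carry 1-based data row numbers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .profiles import ConcProfile, ReleaseProfile
from .synthetic import pool_replicates

__all__ = [
    "RunConfig",
    "read_conc_csv",
    "read_release_csv",
    "write_table",
]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:5])
        raise ValueError(f"{path}: non-numeric {col!r} in data row(s) {rows}")
    return vals.to_numpy(dtype=float)


def read_conc_csv(path) -> dict[str, ConcProfile]:
    """Read concentration profiles, one per arm, pooling replicates."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_h", "conc_ug_ml"], path)
    times = _numeric(df, "time_h", path)
    concs = _numeric(df, "conc_ug_ml", path)
    neg = np.nonzero(concs < 0)[0]
    if neg.size:
        raise ValueError(
            f"{path}: negative concentration in data row {neg[0] + 1}"
        )
    df = df.assign(time_h=times, conc_ug_ml=concs)
    if "arm" not in df.columns:
        df["arm"] = ""
    if "replicate" in df.columns:
        dup = df.duplicated(subset=["arm", "time_h", "replicate"])
        if dup.any():
            row = int(np.nonzero(dup.to_numpy())[0][0]) + 1
            raise ValueError(f"{path}: duplicate (time, replicate) key at data row {row}")
    out: dict[str, ConcProfile] = {}
    for arm, grp in df.groupby("arm", sort=False):
        if not grp["time_h"].is_monotonic_increasing:
            warnings.warn(f"{path}: times out of order for arm {arm!r}; sorting")
        if "replicate" in grp.columns:
            wide = grp.pivot_table(
                index="time_h", columns="replicate", values="conc_ug_ml"
            ).sort_index()
            out[str(arm)] = pool_replicates(
                wide.index.to_numpy(), wide.to_numpy(), arm=str(arm)
            )
        else:
            grp = grp.sort_values("time_h")
            out[str(arm)] = ConcProfile(
                times=grp["time_h"].to_numpy(),
                concentrations=grp["conc_ug_ml"].to_numpy(),
                arm=str(arm),
            )
    return out


def read_release_csv(path) -> dict[str, ReleaseProfile]:
    """Read cumulative-release profiles, one per label."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_h", "released_pct"], path)
    times = _numeric(df, "time_h", path)
    rel = _numeric(df, "released_pct", path)
    df = df.assign(time_h=times, released_pct=rel)
    if "label" not in df.columns:
        df["label"] = ""
    out: dict[str, ReleaseProfile] = {}
    for label, grp in df.groupby("label", sort=False):
        if not grp["time_h"].is_monotonic_increasing:
            warnings.warn(f"{path}: times out of order for label {label!r}; sorting")
        grp = grp.sort_values("time_h")
        out[str(label)] = ReleaseProfile(
            times=grp["time_h"].to_numpy(),
            released=grp["released_pct"].to_numpy(),
            label=str(label),
        )
    return out


def write_table(df: pd.DataFrame, path, *, sig_figs: int = 4) -> None:
    """Write a result table as CSV (rounded for display) and JSON (full).

    The CSV shows ``sig_figs`` significant figures to mirror summary-table
    style; the sibling ``.json`` file keeps full double precision.
    """
    path = Path(path)

    def _fmt(x):
        if isinstance(x, (int, np.integer)) or not isinstance(x, (float, np.floating)):
            return x
        return float(f"{x:.{sig_figs}g}") if np.isfinite(x) else x

    df.map(_fmt).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=2, default=str)
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    Two modes exist: *data mode* reads full profiles from CSV paths; in
    *summary mode* printed per-arm summary parameters (ka, ke, cmax,
    auc_0_24, optionally auc_0_inf and dose) replace raw concentration
    data, which is how headline tables are reproduced when raw profiles
    were never published.
    """

    mic90_ug_ml: float = 1.22
    threshold_multiplier: float = 2.0
    horizon_h: float = 75.0
    window_h: float = 24.0
    n_terminal: int = 3
    seed: int = 0
    release_csv: Optional[str] = None
    conc_csv: Optional[str] = None
    release_fit_window: Optional[tuple] = (0.0, 10.0)
    test_arm: str = "test"
    reference_arm: str = "reference"
    # summary mode: {arm: {"ka":..., "ke":..., "cmax":..., "auc_0_24":...,
    #                      "auc_0_inf":..., "dose": ...}}
    summary: Optional[dict] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("mic90_ug_ml", "threshold_multiplier", "horizon_h", "window_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("release_csv", "conc_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name}: no such file {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        if "release_fit_window" in data and data["release_fit_window"] is not None:
            data["release_fit_window"] = tuple(data["release_fit_window"])
        return cls(**data)
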