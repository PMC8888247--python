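"""Readers/writers for the tidy CSV tables and YAML configuration.

All tabular artifacts are long-format CSV.  Writers prepend ``#`` comment
lines documenting column units; readers skip them.  Schema violations
raise :class:`SchemaError` naming the offending column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .design import ExperimentDesign, SimulationParams
from .simulate import OBS_COLUMNS

TIMESERIES_REQUIRED = ("day", "replicate", "treatment", "chl_total")
TIMESERIES_NUMERIC = (
    "day", "chl_total", "chl_cyano", "chl_green", "chl_diatom",
    "po4", "din", "biovolume",
)
TIMESERIES_UNITS = {
    "day": "days from experiment start (day 0 = first sample)",
    "chl_total": "ug Chl-a/L",
    "chl_cyano": "ug Chl-a/L", "chl_green": "ug Chl-a/L",
    "chl_diatom": "ug Chl-a/L",
    "po4": "ug P/L dissolved orthophosphate",
    "din": "ug N/L dissolved inorganic nitrogen (NH4+NO2+NO3)",
    "biovolume": "um^3/ml",
}

WINDOWS_COLUMNS = (
    "cycle_id", "replicate_id", "treatment_label", "c0", "c0_window_start",
    "c0_window_end", "c0_variance", "peak_value", "peak_day", "dx_level",
    "dx_window_start", "dx_window_end", "recovered_flag",
)
METRICS_COLUMNS = (
    "cycle_id", "replicate_id", "treatment_label", "pulse_intensity",
    "c0", "peak", "d0", "dx", "rs_raw", "rc_raw", "rs_scaled", "rc_scaled",
    "degenerate",
)


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_timeseries(path) -> pd.DataFrame:
    """Read and validate a mesocosm timeseries table."""
    df = _read_csv(path)
    for col in TIMESERIES_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"timeseries file missing required column {col!r}")
    for col in TIMESERIES_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"non-numeric values in column {col!r}") from exc
    dup = df.duplicated(subset=["treatment", "replicate", "day"])
    if dup.any():
        first = df.loc[dup, ["treatment", "replicate", "day"]].iloc[0]
        raise SchemaError(
            "duplicate replicate x day rows, first at "
            f"{first['treatment']}/{first['replicate']} day {first['day']}"
        )
    neg_cols = [c for c in TIMESERIES_NUMERIC if c != "day" and c in df.columns]
    for col in neg_cols:
        if (df[col].dropna() < 0).any():
            raise SchemaError(f"negative concentrations in column {col!r}")
    return df.sort_values(["treatment", "replicate", "day"]).reset_index(drop=True)


def write_timeseries(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# presspulse mesocosm timeseries (long format)\n")
        for col in df.columns:
            if col in TIMESERIES_UNITS:
                fh.write(f"# {col}: {TIMESERIES_UNITS[col]}\n")
        df.to_csv(fh, index=False)


def read_windows(path) -> pd.DataFrame:
    df = _read_csv(path)
    for col in WINDOWS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"windows file missing required column {col!r}")
    return df


def write_windows(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# presspulse response windows: one row per replicate x cycle; "
                 "levels in ug Chl-a/L, days from experiment start\n")
        df.to_csv(fh, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = _read_csv(path)
    for col in METRICS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"metrics file missing required column {col!r}")
    return df


def write_metrics(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# presspulse perturbation metrics: D0/Dx in ug Chl-a/L; "
                 "rs/rc raw in (-1,1], rescaled on [0,10]\n")
        df.to_csv(fh, index=False)


_CONFIG_KEYS = {"design", "simulation", "thresholds", "paths", "seed", "verbosity"}


def load_config(path) -> dict:
    """Load a pipeline YAML config; unknown top-level keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(raw)
    if "design" in cfg and cfg["design"] is not None:
        cfg["design"] = ExperimentDesign.from_dict(cfg["design"])
    else:
        cfg["design"] = ExperimentDesign.default()
    sim = dict(cfg.get("simulation") or {})
    if "seed" in cfg and cfg["seed"] is not None:
        if not isinstance(cfg["seed"], int):
            raise SchemaError("seed must be an integer")
        sim["seed"] = cfg["seed"]
    cfg["simulation"] = SimulationParams.from_dict(sim)
    cfg.setdefault("thresholds", {})
    cfg.setdefault("paths", {})
    return cfg


def save_config(cfg: dict, path) -> None:
    out = dict(cfg)
    if isinstance(out.get("design"), ExperimentDesign):
        out["design"] = out["design"].to_dict()
    if isinstance(out.get("simulation"), SimulationParams):
        out["simulation"] = out["simulation"].to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
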