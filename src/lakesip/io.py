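"""CSV readers/writers for the pipeline's tabular formats, plus provenance.

All tables are UTF-8 CSV with a one-line header. Headers are matched
case-insensitively and order-insensitively against a named schema; row-level
validation failures are collected and reported together with their row
indices rather than one at a time. Unit columns (``time_unit``,
``conc_unit``) are converted to the internal units (days, nmol l^-1) at read
time; computational modules never see anything else.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bulk import EndpointPair, IncubationSeries
from .config import Config
from .singlecell import CellCensus

#: Accepted unit declarations and their conversion factors to internal units.
TIME_UNITS = {"d": 1.0, "h": 1.0 / 24.0}
CONC_UNITS = {"nmol/l": 1.0, "umol/l": 1000.0}


@dataclass
class ColumnSpec:
    name: str
    dtype: str  # "str" or "float"
    check: Callable[[pd.Series], pd.Series] | None = None  # returns bool mask of BAD rows
    message: str = ""


def _nonneg(s: pd.Series) -> pd.Series:
    return s < 0


def _positive(s: pd.Series) -> pd.Series:
    return s <= 0


def _fraction(s: pd.Series) -> pd.Series:
    return (s < 0) | (s > 1)


SCHEMAS: dict[str, list[ColumnSpec]] = {
    "incubation_series": [
        ColumnSpec("sample_id", "str"),
        ColumnSpec("depth_m", "float"),
        ColumnSpec("temperature_c", "float"),
        ColumnSpec("replicate", "str"),
        ColumnSpec("time", "float", _nonneg, "negative time"),
        ColumnSpec("time_unit", "str"),
        ColumnSpec("n15_no2", "float", _nonneg, "negative concentration"),
        ColumnSpec("conc_unit", "str"),
        ColumnSpec("f15n", "float", _fraction, "labeling fraction outside [0, 1]"),
    ],
    "endpoint": [
        ColumnSpec("sample_id", "str"),
        ColumnSpec("element", "str"),
        ColumnSpec("replicate", "str"),
        ColumnSpec("pool_umol_l", "float", _positive, "pool must be positive"),
        ColumnSpec("x0", "float", _fraction, "atom fraction outside [0, 1]"),
        ColumnSpec("x_end", "float", _fraction, "atom fraction outside [0, 1]"),
        ColumnSpec("f_label", "float", _fraction, "labeling fraction outside [0, 1]"),
        ColumnSpec("duration_d", "float", _positive, "duration must be positive"),
    ],
    "cells": [
        ColumnSpec("cell_id", "str"),
        ColumnSpec("sample_id", "str"),
        ColumnSpec("group", "str"),
        ColumnSpec("counts_major_c", "float", _nonneg, "negative ion count"),
        ColumnSpec("counts_minor_c", "float", _nonneg, "negative ion count"),
        ColumnSpec("counts_major_n", "float", _nonneg, "negative ion count"),
        ColumnSpec("counts_minor_n", "float", _nonneg, "negative ion count"),
    ],
    "census": [
        ColumnSpec("sample_id", "str"),
        ColumnSpec("group", "str"),
        ColumnSpec("cells_per_ml", "float", _nonneg, "negative cell density"),
    ],
    "temperature": [
        ColumnSpec("process", "str"),
        ColumnSpec("temperature_c", "float"),
        ColumnSpec("replicate", "str"),
        ColumnSpec("rate", "float", _nonneg, "negative rate"),
    ],
}


class TableValidationError(ValueError):
    """Raised with every offending row listed, not just the first."""

    def __init__(self, path: str | Path, problems: list[str]):
        self.problems = problems
        super().__init__(f"{path}: " + "; ".join(problems))


def read_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read and validate one CSV table against a named schema.

    Header matching is case- and order-insensitive; extra columns are kept.
    Numeric columns are parsed as floats, unit columns are applied (times to
    days, concentrations to nmol l^-1) and then dropped. All problems are
    collected into one :class:`TableValidationError`.
    """
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path} (expected a {schema_id!r} table)")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    specs = SCHEMAS[schema_id]
    problems: list[str] = []
    missing = [s.name for s in specs if s.name not in df.columns]
    if missing:
        raise TableValidationError(path, [f"missing required column(s): {missing}"])
    for spec in specs:
        if spec.dtype == "float":
            parsed = pd.to_numeric(df[spec.name], errors="coerce")
            bad = parsed.isna() & df[spec.name].notna()
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx}: unparseable number {df.at[idx, spec.name]!r} in {spec.name}"
                )
            df[spec.name] = parsed
            if spec.check is not None:
                viol = spec.check(parsed.fillna(0.0)) & ~bad
                for idx in df.index[viol]:
                    problems.append(f"row {idx}: {spec.message} in {spec.name}")
        else:
            df[spec.name] = df[spec.name].astype(str).str.strip()
    if schema_id == "incubation_series" and not problems:
        for unit_col, value_col, table in (
            ("time_unit", "time", TIME_UNITS),
            ("conc_unit", "n15_no2", CONC_UNITS),
        ):
            units = df[unit_col].str.lower()
            unknown = ~units.isin(table)
            for idx in df.index[unknown]:
                problems.append(f"row {idx}: unknown unit {df.at[idx, unit_col]!r} in {unit_col}")
            if not unknown.any():
                df[value_col] = df[value_col] * units.map(table)
        df = df.drop(columns=["time_unit", "conc_unit"])
    if problems:
        raise TableValidationError(path, problems)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with a deterministic float format."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def series_from_table(df: pd.DataFrame) -> list[IncubationSeries]:
    """Group a validated incubation_series table into per-bottle series."""
    out = []
    for (sample_id, replicate), sub in df.groupby(["sample_id", "replicate"], sort=True):
        sub = sub.sort_values("time")
        out.append(
            IncubationSeries(
                sample_id=str(sample_id),
                depth=float(sub["depth_m"].iloc[0]),
                temperature=float(sub["temperature_c"].iloc[0]),
                replicate=str(replicate),
                times=sub["time"].to_numpy(),
                n15_nitrite=sub["n15_no2"].to_numpy(),
                f15n=float(sub["f15n"].iloc[0]),
            )
        )
    return out


def endpoints_from_table(df: pd.DataFrame) -> list[EndpointPair]:
    """Turn a validated endpoint table into EndpointPair objects."""
    return [
        EndpointPair(
            sample_id=str(row.sample_id),
            element=str(row.element),
            replicate=str(row.replicate),
            pool=float(row.pool_umol_l),
            x0=float(row.x0),
            x_end=float(row.x_end),
            f_label=float(row.f_label),
            duration=float(row.duration_d),
        )
        for row in df.itertuples()
    ]


def census_from_table(df: pd.DataFrame) -> CellCensus:
    """Build a CellCensus from a census table (dapi + aoa rows per sample)."""
    pivot = df.pivot_table(index="sample_id", columns="group", values="cells_per_ml")
    pivot.columns = [c.lower() for c in pivot.columns]
    for needed in ("dapi", "aoa"):
        if needed not in pivot.columns:
            raise TableValidationError("census", [f"missing group {needed!r}"])
    first = pivot.iloc[0]
    return CellCensus(
        sample_id=str(pivot.index[0]),
        dapi_density=float(first["dapi"]),
        aoa_density=float(first["aoa"]),
    )


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def make_provenance(
    config: Config,
    inputs: Mapping[str, str | Path],
    stage_seeds: Mapping[str, int],
) -> dict:
    """Everything needed to re-run an output bit-identically.

    The timestamp is informational; determinism rests on the config snapshot
    (every defaulted constant included), input digests and per-stage seeds.
    """
    return {
        "software": {"name": "lakesip", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "inputs": {k: file_digest(v) for k, v in sorted(inputs.items())},
        "stage_seeds": dict(sorted(stage_seeds.items())),
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
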