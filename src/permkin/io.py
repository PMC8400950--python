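"""CSV readers/writers, report rendering and schema checks.

File dialect is deliberately rigid for reproducibility: comma-separated,
dot decimal, UTF-8, mandatory header.  Time is always hours in files;
Table-style PK reports additionally render t_max in minutes.

Permeation files carry either raw receptor samples (``time_h``,
``conc_ug_per_ml``) or a pre-reduced cumulative series (``time_h``,
``q_ug_per_cm2``); PK profiles carry ``time_h``, ``conc``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .diffusion import DiffusionFit, InputError, PermeationSeries
from .franz import SamplingRecord
from .targeting import PKProfile, TargetingMetrics

__all__ = [
    "ParseError",
    "read_timeseries_csv",
    "read_permeation_csv",
    "read_pk_csv",
    "write_sampling_record",
    "write_permeation_series",
    "write_pk_profile",
    "fit_report_dict",
    "targeting_report_dict",
    "targeting_report_frame",
    "write_report",
    "validate_report",
    "FIT_REPORT_SCHEMA",
    "TARGETING_REPORT_SCHEMA",
]


class ParseError(InputError):
    """Malformed input file; the message names the offending row."""


def _read_columns(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r} "
                             f"(found {list(df.columns)})")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise ParseError(f"{path}: non-numeric or empty value in column "
                             f"{col!r} at row {row}")
        df[col] = numeric
    t = df[required[0]].to_numpy()
    drop = np.flatnonzero(np.diff(t) <= 0)
    if drop.size:
        row = int(drop[0]) + 3  # the later of the offending pair, 1-based
        raise ParseError(f"{path}: time_h not strictly increasing at row {row}")
    return df


def read_permeation_csv(path: str | Path) -> SamplingRecord | PermeationSeries:
    """Read a permeation file; the column set decides raw vs pre-reduced."""
    head = pd.read_csv(path, nrows=0)
    if "q_ug_per_cm2" in head.columns:
        df = _read_columns(path, ("time_h", "q_ug_per_cm2"))
        return PermeationSeries(times=df["time_h"].to_numpy(),
                                cumulative_Q=df["q_ug_per_cm2"].to_numpy())
    df = _read_columns(path, ("time_h", "conc_ug_per_ml"))
    return SamplingRecord(times=df["time_h"].to_numpy(),
                          measured_conc=df["conc_ug_per_ml"].to_numpy())


def read_pk_csv(path: str | Path, matrix: str, route: str) -> PKProfile:
    df = _read_columns(path, ("time_h", "conc"))
    return PKProfile(matrix=matrix, route=route,
                     times=df["time_h"].to_numpy(),
                     concentrations=df["conc"].to_numpy())


def read_timeseries_csv(
    path: str | Path,
    kind: str = "permeation",
    matrix: str = "blood",
    route: str = "intranasal",
) -> SamplingRecord | PermeationSeries | PKProfile:
    """Parse a time-series CSV as a permeation record/series or a PK profile."""
    if kind == "permeation":
        return read_permeation_csv(path)
    if kind == "pk":
        return read_pk_csv(path, matrix=matrix, route=route)
    raise InputError(f"kind must be 'permeation' or 'pk', got {kind!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_sampling_record(record: SamplingRecord, path: str | Path) -> None:
    pd.DataFrame({"time_h": record.times, "conc_ug_per_ml": record.measured_conc}
                 ).to_csv(path, index=False)


def write_permeation_series(series: PermeationSeries, path: str | Path) -> None:
    pd.DataFrame({"time_h": series.times, "q_ug_per_cm2": series.cumulative_Q}
                 ).to_csv(path, index=False)


def write_pk_profile(profile: PKProfile, path: str | Path) -> None:
    pd.DataFrame({"time_h": profile.times, "conc": profile.concentrations}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

FIT_REPORT_SCHEMA: dict[str, type] = {
    "D_cm2_per_h": float,
    "K": float,
    "J_ss_ug_per_cm2_h": float,
    "P_app_cm_per_h": float,
    "t_lag_h": float,
    "D_from_Papp_cm2_per_h": float,
    "window_start": int,
    "window_stop": int,
    "r_squared": float,
    "residual_sse": float,
    "converged": bool,
    "weak_identifiability": bool,
}

TARGETING_REPORT_SCHEMA: dict[str, type] = {
    "auc_brain_intranasal": float,
    "auc_blood_intranasal": float,
    "auc_brain_intravenous": float,
    "auc_blood_intravenous": float,
    "Bx": float,
    "dte_pct": float,
    "dtp_pct": float,
    "nasal_bioavailability_pct": float,
    "bioavailability_matrix": str,
}


def fit_report_dict(fit: DiffusionFit) -> dict[str, Any]:
    return {
        "D_cm2_per_h": float(fit.params.D),
        "K": float(fit.params.K),
        "J_ss_ug_per_cm2_h": float(fit.J_ss),
        "P_app_cm_per_h": float(fit.P_app),
        "t_lag_h": float(fit.t_lag),
        "D_from_Papp_cm2_per_h": float(fit.D_from_Papp),
        "window_start": int(fit.linear_window[0]),
        "window_stop": int(fit.linear_window[1]),
        "r_squared": float(fit.regression.r_squared) if fit.regression else float("nan"),
        "residual_sse": float(fit.residual_sse),
        "converged": bool(fit.converged),
        "weak_identifiability": bool(fit.weak_identifiability),
    }


def targeting_report_dict(metrics: TargetingMetrics) -> dict[str, Any]:
    return {
        "auc_brain_intranasal": float(metrics.Bin),
        "auc_blood_intranasal": float(metrics.Pin),
        "auc_brain_intravenous": float(metrics.Biv),
        "auc_blood_intravenous": float(metrics.Piv),
        "Bx": float(metrics.Bx),
        "dte_pct": float(metrics.dte_pct),
        "dtp_pct": float(metrics.dtp_pct),
        "nasal_bioavailability_pct": float(metrics.nasal_bioavailability_pct),
        "bioavailability_matrix": metrics.bioavailability_matrix,
    }


def targeting_report_frame(metrics: TargetingMetrics) -> pd.DataFrame:
    """Table-style per-profile report: Cmax, Tmax (min), AUC per matrix/route."""
    rows = []
    for (matrix, route), nca in (metrics.nca or {}).items():
        rows.append({
            "matrix": matrix,
            "route": route,
            "c_max": nca.c_max,
            "t_max_min": nca.t_max * 60.0,
            "auc_0_t": nca.auc_0_t,
        })
    return pd.DataFrame(rows)


def validate_report(report: Mapping[str, Any], schema: Mapping[str, type]) -> None:
    """Check a report dict against its shipped schema (keys and types)."""
    missing = sorted(set(schema) - set(report))
    extra = sorted(set(report) - set(schema))
    if missing or extra:
        raise InputError(f"report schema mismatch: missing={missing} extra={extra}")
    for key, typ in schema.items():
        value = report[key]
        if typ is float and isinstance(value, (int, float)) and not isinstance(value, bool):
            continue
        if not isinstance(value, typ):
            raise InputError(f"report field {key!r} should be {typ.__name__}, "
                             f"got {type(value).__name__}")


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Write a flat report as JSON (.json) or single-row CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(dict(report), indent=2) + "\n")
    elif path.suffix == ".csv":
        pd.DataFrame([dict(report)]).to_csv(path, index=False)
    else:
        raise InputError(f"unsupported report extension {path.suffix!r}")
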