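"""File formats: time-series CSV dialect, feed-schedule configs, reports.

The CSV dialect is one row per sample with header
``time_h,volume_L,glycerol_g_L,hpa_g_L,hp_g_L,pdo_g_L[,scavenger_g_L,hpa_complex_g_L]``,
decimal point, UTF-8.  Feed schedules are YAML or JSON lists of
``{start_h, end_h, feed_conc_g_L, feed_rate_mL_h}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .rates import _REQUIRED_COLUMNS, FeedStep, TimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_schedule",
    "write_schedule",
    "write_step_reports",
    "format_report_table",
]


def read_timeseries(path, mode: str = "fedbatch", biomass: float = 6.0) -> TimeSeries:
    """Read a sampled reactor time series from the CSV dialect.

    Malformed rows are reported with their line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if not c.endswith(("_h", "_L", "_g_L"))]
    if extra:
        raise ValueError(f"{path}: unknown columns {extra}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric value on line {line}")
    return TimeSeries(numeric, mode=mode, biomass=biomass)


def write_timeseries(series: TimeSeries, path) -> None:
    series.data.to_csv(path, index=False)


def _schedule_from_records(records) -> list[FeedStep]:
    steps = []
    for rec in records:
        steps.append(
            FeedStep(
                t_start=float(rec["start_h"]),
                t_end=float(rec["end_h"]),
                feed_conc_g_L=float(rec["feed_conc_g_L"]),
                feed_rate_L_h=float(rec["feed_rate_mL_h"]) / 1000.0,
            )
        )
    return steps


def read_schedule(path) -> list[FeedStep]:
    """Read a feed schedule from YAML or JSON (by extension)."""
    path = Path(path)
    with open(path) as fh:
        records = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(records, list):
        raise ValueError(f"{path}: schedule must be a list of feed steps")
    return _schedule_from_records(records)


def write_schedule(schedule: Sequence[FeedStep], path) -> None:
    records = [
        {
            "start_h": s.t_start,
            "end_h": s.t_end,
            "feed_conc_g_L": s.feed_conc_g_L,
            "feed_rate_mL_h": s.feed_rate_L_h * 1000.0,
        }
        for s in schedule
    ]
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(records, fh, indent=2)
        else:
            yaml.safe_dump(records, fh, sort_keys=False)


def format_report_table(reports) -> str:
    """Step-by-rate table, rates to one decimal, columns in q_S..q_1,3PDO order."""
    lines = ["step  feed_g_h      q_S   q_3HPA    q_3HP  q_1,3PDO"]
    for r in reports:
        d = r.to_dict()
        lines.append(
            f"{d['step_index']:>4}  {d['feed_g_h']:>8.2f}  {d['q_S']:>7.1f}  "
            f"{d['q_3HPA']:>7.1f}  {d['q_3HP']:>7.1f}  {d['q_1,3PDO']:>8.1f}"
        )
    return "\n".join(lines)


def write_step_reports(reports, csv_path, json_path) -> None:
    """Write the step flux table (CSV, 1 decimal) and full-precision JSON."""
    rows = []
    for r in reports:
        d = r.to_dict()
        rows.append(
            {
                "step": d["step_index"],
                "feed_g_h": round(d["feed_g_h"], 3),
                "q_S": round(d["q_S"], 1),
                "q_3HPA": round(d["q_3HPA"], 1),
                "q_3HP": round(d["q_3HP"], 1),
                "q_1,3PDO": round(d["q_1,3PDO"], 1),
            }
        )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
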