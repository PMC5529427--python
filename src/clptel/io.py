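"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular exchange uses plain UTF-8 CSV (RFC-4180, '.' decimal):

* traces — long format with columns ``mouse_id, time_min, heart_rate_bpm,
  core_temp_c, activity`` (``activity`` optional);
* cohorts — ``mouse_id, time_to_criteria_min, censored, season,
  ambient_temp_c``;
* capture tables / seasonal summaries / equivalency tables — shaped like
  the study's published tables.

Floats are serialized with Python's shortest round-trip repr, so
write-then-read is lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cost import CostParameters, equivalency_quality_mice
from .detect import DeteriorationCriteria, detect_cohort
from .errors import ParseError
from .outcomes import MouseOutcome
from .simulate import SimulationParams, fixture_cohort_table1, simulate_cohort
from .trace import TelemetryTrace
from .variability import (
    CaptureTable,
    best_window,
    capture_table,
    sample_size_plan,
    seasonal_analysis,
)

__all__ = [
    "read_traces",
    "write_traces",
    "read_cohort",
    "write_cohort",
    "write_capture_table",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("clptel")

TRACE_COLUMNS = ["mouse_id", "time_min", "heart_rate_bpm", "core_temp_c"]
COHORT_COLUMNS = ["mouse_id", "time_to_criteria_min", "censored", "season", "ambient_temp_c"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ParseError(f"{path}: non-numeric values in column {col!r} at lines {lines}")
    return out


def write_traces(traces: list[TelemetryTrace], path) -> None:
    """Write traces as one long-format CSV."""
    frames = []
    for tr in traces:
        d = {
            "mouse_id": tr.mouse_id,
            "time_min": tr.times,
            "heart_rate_bpm": tr.heart_rate,
            "core_temp_c": tr.core_temp,
        }
        if tr.activity is not None:
            d["activity"] = tr.activity
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_traces(path) -> list[TelemetryTrace]:
    """Read a long-format trace CSV (or a directory of per-mouse CSVs)."""
    path = Path(path)
    if path.is_dir():
        traces: list[TelemetryTrace] = []
        for f in sorted(path.glob("*.csv")):
            traces.extend(read_traces(f))
        if not traces:
            raise ParseError(f"{path}: no trace CSVs found")
        return traces
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    for col in TRACE_COLUMNS[1:] + (["activity"] if "activity" in df.columns else []):
        df[col] = _numeric(df, col, path)
    traces = []
    for mouse_id, g in df.groupby("mouse_id", sort=False):
        traces.append(
            TelemetryTrace(
                mouse_id=str(mouse_id),
                times=g["time_min"].to_numpy(),
                heart_rate=g["heart_rate_bpm"].to_numpy(),
                core_temp=g["core_temp_c"].to_numpy(),
                activity=g["activity"].to_numpy() if "activity" in g.columns else None,
            )
        )
    return traces


def write_cohort(outcomes: list[MouseOutcome], path) -> None:
    pd.DataFrame(
        {
            "mouse_id": [o.mouse_id for o in outcomes],
            "time_to_criteria_min": [o.time_to_criteria for o in outcomes],
            "censored": [o.censored for o in outcomes],
            "season": [o.season for o in outcomes],
            "ambient_temp_c": [o.ambient_temp for o in outcomes],
        }
    ).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_cohort(path, horizon: float = 1440.0) -> list[MouseOutcome]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["mouse_id", "time_to_criteria_min", "censored"], path)
    df["time_to_criteria_min"] = _numeric(df, "time_to_criteria_min", path)
    outcomes = []
    for i, row in df.iterrows():
        censored = bool(row["censored"]) if not isinstance(row["censored"], str) \
            else row["censored"].strip().lower() in ("true", "1", "yes")
        t = row["time_to_criteria_min"]
        season = row.get("season")
        amb = row.get("ambient_temp_c")
        outcomes.append(
            MouseOutcome(
                mouse_id=str(row["mouse_id"]),
                time_to_criteria=None if censored or pd.isna(t) else float(t),
                censored=censored,
                season=None if pd.isna(season) else str(season),
                ambient_temp=None if amb is None or pd.isna(amb) else float(amb),
                horizon=horizon,
            )
        )
    return outcomes


def write_capture_table(table: CaptureTable, path) -> None:
    """Write the hourly capture table with whole-percent reporting columns."""
    out = table.to_percent()
    out.insert(0, "hour", out.index)
    out.to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``traces_path`` (ingest) or ``simulation`` (generate) feeds the
    detector; ``fixture`` short-circuits both and analyzes the
    deterministic reconstructed cohort.
    """

    out_dir: str = "clptel_out"
    seed: int = 0
    fixture: bool = False
    traces_path: str | None = None
    simulation: SimulationParams | None = None
    criteria: DeteriorationCriteria = field(default_factory=DeteriorationCriteria)
    tolerance: float = 30.0
    cost: CostParameters = field(default_factory=CostParameters)
    quality_mice: int = 120
    equivalency_costs: tuple = (25.0, 37.5, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0)
    seasonal: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationParams(**raw["simulation"])
        if "criteria" in raw:
            raw["criteria"] = DeteriorationCriteria(**raw["criteria"])
        if "cost" in raw:
            raw["cost"] = CostParameters(**raw["cost"])
        if "equivalency_costs" in raw:
            raw["equivalency_costs"] = tuple(raw["equivalency_costs"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/ingest -> detect -> variability -> cost and write outputs.

    Emits ``cohort.csv``, ``table_capture.csv``, ``table_equivalency.csv``
    (plus ``table_seasonal.csv`` when requested) and ``summary.json`` into
    ``config.out_dir``; returns the summary dict.  Outputs are
    byte-identical across reruns of the same configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.fixture:
        logger.info("stage ingest: deterministic reconstructed cohort")
        outcomes = fixture_cohort_table1()
    else:
        if config.traces_path is not None:
            logger.info("stage ingest: reading traces from %s", config.traces_path)
            traces = read_traces(config.traces_path)
        else:
            params = config.simulation or SimulationParams()
            params = params.with_(seed=config.seed)
            logger.info("stage simulate: %d mice, seed %d", params.n_mice, params.seed)
            traces = simulate_cohort(params)
        logger.info("stage detect: %d traces", len(traces))
        outcomes = detect_cohort(traces, config.criteria)
    write_cohort(outcomes, out / "cohort.csv")

    logger.info("stage variability")
    table = capture_table(outcomes, tolerance=config.tolerance)
    write_capture_table(table, out / "table_capture.csv")
    best = best_window(table)
    successes = int(table.data.loc[best, "window_count"])
    plan = sample_size_plan(config.quality_mice, successes=successes, n=table.n_analyzed)

    seasonal_block = None
    if config.seasonal:
        seas = seasonal_analysis(outcomes, tolerance=config.tolerance, at_hour=best)
        seas.per_season.to_csv(out / "table_seasonal.csv")
        seasonal_block = {
            "kruskal_p": seas.kruskal_p,
            "capture_fisher_p": seas.capture_fisher_p,
            "spearman_r": seas.spearman_r,
            "spearman_p": seas.spearman_p,
        }

    logger.info("stage cost")
    cost_params = config.cost.with_(capture_proportion=plan.p_hat)
    eq_rows = []
    for c in config.equivalency_costs:
        try:
            r = equivalency_quality_mice(c, params=cost_params)
        except Exception as exc:
            logger.warning("equivalency at c=%s failed: %s", c, exc)
            continue
        eq_rows.append(
            {
                "cost_per_mouse_usd": c,
                "biotelemetry_mice": r.quality_mice,
                "standard_mice": r.standard_mice,
                "mice_spared": r.mice_spared,
                "battery_replacements": r.battery_replacements,
            }
        )
    pd.DataFrame(eq_rows).to_csv(out / "table_equivalency.csv", index=False)

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_total": len(outcomes),
        "n_censored": sum(o.censored for o in outcomes),
        "n_analyzed": table.n_analyzed,
        "median_time_to_criteria_min": float(
            np.median([o.time_to_criteria for o in outcomes if not o.censored])
        ),
        "best_window_hour": best,
        "capture_proportion": plan.p_hat,
        "capture_ci_pct": [plan.ci_low, plan.ci_high],
        "fold_increase": plan.fold_increase,
        "required_standard_mice": plan.required_total,
        "equivalency": eq_rows,
        "seasonal": seasonal_block,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
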