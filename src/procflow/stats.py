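"""Per-step time and visit statistics with operative-time correlations.

For every catalog step the cohort summary reports the cumulative time
(minutes over all procedures), cumulative visit count, mean +/- SD of
per-procedure step time and visit frequency, and Spearman rank
correlations of those two metrics with console time (CT) and total
operative time (TOT).

Denominator convention: per-step means and SDs are computed over only the
procedures in which the step occurs at least once (steps may be skipped
entirely, and zero-filling skipped procedures would conflate absence with
speed).  Correlations pair metric values with CT/TOT over that same
occurring subset, restricted to procedures where the operative time is
recorded.  SDs are sample (n-1) SDs.  Degenerate statistics are NaN and
render as "NA": an SD over a single observation, and any correlation over
fewer than 3 pairs or over a constant vector.

All values are kept at full precision internally; rounding to the
two-decimal report convention happens only in :func:`summary_frame`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import Cohort, ProcedureRecord
from .catalog import StepCatalog

__all__ = [
    "StepSummary",
    "CohortSummary",
    "step_time",
    "step_visits",
    "spearman_rho",
    "correlate_step",
    "summarize_steps",
    "summary_frame",
]


@dataclass(frozen=True)
class StepSummary:
    """One step's row of the cohort summary (NaN encodes NA)."""

    step_id: int
    n_procedures: int
    cumulative_time_min: float
    mean_time_min: float
    sd_time_min: float
    cumulative_visits: int
    mean_visits: float
    sd_visits: float
    rho_time_tot: float
    rho_time_ct: float
    rho_visits_tot: float
    rho_visits_ct: float


@dataclass(frozen=True)
class CohortSummary:
    steps: tuple[StepSummary, ...]
    n_procedures: int
    mean_occurrences_per_procedure: float
    sd_occurrences_per_procedure: float
    mean_ct_min: float
    sd_ct_min: float
    mean_tot_min: float
    sd_tot_min: float


def _check_step(step_id: int, catalog: Optional[StepCatalog]) -> None:
    if catalog is not None and step_id not in catalog:
        raise KeyError(f"unknown step_id {step_id!r}")


def step_time(
    procedure: ProcedureRecord, step_id: int, catalog: Optional[StepCatalog] = None
) -> float:
    """Total time the procedure spent in ``step_id``, minutes (0.0 if absent)."""
    _check_step(step_id, catalog)
    return sum(ev.duration_s for ev in procedure.events if ev.step_id == step_id) / 60.0


def step_visits(
    procedure: ProcedureRecord, step_id: int, catalog: Optional[StepCatalog] = None
) -> int:
    """Number of visits (annotated events) of ``step_id`` in the procedure."""
    _check_step(step_id, catalog)
    return sum(1 for ev in procedure.events if ev.step_id == step_id)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (NA) when fewer than 3 pairs are available or either vector
    has zero variance — a rank correlation is undefined over a constant.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        return math.nan
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return math.nan
    return float(sps.spearmanr(xa, ya).statistic)


def _metric_value(
    proc: ProcedureRecord, step_id: int, metric: Literal["time", "visits"]
) -> float:
    if metric == "time":
        return step_time(proc, step_id)
    if metric == "visits":
        return float(step_visits(proc, step_id))
    raise ValueError(f"unknown metric {metric!r}")


def _against_value(proc: ProcedureRecord, against: Literal["CT", "TOT"]) -> Optional[float]:
    if against == "CT":
        return proc.console_time_min
    if against == "TOT":
        return proc.total_operative_time_min
    raise ValueError(f"unknown against variable {against!r}")


def correlate_step(
    cohort: Cohort,
    step_id: int,
    metric: Literal["time", "visits"],
    against: Literal["CT", "TOT"],
) -> float:
    """Spearman correlation of a step metric with CT or TOT over the cohort.

    Pairs are formed only from procedures where the step occurs and the
    operative-time variable is recorded.
    """
    _check_step(step_id, cohort.catalog)
    xs, ys = [], []
    for proc in cohort.procedures:
        if step_visits(proc, step_id) == 0:
            continue
        yv = _against_value(proc, against)
        if yv is None:
            continue
        xs.append(_metric_value(proc, step_id, metric))
        ys.append(yv)
    return spearman_rho(xs, ys)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    if n == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sd = math.nan if n == 1 else float(np.std(values, ddof=1))
    return mean, sd


def summarize_steps(cohort: Cohort) -> CohortSummary:
    """Per-step cohort summary plus cohort-level occurrence and CT/TOT stats."""
    if cohort.n_procedures == 0:
        raise ValueError("cannot summarize an empty cohort")

    summaries = []
    for step_id, _ in cohort.catalog:
        times = []
        visits = []
        for proc in cohort.procedures:
            v = step_visits(proc, step_id)
            if v == 0:
                continue
            visits.append(v)
            times.append(step_time(proc, step_id))
        n = len(times)
        mean_t, sd_t = _mean_sd(times)
        mean_v, sd_v = _mean_sd([float(v) for v in visits])
        summaries.append(
            StepSummary(
                step_id=step_id,
                n_procedures=n,
                cumulative_time_min=float(sum(times)),
                mean_time_min=mean_t,
                sd_time_min=sd_t,
                cumulative_visits=int(sum(visits)),
                mean_visits=mean_v,
                sd_visits=sd_v,
                rho_time_tot=correlate_step(cohort, step_id, "time", "TOT"),
                rho_time_ct=correlate_step(cohort, step_id, "time", "CT"),
                rho_visits_tot=correlate_step(cohort, step_id, "visits", "TOT"),
                rho_visits_ct=correlate_step(cohort, step_id, "visits", "CT"),
            )
        )

    counts = [float(p.n_events) for p in cohort.procedures]
    mean_occ, sd_occ = _mean_sd(counts)
    cts = [p.console_time_min for p in cohort.procedures if p.console_time_min is not None]
    tots = [
        p.total_operative_time_min
        for p in cohort.procedures
        if p.total_operative_time_min is not None
    ]
    mean_ct, sd_ct = _mean_sd(cts)
    mean_tot, sd_tot = _mean_sd(tots)
    return CohortSummary(
        steps=tuple(summaries),
        n_procedures=cohort.n_procedures,
        mean_occurrences_per_procedure=mean_occ,
        sd_occurrences_per_procedure=sd_occ,
        mean_ct_min=mean_ct,
        sd_ct_min=sd_ct,
        mean_tot_min=mean_tot,
        sd_tot_min=sd_tot,
    )


SUMMARY_COLUMNS = [
    "step_name",
    "sum_time_min",
    "mean_time_min",
    "sd_time_min",
    "rho_time_tot",
    "rho_time_ct",
    "sum_visits",
    "mean_visits",
    "sd_visits",
    "rho_visits_tot",
    "rho_visits_ct",
    "n_procedures",
]


def summary_frame(summary: CohortSummary, catalog: StepCatalog) -> pd.DataFrame:
    """Presentation table: one row per step, values rounded to two decimals."""
    rows = []
    for s in summary.steps:
        rows.append(
            {
                "step_name": catalog.name(s.step_id),
                "sum_time_min": round(s.cumulative_time_min, 2),
                "mean_time_min": round(s.mean_time_min, 2),
                "sd_time_min": round(s.sd_time_min, 2),
                "rho_time_tot": round(s.rho_time_tot, 2),
                "rho_time_ct": round(s.rho_time_ct, 2),
                "sum_visits": s.cumulative_visits,
                "mean_visits": round(s.mean_visits, 2),
                "sd_visits": round(s.sd_visits, 2),
                "rho_visits_tot": round(s.rho_visits_tot, 2),
                "rho_visits_ct": round(s.rho_visits_ct, 2),
                "n_procedures": s.n_procedures,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
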