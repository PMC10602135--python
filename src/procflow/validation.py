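"""Cohort validation: temporal-overlap checks and repair.

The annotation protocol implies one active step at a time at the console,
so two events of one procedure must never intersect in time (intervals are
half-open, so a shared boundary is legal).  Three policies are offered:

* ``error`` (default) — any overlap raises :class:`OverlapError`;
* ``truncate`` — the later event's start is clipped to the earlier event's
  stop (events swallowed entirely are dropped) and each repair is recorded;
* ``warn`` — findings are recorded, data is returned unchanged.

Absent CT/TOT metadata and ties in start time produce non-fatal findings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .annotations import AnnotationEvent, Cohort, ProcedureRecord

__all__ = ["Finding", "ValidationReport", "OverlapError", "validate_cohort"]

OverlapPolicy = Literal["error", "truncate", "warn"]


@dataclass(frozen=True)
class Finding:
    severity: Literal["info", "warning", "error"]
    code: str
    procedure_id: str
    event_indices: tuple[int, ...]
    message: str


class OverlapError(ValueError):
    """Raised under the ``error`` policy when events of a procedure overlap."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        lines = "; ".join(f.message for f in findings[:5])
        extra = "" if len(findings) <= 5 else f" (+{len(findings) - 5} more)"
        super().__init__(f"overlapping events: {lines}{extra}")


@dataclass(frozen=True)
class ValidationReport:
    """Findings plus the (possibly repaired) cohort they describe."""

    cohort: Cohort
    findings: tuple[Finding, ...]

    @property
    def overlap_findings(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.code.startswith("overlap"))


def _scan_procedure(
    proc: ProcedureRecord, policy: OverlapPolicy
) -> tuple[ProcedureRecord, list[Finding]]:
    findings: list[Finding] = []
    ordered = proc.sorted_by_start()
    events = list(ordered.events)

    for i in range(1, len(events)):
        if events[i].start_s == events[i - 1].start_s:
            findings.append(
                Finding(
                    "warning",
                    "tie-start",
                    proc.procedure_id,
                    (i - 1, i),
                    f"{proc.procedure_id}: events {i - 1} and {i} share "
                    f"start_s={events[i].start_s}; input order preserved",
                )
            )

    repaired: list[AnnotationEvent] = []
    for i, ev in enumerate(events):
        prev_stop = repaired[-1].stop_s if repaired else None
        if prev_stop is not None and ev.start_s < prev_stop:
            msg = (
                f"{proc.procedure_id}: event {i} [{ev.start_s}, {ev.stop_s}) "
                f"overlaps preceding event ending at {prev_stop}"
            )
            if policy == "truncate":
                if ev.stop_s <= prev_stop:
                    findings.append(
                        Finding(
                            "warning",
                            "overlap-dropped",
                            proc.procedure_id,
                            (i,),
                            msg + "; contained event dropped",
                        )
                    )
                    continue
                findings.append(
                    Finding(
                        "warning",
                        "overlap-truncated",
                        proc.procedure_id,
                        (i,),
                        msg + f"; start clipped to {prev_stop}",
                    )
                )
                ev = replace(ev, start_s=prev_stop)
            else:
                findings.append(
                    Finding("error", "overlap", proc.procedure_id, (i - 1, i), msg)
                )
        repaired.append(ev)

    if proc.console_time_min is None:
        findings.append(
            Finding(
                "info",
                "missing-ct",
                proc.procedure_id,
                (),
                f"{proc.procedure_id}: console time absent",
            )
        )
    if proc.total_operative_time_min is None:
        findings.append(
            Finding(
                "info",
                "missing-tot",
                proc.procedure_id,
                (),
                f"{proc.procedure_id}: total operative time absent",
            )
        )

    if policy == "truncate":
        ordered = replace(ordered, events=tuple(repaired))
    return ordered, findings


def validate_cohort(cohort: Cohort, overlap_policy: OverlapPolicy = "error") -> ValidationReport:
    """Check (and under ``truncate``, repair) temporal consistency of a cohort.

    Returns a :class:`ValidationReport`; under the ``error`` policy any
    overlap raises :class:`OverlapError` instead.  Raises ``ValueError`` on
    an empty cohort, which supports no statistics.
    """
    if overlap_policy not in ("error", "truncate", "warn"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    if cohort.n_procedures == 0:
        raise ValueError("cannot validate an empty cohort")

    all_findings: list[Finding] = []
    procedures: list[ProcedureRecord] = []
    for proc in cohort.procedures:
        repaired, findings = _scan_procedure(proc, overlap_policy)
        all_findings.extend(findings)
        procedures.append(repaired)

    errors = [f for f in all_findings if f.severity == "error"]
    if overlap_policy == "error" and errors:
        raise OverlapError(errors)

    out = replace(cohort, procedures=tuple(procedures))
    return ValidationReport(cohort=out, findings=tuple(all_findings))
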