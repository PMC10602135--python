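"""Domain types for timed step annotations.

An :class:`AnnotationEvent` is one contiguous visit to one surgical step
within one procedure, recorded as a half-open interval ``[start_s, stop_s)``
in seconds from the procedure's clock origin (the origin itself is not
assumed to be the first event).  A :class:`ProcedureRecord` bundles a
procedure's events with its externally measured console time (CT) and total
operative time (TOT) in minutes; a :class:`Cohort` bundles procedures with
the step catalog they were annotated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .catalog import StepCatalog

__all__ = ["AnnotationEvent", "ProcedureRecord", "Cohort"]


@dataclass(frozen=True)
class AnnotationEvent:
    """One timed visit to one step. Interval is half-open: [start_s, stop_s)."""

    procedure_id: str
    step_id: int
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(
                f"{self.procedure_id}: start_s must be non-negative, got {self.start_s}"
            )
        if not self.stop_s > self.start_s:
            raise ValueError(
                f"{self.procedure_id}: stop_s ({self.stop_s}) must be strictly "
                f"greater than start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    @property
    def duration_min(self) -> float:
        return (self.stop_s - self.start_s) / 60.0

    def overlaps(self, other: "AnnotationEvent") -> bool:
        """True when the half-open intervals intersect (shared boundary is fine)."""
        return self.start_s < other.stop_s and other.start_s < self.stop_s


@dataclass(frozen=True)
class ProcedureRecord:
    """One procedure's ordered events plus CT/TOT metadata (minutes, optional)."""

    procedure_id: str
    events: tuple[AnnotationEvent, ...]
    console_time_min: Optional[float] = None
    total_operative_time_min: Optional[float] = None

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        for ev in events:
            if ev.procedure_id != self.procedure_id:
                raise ValueError(
                    f"event procedure_id {ev.procedure_id!r} does not match "
                    f"record {self.procedure_id!r}"
                )
        if self.console_time_min is not None and self.console_time_min <= 0:
            raise ValueError("console_time_min must be positive when present")
        if (
            self.total_operative_time_min is not None
            and self.total_operative_time_min <= 0
        ):
            raise ValueError("total_operative_time_min must be positive when present")
        if (
            self.console_time_min is not None
            and self.total_operative_time_min is not None
            and self.total_operative_time_min < self.console_time_min
        ):
            raise ValueError(
                f"{self.procedure_id}: total operative time "
                f"({self.total_operative_time_min}) cannot be less than console "
                f"time ({self.console_time_min})"
            )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def annotated_time_min(self) -> float:
        """Sum of all annotated step durations, minutes."""
        return sum(ev.duration_s for ev in self.events) / 60.0

    def sorted_by_start(self) -> "ProcedureRecord":
        """Events in ascending start_s; equal starts keep input order."""
        ordered = tuple(sorted(self.events, key=lambda ev: ev.start_s))
        return replace(self, events=ordered)


@dataclass(frozen=True)
class Cohort:
    """A set of procedures annotated against a common step catalog."""

    catalog: StepCatalog
    procedures: tuple[ProcedureRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        procedures = tuple(self.procedures)
        object.__setattr__(self, "procedures", procedures)
        ids = [p.procedure_id for p in procedures]
        if len(set(ids)) != len(ids):
            raise ValueError("procedure_ids must be unique within a cohort")
        for proc in procedures:
            for ev in proc.events:
                if ev.step_id not in self.catalog:
                    raise ValueError(
                        f"{proc.procedure_id}: event step_id {ev.step_id} is not "
                        f"in the catalog"
                    )

    @property
    def n_procedures(self) -> int:
        return len(self.procedures)

    def __iter__(self):
        return iter(self.procedures)

    def procedure(self, procedure_id: str) -> ProcedureRecord:
        for proc in self.procedures:
            if proc.procedure_id == procedure_id:
                return proc
        raise KeyError(f"no procedure {procedure_id!r} in cohort")
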