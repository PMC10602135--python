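"""Readers and writers for annotation, metadata and catalog files.

Schemas (delimited text; comma by default, tab accepted):

* events file — header ``procedure_id,step_id,start_s,stop_s`` with an
  optional ``step_name`` column that is cross-checked against the catalog;
  one row per step visit.
* metadata file — header
  ``procedure_id,console_time_min,total_operative_time_min``; empty cells
  mean the measurement is absent.
* catalog file — header ``step_id,step_name``.

Times are serialized in seconds with millisecond precision and operative
times in minutes with two decimals, so a save/load round trip is the
identity at serialized precision.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

from .annotations import AnnotationEvent, Cohort, ProcedureRecord
from .catalog import StepCatalog, default_catalog

__all__ = ["AnnotationFormatError", "load_annotations", "save_annotations"]

EVENT_FIELDS = ("procedure_id", "step_id", "start_s", "stop_s")
METADATA_FIELDS = ("procedure_id", "console_time_min", "total_operative_time_min")


class AnnotationFormatError(ValueError):
    """A malformed events or metadata file; message carries the line number."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_metadata(path: Path) -> dict[str, tuple[Optional[float], Optional[float]]]:
    delim = _sniff_delimiter(path)
    meta: dict[str, tuple[Optional[float], Optional[float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not set(METADATA_FIELDS) <= set(reader.fieldnames):
            raise AnnotationFormatError(
                f"{path}: metadata header must contain {', '.join(METADATA_FIELDS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            pid = (row["procedure_id"] or "").strip()
            if not pid:
                raise AnnotationFormatError(f"{path}:{lineno}: empty procedure_id")

            def _num(key: str) -> Optional[float]:
                raw = (row.get(key) or "").strip()
                if raw in ("", "NA", "NaN"):
                    return None
                try:
                    return float(raw)
                except ValueError:
                    raise AnnotationFormatError(
                        f"{path}:{lineno}: non-numeric {key} {raw!r}"
                    ) from None

            meta[pid] = (_num("console_time_min"), _num("total_operative_time_min"))
    return meta


def load_annotations(
    events_path: str | Path,
    metadata_path: str | Path | None = None,
    catalog: StepCatalog | None = None,
) -> Cohort:
    """Load an events file (and optional metadata file) into a :class:`Cohort`.

    Events are grouped by procedure and sorted by ``start_s`` (stable, so
    equal starts keep file order).  Procedures present in the events file
    but absent from the metadata carry absent CT/TOT.  Malformed rows,
    unknown step ids, non-positive durations and duplicate
    ``(procedure_id, start_s, step_id)`` rows raise
    :class:`AnnotationFormatError` naming the offending line.
    """
    events_path = Path(events_path)
    if catalog is None:
        catalog = default_catalog()

    delim = _sniff_delimiter(events_path)
    by_proc: dict[str, list[AnnotationEvent]] = {}
    seen: set[tuple[str, float, int]] = set()
    with open(events_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not set(EVENT_FIELDS) <= set(reader.fieldnames):
            raise AnnotationFormatError(
                f"{events_path}: events header must contain {', '.join(EVENT_FIELDS)}"
            )
        check_names = "step_name" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = (row["procedure_id"] or "").strip()
                step_id = int(row["step_id"])
                start_s = float(row["start_s"])
                stop_s = float(row["stop_s"])
            except (TypeError, ValueError):
                raise AnnotationFormatError(
                    f"{events_path}:{lineno}: malformed row {row!r}"
                ) from None
            if not pid:
                raise AnnotationFormatError(f"{events_path}:{lineno}: empty procedure_id")
            if step_id not in catalog:
                raise AnnotationFormatError(
                    f"{events_path}:{lineno}: unknown step_id {step_id}"
                )
            if check_names:
                name = (row.get("step_name") or "").strip()
                if name and name != catalog.name(step_id):
                    raise AnnotationFormatError(
                        f"{events_path}:{lineno}: step_name {name!r} does not match "
                        f"catalog name {catalog.name(step_id)!r} for step {step_id}"
                    )
            key = (pid, start_s, step_id)
            if key in seen:
                raise AnnotationFormatError(
                    f"{events_path}:{lineno}: duplicate row for "
                    f"(procedure_id={pid}, start_s={start_s}, step_id={step_id})"
                )
            seen.add(key)
            try:
                event = AnnotationEvent(pid, step_id, start_s, stop_s)
            except ValueError as exc:
                raise AnnotationFormatError(f"{events_path}:{lineno}: {exc}") from None
            by_proc.setdefault(pid, []).append(event)

    meta = _read_metadata(Path(metadata_path)) if metadata_path is not None else {}
    procedures = []
    for pid, events in by_proc.items():
        ct, tot = meta.get(pid, (None, None))
        record = ProcedureRecord(
            procedure_id=pid,
            events=tuple(events),
            console_time_min=ct,
            total_operative_time_min=tot,
        ).sorted_by_start()
        procedures.append(record)
    return Cohort(catalog=catalog, procedures=tuple(procedures))


def save_annotations(
    cohort: Cohort,
    events_path: str | Path,
    metadata_path: str | Path | None = None,
    catalog_path: str | Path | None = None,
    include_step_names: bool = True,
) -> None:
    """Write a cohort back to the delimited file schema.

    ``load_annotations`` inverts this exactly on values: times are written
    with three decimals (milliseconds) and operative times with two.
    An empty cohort yields header-only files.
    """
    with open(events_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(EVENT_FIELDS) + (["step_name"] if include_step_names else [])
        writer.writerow(header)
        for proc in cohort.procedures:
            for ev in proc.events:
                row = [ev.procedure_id, ev.step_id, f"{ev.start_s:.3f}", f"{ev.stop_s:.3f}"]
                if include_step_names:
                    row.append(cohort.catalog.name(ev.step_id))
                writer.writerow(row)

    if metadata_path is not None:
        with open(metadata_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(METADATA_FIELDS)
            for proc in cohort.procedures:
                ct = "" if proc.console_time_min is None else f"{proc.console_time_min:.2f}"
                tot = (
                    ""
                    if proc.total_operative_time_min is None
                    else f"{proc.total_operative_time_min:.2f}"
                )
                writer.writerow([proc.procedure_id, ct, tot])

    if catalog_path is not None:
        cohort.catalog.save(catalog_path)
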