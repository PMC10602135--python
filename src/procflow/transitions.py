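"""Visit sequences, transition matrices and step classification.

A procedure's visit sequence is its step ids in chronological order; the
cohort transition matrix counts direct (first-order) transitions between
consecutive visits, never across procedure boundaries.  Row sums measure a
step's outgoing traffic (divergence), column sums its incoming traffic
(convergence).  Classifying a step compares the number of *distinct* step
types preceding and following it to a threshold (default 10):

* nodal — at least ``threshold`` distinct types on both sides;
* divergent — fewer preceding, more than ``threshold`` following;
* convergent — more than ``threshold`` preceding, fewer following;
* unclassified — anything else.

The nodal rule is evaluated first; at exactly the threshold on both sides
a step is nodal.  Self-transitions (consecutive visits to the same step)
are counted in the matrix — chord diagrams draw them as ribbons entering
and exiting one step — but are excluded from distinct-neighbor counts
unless ``include_self`` is set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .annotations import Cohort, ProcedureRecord
from .catalog import StepCatalog

__all__ = [
    "VisitSequence",
    "TransitionMatrix",
    "TransitionProfile",
    "StepClass",
    "visit_sequence",
    "transition_pairs",
    "transition_matrix",
    "neighbor_counts",
    "classify_step",
    "profile_steps",
    "classification_frame",
    "export_chord_matrix",
    "load_chord_matrix",
    "chord_figure",
]

StepClass = Literal["nodal", "convergent", "divergent", "unclassified"]


@dataclass(frozen=True)
class VisitSequence:
    procedure_id: str
    step_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.step_ids)


@dataclass(frozen=True)
class TransitionMatrix:
    """Square count matrix in catalog order; entry (i, j) counts i -> j."""

    catalog: StepCatalog
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.catalog)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("transition counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def get(self, from_step: int, to_step: int) -> int:
        return int(self.counts[self.catalog.index(from_step), self.catalog.index(to_step)])

    def total(self) -> int:
        return int(self.counts.sum())

    def row_sum(self, step_id: int) -> int:
        return int(self.counts[self.catalog.index(step_id)].sum())

    def col_sum(self, step_id: int) -> int:
        return int(self.counts[:, self.catalog.index(step_id)].sum())


@dataclass(frozen=True)
class TransitionProfile:
    step_id: int
    cumulative_visits: int
    n_preceding_types: int
    n_following_types: int
    step_class: StepClass


def visit_sequence(procedure: ProcedureRecord, merge_gap_s: float = 0.0) -> VisitSequence:
    """Step ids in ascending start order, one entry per visit.

    With ``merge_gap_s > 0``, consecutive same-step visits separated by
    less than the gap are fused into a single visit (brief interruptions,
    e.g. off-console pauses, then do not inflate visit counts).
    """
    if merge_gap_s < 0:
        raise ValueError("merge_gap_s must be non-negative")
    ordered = procedure.sorted_by_start().events
    steps: list[int] = []
    last_stop: Optional[float] = None
    for ev in ordered:
        if (
            merge_gap_s > 0
            and steps
            and ev.step_id == steps[-1]
            and last_stop is not None
            and ev.start_s - last_stop < merge_gap_s
        ):
            last_stop = max(last_stop, ev.stop_s)
            continue
        steps.append(ev.step_id)
        last_stop = ev.stop_s
    return VisitSequence(procedure.procedure_id, tuple(steps))


def transition_pairs(sequence: VisitSequence) -> list[tuple[int, int]]:
    """Consecutive (from, to) pairs; self-pairs are legal and kept."""
    ids = sequence.step_ids
    return [(ids[k], ids[k + 1]) for k in range(len(ids) - 1)]


def transition_matrix(cohort: Cohort, merge_gap_s: float = 0.0) -> TransitionMatrix:
    """Cohort-wide direct-transition counts; never crosses procedures."""
    if cohort.n_procedures == 0:
        raise ValueError("cannot build a transition matrix from an empty cohort")
    n = len(cohort.catalog)
    counts = np.zeros((n, n), dtype=np.int64)
    for proc in cohort.procedures:
        seq = visit_sequence(proc, merge_gap_s=merge_gap_s)
        for a, b in transition_pairs(seq):
            counts[cohort.catalog.index(a), cohort.catalog.index(b)] += 1
    return TransitionMatrix(cohort.catalog, counts)


def neighbor_counts(
    matrix: TransitionMatrix, step_id: int, include_self: bool = False
) -> tuple[int, int]:
    """(distinct step types preceding, distinct step types following)."""
    k = matrix.catalog.index(step_id)
    incoming = matrix.counts[:, k] > 0
    outgoing = matrix.counts[k, :] > 0
    if not include_self:
        incoming = incoming.copy()
        outgoing = outgoing.copy()
        incoming[k] = False
        outgoing[k] = False
    return int(incoming.sum()), int(outgoing.sum())


def classify_step(
    n_preceding_types: int, n_following_types: int, threshold: int = 10
) -> StepClass:
    """Classify a step from its distinct predecessor/successor type counts."""
    if n_preceding_types < 0 or n_following_types < 0:
        raise ValueError("neighbor counts must be non-negative")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    pre, post = n_preceding_types, n_following_types
    if pre >= threshold and post >= threshold:
        return "nodal"
    if pre < threshold and post > threshold:
        return "divergent"
    if pre > threshold and post < threshold:
        return "convergent"
    return "unclassified"


def profile_steps(
    cohort: Cohort,
    threshold: int = 10,
    include_self: bool = False,
    merge_gap_s: float = 0.0,
) -> list[TransitionProfile]:
    """One profile per catalog step: visits, neighbor counts, class."""
    matrix = transition_matrix(cohort, merge_gap_s=merge_gap_s)
    visits: dict[int, int] = {sid: 0 for sid in cohort.catalog.step_ids}
    for proc in cohort.procedures:
        for sid in visit_sequence(proc, merge_gap_s=merge_gap_s).step_ids:
            visits[sid] += 1
    profiles = []
    for step_id, _ in cohort.catalog:
        pre, post = neighbor_counts(matrix, step_id, include_self=include_self)
        profiles.append(
            TransitionProfile(
                step_id=step_id,
                cumulative_visits=visits[step_id],
                n_preceding_types=pre,
                n_following_types=post,
                step_class=classify_step(pre, post, threshold=threshold),
            )
        )
    return profiles


def classification_frame(
    profiles: list[TransitionProfile], catalog: StepCatalog
) -> pd.DataFrame:
    rows = [
        {
            "step_name": catalog.name(p.step_id),
            "cumulative_visits": p.cumulative_visits,
            "n_preceding_types": p.n_preceding_types,
            "n_following_types": p.n_following_types,
            "step_class": p.step_class,
        }
        for p in profiles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "step_name",
            "cumulative_visits",
            "n_preceding_types",
            "n_following_types",
            "step_class",
        ],
    )


def export_chord_matrix(matrix: TransitionMatrix, path: str | Path) -> None:
    """Write a labeled square matrix in chord-diagram (tableviewer) layout.

    Tab-delimited; the first row and first column carry step names; rows
    are transition sources, columns destinations.
    """
    names = matrix.catalog.step_names
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["step", *names])
        for i, name in enumerate(names):
            writer.writerow([name, *matrix.counts[i].tolist()])


def load_chord_matrix(path: str | Path, catalog: StepCatalog) -> TransitionMatrix:
    """Parse a matrix written by :func:`export_chord_matrix` back into counts."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header[1:]) != catalog.step_names:
            raise ValueError(f"{path}: column labels do not match the catalog")
        rows = list(reader)
    if tuple(r[0] for r in rows) != catalog.step_names:
        raise ValueError(f"{path}: row labels do not match the catalog")
    counts = np.array([[int(v) for v in r[1:]] for r in rows], dtype=np.int64)
    return TransitionMatrix(catalog, counts)


def chord_figure(matrix: TransitionMatrix, path: str | Path) -> None:
    """Best-effort transition figure (heatmap of counts, catalog order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(matrix.catalog)
    fig, ax = plt.subplots(figsize=(0.45 * n + 2, 0.45 * n + 2))
    im = ax.imshow(matrix.counts, cmap="viridis")
    ax.set_xticks(range(n), [str(s) for s in matrix.catalog.step_ids], fontsize=7)
    ax.set_yticks(range(n), [str(s) for s in matrix.catalog.step_ids], fontsize=7)
    ax.set_xlabel("destination step")
    ax.set_ylabel("source step")
    ax.set_title("Step transition counts")
    fig.colorbar(im, ax=ax, shrink=0.8, label="transitions")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
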