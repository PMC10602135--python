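"""Shared fixtures and cohort-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from procflow.annotations import AnnotationEvent, Cohort, ProcedureRecord
from procflow.catalog import StepCatalog, default_catalog
from procflow.simulate import WorkflowModel, default_model


def make_procedure(
    procedure_id: str,
    visits: list[tuple[int, float, float]],
    ct: float | None = None,
    tot: float | None = None,
) -> ProcedureRecord:
    """Procedure from (step_id, start_s, stop_s) triples."""
    events = tuple(
        AnnotationEvent(procedure_id, step, start, stop) for step, start, stop in visits
    )
    return ProcedureRecord(
        procedure_id=procedure_id,
        events=events,
        console_time_min=ct,
        total_operative_time_min=tot,
    )


def cohort_from_sequences(
    catalog: StepCatalog,
    sequences: list[list[int]],
    visit_s: float = 60.0,
    gap_s: float = 10.0,
    cts: list[float | None] | None = None,
    tots: list[float | None] | None = None,
) -> Cohort:
    """Cohort whose procedures visit the given step sequences back to back."""
    procedures = []
    for k, seq in enumerate(sequences):
        pid = f"P{k + 1:04d}"
        t = 0.0
        visits = []
        for step in seq:
            visits.append((step, t, t + visit_s))
            t += visit_s + gap_s
        ct = cts[k] if cts else None
        tot = tots[k] if tots else None
        procedures.append(make_procedure(pid, visits, ct=ct, tot=tot))
    return Cohort(catalog=catalog, procedures=tuple(procedures))


def uniform_traffic_model(seed: int = 123, end_prob: float = 0.02) -> WorkflowModel:
    """21-step model with a seeded Dirichlet kernel and even step traffic.

    Every step is always available and roughly equally visited, so each
    kernel row accumulates enough transitions for sampling-accuracy checks.
    """
    catalog = default_catalog()
    n = len(catalog)
    rng = np.random.default_rng(seed)
    kernel = np.zeros((n, n + 1))
    kernel[:, :n] = rng.dirichlet(np.full(n, 1.5), size=n) * (1.0 - end_prob)
    kernel[:, n] = end_prob
    return WorkflowModel(
        catalog=catalog,
        initial_probs=np.full(n, 1.0 / n),
        kernel=kernel,
        occurrence_mask_probs=np.ones(n),
        duration_params=np.column_stack(
            [np.full(n, np.log(120.0)) + 0.05 * np.arange(n), np.full(n, 0.4)]
        ),
        gap_params=(np.log(10.0), 0.3),
        ct_overhead_min=(np.log(60.0), 0.3),
        tot_overhead_min=(np.log(50.0), 0.3),
        max_visits=300,
    )


def chain_model() -> WorkflowModel:
    """Degenerate deterministic model: steps 1..21 in order, then END."""
    catalog = default_catalog()
    n = len(catalog)
    kernel = np.zeros((n, n + 1))
    for i in range(n - 1):
        kernel[i, i + 1] = 1.0
    kernel[n - 1, n] = 1.0
    initial = np.zeros(n)
    initial[0] = 1.0
    return WorkflowModel(
        catalog=catalog,
        initial_probs=initial,
        kernel=kernel,
        occurrence_mask_probs=np.ones(n),
        duration_params=np.column_stack([np.full(n, np.log(60.0)), np.full(n, 0.2)]),
        gap_params=(np.log(15.0), 0.2),
        ct_overhead_min=(np.log(30.0), 0.2),
        tot_overhead_min=(np.log(30.0), 0.2),
        max_visits=50,
    )


@pytest.fixture(scope="session")
def catalog() -> StepCatalog:
    return default_catalog()


@pytest.fixture(scope="session")
def model() -> WorkflowModel:
    return default_model()


@pytest.fixture(scope="session")
def small_cohort(model) -> Cohort:
    from procflow.simulate import simulate_cohort

    return simulate_cohort(model, n=31, rng_seed=7)
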