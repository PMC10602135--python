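"""Seeded generative model of annotated robotic-proctectomy workflows.

The generator emulates a 31-procedure robotic proctectomy cohort so every
pipeline stage is testable without clinical recordings.  Each procedure is
drawn in four stages:

1. **Occurrence mask** — each step is available with a per-step
   probability, reproducing step skipping (the inferior mesenteric vein
   steps appear in well under a quarter of procedures).
2. **Step walk** — a first-order Markov walk over the available steps from
   an initial-step distribution, with an absorbing END state reachable
   from every step; a hard visit cap is a backstop against pathological
   configurations.  Kernel rows are renormalized over the procedure's
   available steps.
3. **Timing** — per-step log-normal visit durations and log-normal
   inter-visit gaps laid out sequentially, so events are chronological and
   never overlap; times are kept at millisecond precision.
4. **Operative times** — console time = annotated minutes plus a
   log-normal non-annotated console overhead; total operative time adds a
   log-normal off-console overhead, so TOT >= CT by construction.

Default calibration targets the reference cohort's marginals: ~49 step
visits per procedure, posterior rectal dissection the most revisited
step, mean console time near 213 minutes and 40-100 minutes of
off-console time.  Log-normals are used because step durations are
strictly positive and right-skewed, with SDs of the same order as the
means.

A master seed spawns independent per-procedure substreams, so cohorts are
reproducible regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .annotations import AnnotationEvent, Cohort, ProcedureRecord
from .catalog import StepCatalog, default_catalog

__all__ = [
    "WorkflowModel",
    "default_model",
    "simulate_procedure",
    "simulate_cohort",
    "save_model",
    "load_model",
]

# Per-step calibration of the default 21-step model, in catalog order:
# (relative visit weight, mean visit duration in minutes, occurrence
# probability).  Visit weights are proportional to each step's cumulative
# visit count in the reference cohort; occurrence probabilities are the
# fraction of the 31 procedures in which the step occurred.
_DEFAULT_STEP_CALIBRATION: tuple[tuple[float, float, float], ...] = (
    (31, 7.584, 26 / 31),   # Initial Exposure
    (92, 2.708, 28 / 31),   # IMA dissection
    (32, 1.224, 28 / 31),   # Ligation & division of IMA
    (8, 2.120, 5 / 31),     # IMV dissection
    (6, 0.925, 6 / 31),     # Ligation & division of IMV
    (44, 3.231, 11 / 31),   # Splenic flexure mobilization (medial-to-lateral)
    (34, 3.112, 15 / 31),   # Splenic flexure mobilization (lateral-to-medial)
    (19, 6.568, 7 / 31),    # Splenic flexure mobilization (supracolic)
    (92, 2.525, 29 / 31),   # Rectal mobilization (medial-to-lateral)
    (86, 2.967, 27 / 31),   # Desc. & sigmoid colon mobilization (medial-to-lateral)
    (90, 3.395, 30 / 31),   # Desc. & sigmoid colon mobilization (lateral-to-medial)
    (261, 1.535, 30 / 31),  # Posterior rectal dissection
    (118, 1.396, 23 / 31),  # Anterior rectal dissection
    (220, 0.561, 29 / 31),  # Right lateral rectal dissection
    (135, 1.318, 30 / 31),  # Left lateral rectal dissection
    (78, 5.829, 29 / 31),   # Division of the mesorectum
    (39, 5.386, 28 / 31),   # Rectal transection
    (37, 6.001, 26 / 31),   # Division of the mesocolon
    (25, 2.327, 23 / 31),   # Proximal colon transection
    (26, 2.040, 19 / 31),   # Testing for leak (optional)
    (45, 8.812, 22 / 31),   # Colorectal anastomosis
)

#: Per-transition probability of moving to the absorbing END state; the
#: walk length is then roughly geometric with mean 1/p, targeting ~49-50
#: visits per procedure.
_DEFAULT_END_PROB = 0.02

#: Log-sd of per-visit durations (right-skewed; SD comparable to the mean).
_DEFAULT_DURATION_SIGMA = 0.9


@dataclass(frozen=True)
class WorkflowModel:
    """Generative parameters for a synthetic annotated cohort.

    ``kernel`` has shape ``(n, n + 1)``: column ``n`` is the absorbing END
    state.  ``duration_params`` are per-step ``(log_mean, log_sd)`` of the
    visit duration in seconds; ``gap_params`` the same for inter-visit
    gaps.  Overhead parameters are log-normal ``(log_mean, log_sd)`` in
    minutes.
    """

    catalog: StepCatalog
    initial_probs: np.ndarray
    kernel: np.ndarray
    occurrence_mask_probs: np.ndarray
    duration_params: np.ndarray
    gap_params: tuple[float, float]
    ct_overhead_min: tuple[float, float]
    tot_overhead_min: tuple[float, float]
    max_visits: int = 200

    def __post_init__(self) -> None:
        n = len(self.catalog)
        initial = np.asarray(self.initial_probs, dtype=float)
        kernel = np.asarray(self.kernel, dtype=float)
        masks = np.asarray(self.occurrence_mask_probs, dtype=float)
        durations = np.asarray(self.duration_params, dtype=float)
        object.__setattr__(self, "initial_probs", initial)
        object.__setattr__(self, "kernel", kernel)
        object.__setattr__(self, "occurrence_mask_probs", masks)
        object.__setattr__(self, "duration_params", durations)

        if initial.shape != (n,):
            raise ValueError(f"initial_probs must have shape ({n},)")
        if kernel.shape != (n, n + 1):
            raise ValueError(f"kernel must have shape ({n}, {n + 1}) including END")
        if masks.shape != (n,):
            raise ValueError(f"occurrence_mask_probs must have shape ({n},)")
        if durations.shape != (n, 2):
            raise ValueError(f"duration_params must have shape ({n}, 2)")
        if (initial < 0).any() or not math.isclose(initial.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("initial_probs must be a probability distribution")
        if (kernel < 0).any():
            raise ValueError("kernel entries must be non-negative")
        rowsums = kernel.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("every kernel row must sum to 1 including END")
        if ((masks < 0) | (masks > 1)).any():
            raise ValueError("occurrence_mask_probs must lie in [0, 1]")
        if self.max_visits < 1:
            raise ValueError("max_visits must be >= 1")
        self._check_end_reachable()

    def _check_end_reachable(self) -> None:
        # BFS backwards from END over kernel support; every step must reach it.
        n = len(self.catalog)
        support = self.kernel > 0
        reaches = support[:, n].copy()
        changed = True
        while changed:
            changed = False
            for i in range(n):
                if not reaches[i] and (support[i, :n] & reaches).any():
                    reaches[i] = True
                    changed = True
        if not reaches.all():
            bad = [self.catalog.step_ids[i] for i in range(n) if not reaches[i]]
            raise ValueError(f"END state unreachable from steps {bad}")

    @property
    def n_steps(self) -> int:
        return len(self.catalog)


def default_model(catalog: Optional[StepCatalog] = None) -> WorkflowModel:
    """The calibrated 21-step robotic proctectomy model."""
    catalog = catalog or default_catalog()
    n = len(catalog)
    if n != len(_DEFAULT_STEP_CALIBRATION):
        raise ValueError("default calibration is defined for the 21-step catalog")
    weights = np.array([w for w, _, _ in _DEFAULT_STEP_CALIBRATION], dtype=float)
    mean_min = np.array([m for _, m, _ in _DEFAULT_STEP_CALIBRATION], dtype=float)
    masks = np.array([p for _, _, p in _DEFAULT_STEP_CALIBRATION], dtype=float)

    # Procedures open with initial exposure in the vast majority of cases.
    initial = 0.25 * weights / weights.sum()
    initial[0] += 0.75
    initial /= initial.sum()

    # Destination preference: overall visit weight shaped by procedural
    # proximity — forward moves fall off more slowly than backtracking,
    # and self-transitions (interrupted then resumed steps) are common.
    idx = np.arange(n)
    dist = idx[None, :] - idx[:, None]
    affinity = np.where(
        dist >= 0, np.exp(-dist / 4.0), np.exp(dist / 3.0)
    ) + 0.02
    raw = weights[None, :] * affinity
    kernel = np.zeros((n, n + 1))
    kernel[:, :n] = (1.0 - _DEFAULT_END_PROB) * raw / raw.sum(axis=1, keepdims=True)
    kernel[:, n] = _DEFAULT_END_PROB

    sigma = _DEFAULT_DURATION_SIGMA
    mu = np.log(mean_min * 60.0) - sigma**2 / 2.0
    duration_params = np.column_stack([mu, np.full(n, sigma)])

    gap_sigma = 0.8
    gap_mu = math.log(45.0) - gap_sigma**2 / 2.0  # mean gap ~45 s

    ct_sigma = 0.5
    ct_mu = math.log(85.0) - ct_sigma**2 / 2.0  # mean non-annotated console ~85 min
    tot_sigma = 0.5
    tot_mu = math.log(70.0) - tot_sigma**2 / 2.0  # mean off-console ~70 min

    return WorkflowModel(
        catalog=catalog,
        initial_probs=initial,
        kernel=kernel,
        occurrence_mask_probs=masks,
        duration_params=duration_params,
        gap_params=(gap_mu, gap_sigma),
        ct_overhead_min=(ct_mu, ct_sigma),
        tot_overhead_min=(tot_mu, tot_sigma),
        max_visits=200,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_procedure(
    model: WorkflowModel, rng_seed, procedure_id: str = "P0001"
) -> ProcedureRecord:
    """Draw one annotated procedure; identical seeds give identical records."""
    rng = _as_rng(rng_seed)
    n = model.n_steps

    mask = rng.random(n) < model.occurrence_mask_probs
    if not mask.any():
        raise ValueError("no steps available after occurrence masking")

    init = model.initial_probs * mask
    if init.sum() == 0:
        # Initial preference fell entirely on masked-out steps; fall back
        # to a uniform choice over the available ones.
        init = mask.astype(float)
    init = init / init.sum()

    # Precompute masked, renormalized rows lazily (only for visited steps).
    row_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def masked_row(i: int) -> tuple[np.ndarray, np.ndarray]:
        if i not in row_cache:
            w = np.empty(n + 1)
            w[:n] = model.kernel[i, :n] * mask
            w[n] = model.kernel[i, n]
            total = w.sum()
            if total == 0:  # defensive: row support entirely masked and no END mass
                w[n] = 1.0
                total = 1.0
            cdf = np.cumsum(w / total)
            row_cache[i] = (w, cdf)
        return row_cache[i]

    current = int(rng.choice(n, p=init))
    walk = [current]
    while len(walk) < model.max_visits:
        _, cdf = masked_row(current)
        nxt = int(np.searchsorted(cdf, rng.random(), side="right"))
        if nxt >= n:  # END
            break
        current = nxt
        walk.append(current)

    steps = np.array(walk, dtype=int)
    mus = model.duration_params[steps, 0]
    sigmas = model.duration_params[steps, 1]
    durations = rng.lognormal(mean=mus, sigma=sigmas)
    gap_mu, gap_sigma = model.gap_params
    gaps = rng.lognormal(mean=gap_mu, sigma=gap_sigma, size=len(steps))

    events = []
    t = round(float(gaps[0]), 3)
    for k, step_idx in enumerate(steps):
        start = t
        stop = round(start + max(float(durations[k]), 0.002), 3)
        events.append(
            AnnotationEvent(
                procedure_id=procedure_id,
                step_id=model.catalog.step_ids[int(step_idx)],
                start_s=start,
                stop_s=stop,
            )
        )
        if k + 1 < len(steps):
            t = round(stop + max(float(gaps[k + 1]), 0.001), 3)

    annotated_min = sum(ev.duration_s for ev in events) / 60.0
    ct = annotated_min + float(rng.lognormal(*model.ct_overhead_min))
    tot = ct + float(rng.lognormal(*model.tot_overhead_min))
    return ProcedureRecord(
        procedure_id=procedure_id,
        events=tuple(events),
        console_time_min=round(ct, 2),
        total_operative_time_min=round(tot, 2),
    )


def simulate_cohort(model: WorkflowModel, n: int, rng_seed: int) -> Cohort:
    """Simulate ``n`` procedures ("P0001"...) from per-procedure substreams."""
    if n < 1:
        raise ValueError("n must be >= 1")
    streams = np.random.SeedSequence(rng_seed).spawn(n)
    procedures = tuple(
        simulate_procedure(model, np.random.default_rng(ss), procedure_id=f"P{k + 1:04d}")
        for k, ss in enumerate(streams)
    )
    return Cohort(catalog=model.catalog, procedures=procedures)


# -- model config io ---------------------------------------------------------


def save_model(model: WorkflowModel, path: str | Path) -> None:
    """Serialize a model to YAML (lossless for float64 parameters)."""
    doc = {
        "catalog": [[int(i), str(name)] for i, name in model.catalog],
        "initial": [float(v) for v in model.initial_probs],
        "kernel": [[float(v) for v in row] for row in model.kernel],
        "masks": [float(v) for v in model.occurrence_mask_probs],
        "durations": [[float(a), float(b)] for a, b in model.duration_params],
        "gaps": [float(model.gap_params[0]), float(model.gap_params[1])],
        "overheads": {
            "console_min": [float(v) for v in model.ct_overhead_min],
            "total_min": [float(v) for v in model.tot_overhead_min],
        },
        "max_visits": int(model.max_visits),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path: str | Path) -> WorkflowModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    catalog = StepCatalog(tuple((int(i), str(name)) for i, name in doc["catalog"]))
    return WorkflowModel(
        catalog=catalog,
        initial_probs=np.array(doc["initial"], dtype=float),
        kernel=np.array(doc["kernel"], dtype=float),
        occurrence_mask_probs=np.array(doc["masks"], dtype=float),
        duration_params=np.array(doc["durations"], dtype=float),
        gap_params=(float(doc["gaps"][0]), float(doc["gaps"][1])),
        ct_overhead_min=tuple(float(v) for v in doc["overheads"]["console_min"]),
        tot_overhead_min=tuple(float(v) for v in doc["overheads"]["total_min"]),
        max_visits=int(doc["max_visits"]),
    )
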