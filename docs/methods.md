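# Methods

## The problem

Robotic procedures can be segmented into named surgical steps by
annotating start and stop times on recorded video.  A surgeon may skip a
step, perform it once, or revisit it repeatedly, so the resulting event
log is a sequence of timed *step visits* rather than a fixed phase
ordering.  `procflow` quantifies that workflow three ways: per-step time
and visit-frequency statistics, rank correlations of those metrics with
console time (CT) and total operative time (TOT), and a first-order
transition analysis that classifies steps as nodal, convergent or
divergent.  The built-in vocabulary is a 21-step robotic proctectomy
catalog; any catalog of two or more steps is accepted.

## Annotation model

A visit is a half-open interval `[start_s, stop_s)` in seconds on the
procedure's own clock; the origin is deliberately unspecified (skin
incision vs first console event differs between institutions), and no
statistic depends on it — per-procedure transition structure is invariant
under uniform time shifts.  Half-open intervals make adjacent visits that
share a boundary legal and prevent double counting.  Durations are
strictly positive; within a procedure visits must be pairwise disjoint,
because the annotation protocol records one active step at a time at the
console.  Three overlap policies are provided: `error` (default, the
protocol's contract), `truncate` (clip the later visit's start to the
earlier visit's stop; a visit swallowed whole is dropped), and `warn`.
Truncation is idempotent: a repaired cohort re-validates clean.  Events
with equal starts keep file order and raise a warning; CT and TOT are
external measurements joined from a metadata file, never inferred from
annotations.  Annotation times are stored in seconds at millisecond
precision and reported in minutes, rounded to two decimals only at the
presentation layer.

## Per-step statistics

For each step the summary reports cumulative time and cumulative visit
count across the cohort, and the mean ± SD of per-procedure step time and
visit count.  Means and SDs are taken **over only the procedures in which
the step occurs**; skipped procedures are not zero-filled.  Zero-filling
would let occurrence frequency dominate every statistic of a rarely
performed step (the inferior mesenteric vein steps occur in a small
minority of procedures) and would manufacture spurious correlations from
absence alone.  SDs are sample (n−1) SDs, conventional for small clinical
cohorts.  A step occurring in a single procedure has an undefined SD,
reported as NA; a step never occurring has all statistics NA.

Associations with CT and TOT use Spearman's rank correlation with average
ranks for ties (computed as the product-moment correlation of the rank
vectors).  Pairs come from the same occurring-procedure subset, further
restricted to procedures where the operative time is recorded.  The
coefficient is NA when fewer than three pairs remain or either vector is
constant — notably a step always visited exactly once has constant visit
frequency and hence NA visit correlations.  NA is never rendered as 0.
No p-values or confidence intervals are attached; with ~31 procedures the
coefficients are descriptive.

A known quirk of occurring-subset accounting in the reference summary
statistics this package emulates: one rarely performed step's cumulative
and mean values imply five occurring procedures while the accompanying
narrative says four.  The package always computes the denominator from
the data, so such discrepancies cannot arise internally.

## Transitions and classification

The visit sequence is the chronological list of step ids; consecutive
pairs within a procedure are transitions (never across procedures).  The
cohort transition matrix holds raw counts — no smoothing or row
normalization — because chord-diagram ribbons encode frequencies.  Flow
conservation holds exactly: a step's row sum equals its occurrences minus
the procedures that end on it, and its column sum equals occurrences
minus the procedures that start on it.

Self-transitions (a step immediately revisited) are counted in the matrix
— chord plots draw them as ribbons entering and exiting one step — but
excluded from distinct-neighbor counts by default, since classification
is about *different* steps preceding and following; `include_self`
reverses this.  An optional `merge_gap_s` fuses same-step visits
separated by less than a gap, for logs where brief interruptions split
one visit; the default is 0 (no merging).

Classification compares the number of distinct predecessor and successor
step types to a threshold (default 10): at least the threshold on both
sides is **nodal**; fewer preceding and strictly more following is
**divergent**; strictly more preceding and fewer following is
**convergent**.  The stated rules overlap at exactly the threshold, so
the nodal rule is evaluated first; counts of exactly (10, 10) are nodal.
Steps matching no rule are **unclassified** — only a subset of steps is
expected to earn a class.  The classifier is monotone: increasing either
count never demotes a nodal step.

## Synthetic cohort generator

No clinical annotations ship with the package, so a seeded generative
model stands in for a recorded cohort.  Each procedure is drawn as:

1. **Occurrence mask** — each step is independently available with a
   per-step probability (the fraction of reference procedures in which
   the step occurred, e.g. ≈5/31 for the IMV steps).  Masking is drawn
   before the walk so step skipping is independent of transition
   dynamics.
2. **Markov walk** — from an initial-step distribution (weighted heavily
   toward initial exposure), a first-order walk over the available steps.
   Kernel rows are renormalized over the mask; each row carries 0.02
   probability of moving to an absorbing END state, giving a roughly
   geometric walk length with mean ≈50 visits.  A 200-visit hard cap is a
   termination backstop.  Destination preference combines each step's
   overall visit weight with procedural proximity (forward moves decay
   more slowly than backtracking; self-transitions are common), which
   yields the convergent/divergent heterogeneity the transition analysis
   expects.
3. **Timing** — per-step log-normal visit durations (log-sd 0.9, log-mean
   set so the arithmetic mean matches each step's mean visit duration in
   minutes) and log-normal inter-visit gaps (mean ≈45 s).  Events are
   laid out sequentially — each starts after the previous stops — so
   generated cohorts are overlap-free by construction.  Log-normals are
   used because durations are strictly positive and right-skewed, with
   SDs of the same order as the means.
4. **Operative times** — CT is the annotated time plus a log-normal
   non-annotated console overhead (mean ≈85 min); TOT adds a log-normal
   off-console overhead (mean ≈70 min), so TOT ≥ CT by construction.

Calibration targets coarse cohort marginals, not exact per-step moments
(matching 21 coupled marginals exactly is neither feasible from summary
statistics nor needed for testing): ~40–60 visits per procedure,
posterior rectal dissection among the most revisited steps, IMV steps in
well under a quarter of procedures, mean CT within 170–260 min and 40–100
min of off-console time.  These checks run on a 500-procedure cohort in
the test suite.  Known departures from real data: walk lengths are
near-geometric, so visit-count dispersion exceeds a real cohort's; step
durations are independent of case factors, so cross-step correlations
with CT arise only through shared walk length; and per-visit counts of
individual steps track visit weights only approximately once masking
renormalizes the kernel.  Passing tests therefore demonstrate pipeline
correctness and calibration to the stated ranges, not clinical realism of
any individual simulated procedure.

Randomness follows one master seed: a `SeedSequence` spawns an
independent substream per procedure, so cohorts are reproducible and
byte-identical across runs regardless of generation order.  Models
serialize losslessly to YAML.

## Numerical and testing choices

* All statistics are computed at full double precision; rounding (two
  decimals for minutes and correlations, one for cohort means) happens
  only when tables are rendered.  NA renders literally as `NA`.
* The Spearman implementation is verified against an independent
  brute-force oracle (explicit average-rank enumeration followed by a
  hand-written Pearson formula) on 1000 random vectors, to 1e-12.
* Sampler fidelity is checked on an evenly trafficked test model (a
  seeded Dirichlet kernel with all steps always available): with the
  default model's highly skewed visit weights, rarely visited steps do
  not accrue enough row samples at n = 5000 for a ±0.02 bound to be a
  meaningful estimator check.  Kernel recovery uses 5000 procedures;
  empirical row frequencies at 2000; duration-mean recovery (within 5%)
  at 5000.  Flow conservation is checked exactly on 200 seeded cohorts.
* The analysis scripts simulate a 31-procedure cohort (seed 20231),
  mirroring the cohort size the default calibration emulates.

## Limitations

First-order transitions only (no semi-Markov or higher-order structure);
no fitting of the generative model to raw data; chord-diagram rendering
is a best-effort heatmap — the exported matrix, not the figure, is the
normative artifact; no surgeon- or case-mix covariates.
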