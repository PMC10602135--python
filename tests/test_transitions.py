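import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from procflow.simulate import simulate_cohort
from procflow.transitions import (
    TransitionMatrix,
    classify_step,
    export_chord_matrix,
    load_chord_matrix,
    neighbor_counts,
    profile_steps,
    transition_matrix,
    transition_pairs,
    visit_sequence,
)

from .conftest import cohort_from_sequences, make_procedure, uniform_traffic_model


class TestVisitSequence:
    def test_orders_by_start(self):
        proc = make_procedure(
            "P1", [(2, 0.0, 60.0), (9, 100.0, 200.0), (2, 250.0, 300.0)]
        )
        assert visit_sequence(proc).step_ids == (2, 9, 2)

    def test_empty_procedure(self):
        proc = make_procedure("P1", [])
        assert visit_sequence(proc).step_ids == ()

    def test_merge_gap_fuses_same_step_visits(self):
        proc = make_procedure("P1", [(4, 0.0, 60.0), (4, 70.0, 120.0)])
        assert visit_sequence(proc).step_ids == (4, 4)
        assert visit_sequence(proc, merge_gap_s=30.0).step_ids == (4,)
        # gap of exactly the threshold is not fused
        assert visit_sequence(proc, merge_gap_s=10.0).step_ids == (4, 4)

    def test_merge_does_not_fuse_across_other_steps(self):
        proc = make_procedure(
            "P1", [(4, 0.0, 60.0), (7, 61.0, 62.0), (4, 63.0, 120.0)]
        )
        assert visit_sequence(proc, merge_gap_s=30.0).step_ids == (4, 7, 4)

    def test_negative_gap_rejected(self):
        proc = make_procedure("P1", [])
        with pytest.raises(ValueError):
            visit_sequence(proc, merge_gap_s=-1.0)


class TestTransitionPairs:
    def test_consecutive_pairs(self):
        seq = visit_sequence(
            make_procedure(
                "P1",
                [(2, 0, 10), (9, 20, 30), (2, 40, 50), (12, 60, 70)],
            )
        )
        assert transition_pairs(seq) == [(2, 9), (9, 2), (2, 12)]

    def test_single_visit_has_no_pairs(self):
        seq = visit_sequence(make_procedure("P1", [(5, 0, 10)]))
        assert transition_pairs(seq) == []

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 21), max_size=40))
    def test_matches_sliding_window_oracle(self, ids):
        from procflow.transitions import VisitSequence

        seq = VisitSequence("P1", tuple(ids))
        expected = [(ids[k], ids[k + 1]) for k in range(max(0, len(ids) - 1))]
        assert transition_pairs(seq) == expected


class TestTransitionMatrix:
    def test_two_procedure_example(self, catalog):
        cohort = cohort_from_sequences(catalog, [[1, 2], [2, 1]])
        m = transition_matrix(cohort)
        assert m.get(1, 2) == 1 and m.get(2, 1) == 1
        assert m.total() == 2

    def test_single_visit_procedures_contribute_nothing(self, catalog):
        cohort = cohort_from_sequences(catalog, [[1], [2], [3]])
        assert transition_matrix(cohort).total() == 0

    def test_self_transitions_counted(self, catalog):
        cohort = cohort_from_sequences(catalog, [[12, 12, 12]])
        assert transition_matrix(cohort).get(12, 12) == 2

    def test_total_conservation_on_synthetic(self, small_cohort):
        m = transition_matrix(small_cohort)
        expected = sum(max(0, p.n_events - 1) for p in small_cohort.procedures)
        assert m.total() == expected

    def test_flow_conservation_rows_and_columns(self, small_cohort):
        m = transition_matrix(small_cohort)
        firsts = {}
        lasts = {}
        occ = {s: 0 for s in small_cohort.catalog.step_ids}
        for p in small_cohort.procedures:
            seq = visit_sequence(p).step_ids
            for s in seq:
                occ[s] += 1
            if seq:
                firsts[seq[0]] = firsts.get(seq[0], 0) + 1
                lasts[seq[-1]] = lasts.get(seq[-1], 0) + 1
        for s in small_cohort.catalog.step_ids:
            assert m.row_sum(s) == occ[s] - lasts.get(s, 0)
            assert m.col_sum(s) == occ[s] - firsts.get(s, 0)

    def test_invariant_under_time_shift(self, catalog):
        base = [(2, 0.0, 60.0), (9, 100.0, 200.0), (2, 250.0, 300.0)]
        shifted = [(s, a + 5000.0, b + 5000.0) for s, a, b in base]
        from procflow.annotations import Cohort

        c1 = Cohort(catalog, (make_procedure("P1", base),))
        c2 = Cohort(catalog, (make_procedure("P1", shifted),))
        assert (transition_matrix(c1).counts == transition_matrix(c2).counts).all()

    def test_empty_cohort_rejected(self, catalog):
        from procflow.annotations import Cohort

        with pytest.raises(ValueError):
            transition_matrix(Cohort(catalog, ()))

    def test_negative_counts_rejected(self, catalog):
        bad = np.zeros((21, 21), dtype=np.int64)
        bad[0, 1] = -1
        with pytest.raises(ValueError):
            TransitionMatrix(catalog, bad)


class TestNeighborCounts:
    def test_zero_matrix(self, catalog):
        m = TransitionMatrix(catalog, np.zeros((21, 21), dtype=np.int64))
        assert neighbor_counts(m, 9) == (0, 0)

    def test_distinct_predecessors(self, catalog):
        counts = np.zeros((21, 21), dtype=np.int64)
        for src in (2, 12, 15):
            counts[src - 1, 8] = 4  # into step 9
        m = TransitionMatrix(catalog, counts)
        assert neighbor_counts(m, 9) == (3, 0)

    def test_self_excluded_by_default(self, catalog):
        counts = np.zeros((21, 21), dtype=np.int64)
        counts[8, 8] = 7
        counts[1, 8] = 1
        m = TransitionMatrix(catalog, counts)
        assert neighbor_counts(m, 9) == (1, 0)
        assert neighbor_counts(m, 9, include_self=True) == (2, 1)

    def test_matches_set_oracle_on_random_matrices(self, catalog):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 3, size=(21, 21))
            m = TransitionMatrix(catalog, counts)
            for step in catalog.step_ids:
                k = step - 1
                pre = {i + 1 for i in range(21) if counts[i, k] > 0 and i != k}
                post = {j + 1 for j in range(21) if counts[k, j] > 0 and j != k}
                assert neighbor_counts(m, step) == (len(pre), len(post))


class TestClassifyStep:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (10, 10, "nodal"),
            (9, 11, "divergent"),
            (11, 9, "convergent"),
            (5, 5, "unclassified"),
            (9, 10, "unclassified"),  # following not strictly above threshold
            (10, 9, "unclassified"),
            (0, 0, "unclassified"),
        ],
    )
    def test_threshold_boundaries(self, pre, post, expected):
        assert classify_step(pre, post) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_step(-1, 5)

    def test_threshold_zero_makes_everything_nodal(self):
        assert classify_step(1, 1, threshold=0) == "nodal"
        assert classify_step(0, 5, threshold=0) == "nodal"

    def test_threshold_above_catalog_size_never_nodal(self):
        for pre in range(22):
            for post in range(22):
                assert classify_step(pre, post, threshold=25) != "nodal"

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        pre=st.integers(0, 21),
        post=st.integers(0, 21),
        dpre=st.integers(0, 5),
        dpost=st.integers(0, 5),
    )
    def test_nodal_is_monotone(self, pre, post, dpre, dpost):
        if classify_step(pre, post) == "nodal":
            assert classify_step(pre + dpre, post + dpost) == "nodal"


class TestProfileSteps:
    def test_strict_chain_is_unclassified(self, catalog):
        cohort = cohort_from_sequences(catalog, [list(range(1, 22))] * 5)
        profiles = profile_steps(cohort)
        by_id = {p.step_id: p for p in profiles}
        for step in range(2, 21):
            assert (by_id[step].n_preceding_types, by_id[step].n_following_types) == (1, 1)
            assert by_id[step].step_class == "unclassified"
        assert by_id[1].n_preceding_types == 0
        assert by_id[21].n_following_types == 0

    def test_hub_step_is_nodal(self, catalog):
        # every other step routes through step 12
        seqs = [[k, 12, k] for k in range(1, 22) if k != 12]
        cohort = cohort_from_sequences(catalog, seqs)
        profiles = {p.step_id: p for p in profile_steps(cohort)}
        assert profiles[12].n_preceding_types == 20
        assert profiles[12].n_following_types == 20
        assert profiles[12].step_class == "nodal"
        # spokes see only the hub
        assert profiles[3].step_class == "unclassified"

    def test_cumulative_visits_match_matrix_margins(self, small_cohort):
        profiles = {p.step_id: p for p in profile_steps(small_cohort)}
        m = transition_matrix(small_cohort)
        firsts = {}
        lasts = {}
        for p in small_cohort.procedures:
            seq = visit_sequence(p).step_ids
            if seq:
                firsts[seq[0]] = firsts.get(seq[0], 0) + 1
                lasts[seq[-1]] = lasts.get(seq[-1], 0) + 1
        for step, prof in profiles.items():
            assert m.row_sum(step) == prof.cumulative_visits - lasts.get(step, 0)
            assert m.col_sum(step) == prof.cumulative_visits - firsts.get(step, 0)

    def test_dense_kernel_hub_from_generator(self):
        """A generator kernel with every destination trafficked makes well
        sampled steps nodal in a large cohort."""
        model = uniform_traffic_model(seed=42)
        cohort = simulate_cohort(model, n=60, rng_seed=3)
        profiles = {p.step_id: p for p in profile_steps(cohort)}
        # with ~50 visits/procedure over 60 procedures and a dense kernel,
        # every step accrues well over 10 neighbor types each way
        nodal = [p for p in profiles.values() if p.step_class == "nodal"]
        assert len(nodal) == 21


class TestChordExport:
    def test_two_step_matrix_grid(self, tmp_path):
        from procflow.catalog import StepCatalog

        cat = StepCatalog(((1, "open"), (2, "close")))
        m = TransitionMatrix(cat, np.array([[0, 3], [1, 2]]))
        path = tmp_path / "chord.tsv"
        export_chord_matrix(m, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0].split("\t") == ["step", "open", "close"]
        assert lines[1].split("\t") == ["open", "0", "3"]

    def test_round_trip(self, tmp_path, small_cohort):
        m = transition_matrix(small_cohort)
        path = tmp_path / "chord.tsv"
        export_chord_matrix(m, path)
        loaded = load_chord_matrix(path, small_cohort.catalog)
        assert (loaded.counts == m.counts).all()

    def test_zero_matrix_round_trip(self, tmp_path, catalog):
        m = TransitionMatrix(catalog, np.zeros((21, 21), dtype=np.int64))
        path = tmp_path / "chord.tsv"
        export_chord_matrix(m, path)
        assert load_chord_matrix(path, catalog).total() == 0

    def test_mismatched_catalog_rejected(self, tmp_path, small_cohort):
        from procflow.catalog import StepCatalog

        m = transition_matrix(small_cohort)
        path = tmp_path / "chord.tsv"
        export_chord_matrix(m, path)
        other = StepCatalog(((1, "a"), (2, "b")))
        with pytest.raises(ValueError):
            load_chord_matrix(path, other)
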