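import numpy as np
import pytest

from lfpstates.errors import InsufficientDataError, InvalidParameterError
from lfpstates.markov import (
    REPORT_FLOOR,
    apply_report_floor,
    dwell_distribution_fit,
    estimate_transition_matrix,
    extract_dwells,
    jackknife_bounds,
    per_concentration_matrices,
    stickiness_ratio,
)
from lfpstates.synthgen import build_transition_matrix, sample_state_sequence
from lfpstates.types import DwellRecord, StateSequence, TransitionMatrix


def _seq(labels, wd=10.0, subject="s0", condition="c0"):
    return StateSequence(np.asarray(labels), wd, subject, condition)


class TestEstimateTransitionMatrix:
    def test_hand_enumerated_counts(self):
        # [0,0,0,1,1,0]: pairs 00,00,01,11,10
        C, T = estimate_transition_matrix([_seq([0, 0, 0, 1, 1, 0])], 2)
        assert C.C.tolist() == [[2, 1], [1, 1]]
        assert np.allclose(T.P, [[2 / 3, 1 / 3], [1 / 2, 1 / 2]])
        assert C.total_transitions == 5

    def test_constant_sequence_flags_other_rows(self):
        C, T = estimate_transition_matrix([_seq([0] * 100)], 3)
        assert np.allclose(T.P[0], [1, 0, 0])
        assert T.unobserved_rows == {1, 2}

    def test_no_counting_across_sequence_boundaries(self):
        C, _ = estimate_transition_matrix([_seq([0, 0]), _seq([1, 1])], 2)
        assert C.C.tolist() == [[1, 0], [0, 1]]

    def test_consistency_at_long_sequences(self):
        # entrywise |P_hat - T| <= 3 binomial SE at 50,000 windows
        T = build_transition_matrix(2, 60.0)
        seq = sample_state_sequence(T, 50_000, seed=17)
        C, T_hat = estimate_transition_matrix([seq], 2)
        row_n = C.C.sum(axis=1)
        for i in range(2):
            for j in range(2):
                se = np.sqrt(T.P[i, j] * (1 - T.P[i, j]) / row_n[i])
                assert abs(T_hat.P[i, j] - T.P[i, j]) <= 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_transition_matrix([], 2)


class TestReportFloor:
    def test_zero_entries_raised_to_floor(self):
        _, T = estimate_transition_matrix([_seq([0, 0, 1, 1])], 2)
        R = apply_report_floor(T)
        assert R.P_report[0, 1] > 0
        assert R.P_report[1, 0] == REPORT_FLOOR

    def test_large_entries_unchanged(self):
        P = TransitionMatrix((0, 1), np.array([[0.5, 0.5], [0.5, 0.5]]), 10.0)
        R = apply_report_floor(P)
        assert np.allclose(R.P_report, 0.5)

    def test_unobserved_state_row_and_column_floored(self):
        P = build_transition_matrix(4, 10.0)
        R = apply_report_floor(P, unobserved_states={3})
        assert np.all(R.P_report[3, :] == REPORT_FLOOR)
        assert np.all(R.P_report[:, 3] == REPORT_FLOOR)
        # underlying estimate retained unmodified
        assert np.allclose(R.P_underlying, P.P)

    def test_floor_idempotent(self):
        P = build_transition_matrix(8, 2000.0)
        once = apply_report_floor(P)
        twice = apply_report_floor(once.P_report)
        assert np.array_equal(once.P_report, twice.P_report)


class TestJackknife:
    def test_identical_subjects_zero_width(self):
        labels = [0, 0, 1, 1, 0, 0, 1]
        per_subj = {f"s{i}": [_seq(labels, subject=f"s{i}")] for i in range(5)}
        lo, hi = jackknife_bounds(per_subj, 2)
        assert np.allclose(lo.P_report, hi.P_report)

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            jackknife_bounds({"s0": [_seq([0, 1, 0])]}, 2)

    def test_bounds_bracket_pooled_estimate(self, markov_sequences):
        T, per_subj = markov_sequences
        all_seqs = [s for v in per_subj.values() for s in v]
        _, pooled = estimate_transition_matrix(all_seqs, 2)
        lo, hi = jackknife_bounds(per_subj, 2)
        pooled_report = np.clip(pooled.P, REPORT_FLOOR, 1.0)
        assert np.all(lo.P_report <= pooled_report + 1e-12)
        assert np.all(pooled_report <= hi.P_report + 1e-12)

    def test_coverage_over_replicate_cohorts(self):
        # true T inside the 95% limits for >= 90% of entries over 100 cohorts
        T = build_transition_matrix(2, 60.0)
        covered = total = 0
        for rep in range(100):
            per_subj = {}
            for s in range(5):
                seed = np.random.SeedSequence(rep, spawn_key=(s,))
                per_subj[f"s{s}"] = [
                    sample_state_sequence(T, 2000, seed=seed, subject_id=f"s{s}")
                ]
            lo, hi = jackknife_bounds(per_subj, 2)
            truth = np.clip(T.P, REPORT_FLOOR, 1.0)
            ok = (lo.P_report <= truth + 1e-12) & (truth <= hi.P_report + 1e-12)
            covered += int(ok.sum())
            total += ok.size
        assert covered / total >= 0.90


class TestPerConcentration:
    def test_absent_state_floored_per_condition(self):
        by_cond = {
            "deep": [_seq([0, 1, 0, 1, 2, 0], condition="deep")],
            "light": [_seq([1, 1, 1, 1], condition="light")],
        }
        out = per_concentration_matrices(by_cond, 3)
        assert set(out) == {"deep", "light"}
        light = out["light"]
        assert light.unobserved_states == {0, 2}
        assert np.all(light.P_report[0, :] == REPORT_FLOOR)
        assert np.all(light.P_report[:, 2] == REPORT_FLOOR)
        assert light.P_report[1, 1] == 1.0

    def test_identical_conditions_agree_within_sampling_error(self):
        T = build_transition_matrix(2, 20.0)
        by_cond = {
            c: [sample_state_sequence(T, 20_000, seed=i, condition=c)]
            for i, c in enumerate(["a", "b", "c"])
        }
        out = per_concentration_matrices(by_cond, 2)
        mats = [r.P_underlying for r in out.values()]
        for M in mats[1:]:
            assert np.max(np.abs(M - mats[0])) < 0.02


class TestExtractDwells:
    def test_run_lengths_by_hand(self):
        dwells = extract_dwells([_seq([0, 0, 0, 1, 1, 0])])
        assert [(d.state, d.duration_s) for d in dwells] == [
            (0, 30.0),
            (1, 20.0),
            (0, 10.0),
        ]
        assert [d.censored for d in dwells] == [True, False, True]
        assert sum(d.duration_s for d in dwells) == 60.0

    def test_constant_sequence_single_censored_dwell(self):
        dwells = extract_dwells([_seq([2] * 10)])
        assert len(dwells) == 1
        assert dwells[0].duration_s == 100.0
        assert dwells[0].censored

    def test_alternating_sequence_unit_dwells(self):
        dwells = extract_dwells([_seq([0, 1] * 5)])
        assert all(d.duration_s == 10.0 for d in dwells)
        assert len(dwells) == 10


class TestDwellFit:
    def _records(self, windows, wd=10.0):
        return [DwellRecord(0, float(w) * wd) for w in windows]

    def test_constant_dwells_rate_exact(self):
        fit = dwell_distribution_fit(self._records([6] * 30), 10.0)
        assert fit.rate_per_s == pytest.approx(1 / 60.0)
        assert fit.mean_dwell_s == 60.0

    def test_geometric_dwells_prefer_exponential(self):
        rng = np.random.default_rng(23)
        prefer = 0
        means_ok = 0
        for rep in range(100):
            d = rng.geometric(1 / 60, size=5000)
            fit = dwell_distribution_fit(self._records(d), 10.0)
            prefer += fit.preferred == "exponential"
            se = np.sqrt(59 * 60) / np.sqrt(5000) * 10.0
            means_ok += abs(fit.mean_dwell_s - 600.0) <= 3 * se
        assert prefer >= 95
        assert means_ok >= 95

    def test_powerlaw_dwells_prefer_powerlaw(self):
        rng = np.random.default_rng(29)
        prefer = 0
        for rep in range(20):
            u = rng.random(2000)
            d = np.floor(1.5 * (1 - u) ** (-1 / 1.5) + 0.5).astype(int)
            fit = dwell_distribution_fit(self._records(d), 10.0)
            prefer += fit.preferred == "powerlaw"
        assert prefer > 10

    def test_too_few_dwells_rejected(self):
        with pytest.raises(InsufficientDataError):
            dwell_distribution_fit(self._records([3] * 5), 10.0)

    def test_censored_dwells_excluded(self):
        recs = self._records([6] * 30) + [DwellRecord(0, 1e6, censored=True)]
        fit = dwell_distribution_fit(recs, 10.0)
        assert fit.mean_dwell_s == 60.0


class TestStickiness:
    def test_two_state_example(self):
        P = TransitionMatrix((0, 1), np.array([[0.99, 0.01], [0.01, 0.99]]), 10.0)
        assert stickiness_ratio(P) == pytest.approx(99.0)

    def test_uniform_matrix_is_one(self):
        P = TransitionMatrix((0, 1, 2), np.full((3, 3), 1 / 3), 10.0)
        assert stickiness_ratio(P) == pytest.approx(1.0)

    def test_metastable_cohort_estimate_above_ten(self):
        T = build_transition_matrix(2, 60.0)
        seq = sample_state_sequence(T, 20_000, seed=31)
        _, T_hat = estimate_transition_matrix([seq], 2)
        assert stickiness_ratio(T_hat) >= 10.0
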