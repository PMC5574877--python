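import numpy as np
import pytest

from lfpstates.errors import (
    DegenerateReferenceError,
    EmptySelectionError,
    InvalidParameterError,
)
from lfpstates.spectral import (
    circular_shift_average,
    compute_spectrogram,
    db_deviation,
    decimate_to,
    find_spectral_peaks,
    welch_average_at_times,
    zero_phase_lowpass,
)
from lfpstates.types import SignalTrace, Spectrogram


def _trace(samples, fs=1000.0):
    return SignalTrace(np.asarray(samples, dtype=float), fs)


class TestLowpass:
    def test_dc_passband_identity(self):
        x = _trace(np.ones(5000))
        y = zero_phase_lowpass(x, 100.0, 4)
        assert np.max(np.abs(y.samples - 1.0)) < 1e-6

    def test_tone_at_twice_cutoff_heavily_attenuated(self):
        # order-4 Butterworth applied forward and backward: >= 40 dB at 2 fc
        fs, fc = 1000.0, 100.0
        t = np.arange(int(10 * fs)) / fs
        x = _trace(np.sin(2 * np.pi * 2 * fc * t), fs)
        y = zero_phase_lowpass(x, fc, 4)
        mid = slice(1000, -1000)  # avoid edge transients
        ratio = np.std(y.samples[mid]) / np.std(x.samples[mid])
        assert ratio < 10 ** (-40 / 20)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            zero_phase_lowpass(_trace(np.zeros(100)), 500.0, 4)


class TestDecimate:
    def test_integer_factor_preserves_duration(self):
        x = _trace(np.random.default_rng(0).standard_normal(40_000), 4000.0)
        y = decimate_to(x, 1000.0)
        assert y.sampling_rate_hz == 1000.0
        assert y.n_samples == 10_000
        assert abs(y.duration_s - x.duration_s) < 1 / 1000.0

    def test_identity_when_rates_match(self):
        x = _trace(np.arange(100.0), 1000.0)
        y = decimate_to(x, 1000.0)
        assert np.array_equal(y.samples, x.samples)

    def test_upsampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            decimate_to(_trace(np.zeros(100)), 3000.0)

    def test_band_limited_tone_amplitude_preserved_through_chain(self):
        # filter + decimate on a tone far below cutoff keeps amplitude within 1%
        fs = 4000.0
        t = np.arange(int(40 * fs)) / fs
        x = _trace(np.sin(2 * np.pi * 6.0 * t), fs)
        y = decimate_to(zero_phase_lowpass(x, 500.0, 4), 1000.0)
        mid = slice(2000, -2000)
        assert np.std(y.samples[mid]) == pytest.approx(np.std(x.samples[mid]), rel=0.01)


class TestComputeSpectrogram:
    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(1)
        x = _trace(rng.standard_normal(500_000), 500.0)
        S = compute_spectrogram(x, 10.0, (0.5, 200.0))
        assert S.n_windows == 100
        avg = S.power.mean(axis=0)
        assert avg.max() / avg.min() < 2.0

    def test_pure_tone_argmax_in_every_window(self):
        fs = 250.0
        t = np.arange(int(100 * fs)) / fs
        x = _trace(np.sin(2 * np.pi * 6.0 * t), fs)
        S = compute_spectrogram(x, 10.0, (0.5, 20.0))
        peak_freqs = S.freqs_hz[np.argmax(S.power, axis=1)]
        assert np.all(np.abs(peak_freqs - 6.0) <= 0.1 + 1e-9)

    def test_window_count(self):
        x = _trace(np.zeros(int(3600 * 125)), 125.0)
        S = compute_spectrogram(x, 10.0, (0.5, 60.0))
        assert S.n_windows == 360

    def test_inverted_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_spectrogram(_trace(np.zeros(10_000)), 1.0, (20.0, 5.0))


class TestDbDeviation:
    def test_stationary_spectrogram_gives_zero_db(self):
        power = np.tile([[1.0, 2.0, 3.0]], (5, 1))
        S = Spectrogram(power, np.arange(5) * 10.0, np.array([1.0, 2.0, 3.0]), 10.0)
        db = db_deviation(S)
        assert np.allclose(db.db, 0.0, atol=1e-12)

    def test_two_window_hand_computed_case(self):
        # windows at 2x and 1x: ratios 4/3 and 2/3 -> +1.2494 / -1.7609 dB
        S = Spectrogram(
            np.array([[2.0], [1.0]]), np.array([0.0, 10.0]), np.array([5.0]), 10.0
        )
        db = db_deviation(S)
        assert db.db[0, 0] == pytest.approx(10 * np.log10(4 / 3), abs=1e-4)
        assert db.db[1, 0] == pytest.approx(10 * np.log10(2 / 3), abs=1e-4)
        # mean linear ratio is exactly 1
        assert np.mean(10 ** (db.db[:, 0] / 10)) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(3)
        power = rng.exponential(size=(40, 7))
        S = Spectrogram(power, np.arange(40) * 2.0, np.arange(1.0, 8.0), 2.0)
        db = db_deviation(S)
        assert np.allclose(db.to_linear(), power, rtol=1e-9)

    def test_all_zero_bin_rejected(self):
        power = np.ones((4, 2))
        power[:, 1] = 0.0
        S = Spectrogram(power, np.arange(4) * 1.0, np.array([1.0, 2.0]), 1.0)
        with pytest.raises(DegenerateReferenceError):
            db_deviation(S)


class TestDbDeviationCohort:
    def test_per_subject_reference_preserves_single_state_signature(self):
        from lfpstates.spectral import db_deviation_cohort

        freqs = np.array([2.0, 6.0])
        vA, vB = np.array([1.0, 4.0]), np.array([4.0, 1.0])
        mixed = Spectrogram(
            np.vstack([vA, vB, vA, vB]), np.arange(4) * 10.0, freqs, 10.0,
            subject_id="s0", condition="deep",
        )
        pure = Spectrogram(
            np.vstack([vB, vB]), np.arange(2) * 10.0, freqs, 10.0,
            subject_id="s0", condition="light",
        )
        dbs = db_deviation_cohort([mixed, pure])
        # the single-state segment deviates from the subject's overall mean,
        # so its 2 Hz elevation is still visible (per-cell normalization
        # would have flattened it to zero)
        assert np.all(dbs[1].db[:, 0] > 0)
        assert np.all(dbs[1].db[:, 1] < 0)
        # within the subject, linear ratios pooled over all windows average to 1
        pooled = np.vstack([10 ** (d.db / 10.0) for d in dbs])
        assert np.allclose(pooled.mean(axis=0), 1.0, atol=1e-12)

    def test_shared_reference_is_subject_mean(self):
        from lfpstates.spectral import db_deviation_cohort

        rng = np.random.default_rng(9)
        freqs = np.arange(1.0, 5.0)
        specs = [
            Spectrogram(rng.exponential(size=(6, 4)) + 0.1, np.arange(6) * 10.0,
                        freqs, 10.0, subject_id=s, condition=c)
            for s in ("s0", "s1") for c in ("a", "b")
        ]
        dbs = db_deviation_cohort(specs)
        for s in ("s0", "s1"):
            group = [S for S in specs if S.subject_id == s]
            expected = np.vstack([g.power for g in group]).mean(axis=0)
            for d in dbs:
                if d.subject_id == s:
                    assert np.allclose(d.reference_spectrum, expected)


def _two_state_spectrogram():
    """Deterministic rows: state A = [4, 1, 1], state B = [1, 1, 4]."""
    vA = np.array([4.0, 1.0, 1.0])
    vB = np.array([1.0, 1.0, 4.0])
    labels = np.array([0, 0, 0, 1, 1, 0, 1, 1, 1, 1])
    power = np.where(labels[:, None] == 0, vA[None, :], vB[None, :])
    S = Spectrogram(power, np.arange(10) * 10.0, np.array([2.0, 4.0, 6.0]), 10.0)
    return S, labels, vA, vB


class TestWelchAverage:
    def test_stationary_input_recovers_mean(self):
        power = np.tile([[1.0, 2.0]], (20, 1))
        S = Spectrogram(power, np.arange(20) * 10.0, np.array([1.0, 2.0]), 10.0)
        avg = welch_average_at_times(S, [50.0, 120.0], 30.0)
        assert np.allclose(avg, [1.0, 2.0])

    def test_mixture_linearity_against_label_oracle(self):
        S, labels, vA, vB = _two_state_spectrogram()
        times = [25.0, 75.0]
        avg = welch_average_at_times(S, times, 25.0)
        # oracle: selected window indices by the midpoint rule, averaged by label
        sel = []
        for t in times:
            mid = S.times_s + 5.0
            sel.extend(np.nonzero((mid >= t - 25.0) & (mid <= t + 25.0))[0])
        q = np.mean(labels[sel] == 0)
        assert np.allclose(avg, q * vA + (1 - q) * vB)

    def test_interval_outside_recording_rejected(self):
        S, *_ = _two_state_spectrogram()
        with pytest.raises(InvalidParameterError):
            welch_average_at_times(S, [5.0], 30.0)

    def test_empty_selection_rejected(self):
        S, *_ = _two_state_spectrogram()
        with pytest.raises(EmptySelectionError):
            welch_average_at_times(S, [], 30.0)


class TestCircularShiftAverage:
    def _db(self):
        rng = np.random.default_rng(8)
        power = rng.exponential(size=(30, 4)) + 0.1
        S = Spectrogram(power, np.arange(30) * 10.0, np.arange(1.0, 5.0), 10.0)
        return db_deviation(S)

    def test_zero_rotation_is_identity(self):
        db = self._db()
        avg = circular_shift_average(db, [0.0])
        assert np.allclose(avg, db.db)

    def test_all_starts_give_constant_rows(self):
        db = self._db()
        starts = np.arange(30) * 10.0
        avg = circular_shift_average(db, starts)
        mean_row = db.db.mean(axis=0)
        assert np.allclose(avg, np.tile(mean_row, (30, 1)))

    def test_commutes_with_bin_selection(self):
        db = self._db()
        starts = [30.0, 110.0, 200.0]
        full = circular_shift_average(db, starts)[:, :2]
        import dataclasses

        sub = dataclasses.replace(
            db, db=db.db[:, :2], reference_spectrum=db.reference_spectrum[:2],
            freqs_hz=db.freqs_hz[:2],
        )
        assert np.allclose(full, circular_shift_average(sub, starts))

    def test_random_starts_shrink_temporal_variance(self):
        # averaging 10 independent phases of the alternation ~ 1/10 variance
        period = np.tile(np.repeat([3.0, -3.0], 3), 10)
        db_arr = np.tile(period[:, None], (1, 4))
        base = self._db()
        import dataclasses

        db = dataclasses.replace(
            base, db=db_arr, times_s=np.arange(60) * 10.0,
            freqs_hz=base.freqs_hz, window_duration_s=10.0,
        )
        rng = np.random.default_rng(5)
        starts = rng.choice(60, size=10, replace=False) * 10.0
        avg = circular_shift_average(db, starts)
        var_in = db.db.var(axis=0).mean()
        var_out = avg.var(axis=0).mean()
        assert var_out < 0.5 * var_in


class TestFindSpectralPeaks:
    def _resonance(self, freqs, f0, width, height):
        return height / (1 + ((freqs - f0) / width) ** 2)

    def test_single_resonance(self):
        freqs = np.arange(0.5, 20.0, 0.1)
        spec = 0.05 / freqs + self._resonance(freqs, 6.0, 0.8, 1.0)
        peaks = find_spectral_peaks(freqs, spec, (0.5, 19.0), 3.0)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 6.0) <= 0.1

    def test_two_well_separated_resonances(self):
        freqs = np.arange(0.5, 20.0, 0.1)
        spec = (
            0.05 / freqs
            + self._resonance(freqs, 2.0, 0.5, 1.0)
            + self._resonance(freqs, 6.0, 0.8, 1.0)
        )
        peaks = find_spectral_peaks(freqs, spec, (0.5, 19.0), 3.0)
        assert [round(f) for f, _ in peaks] == [2, 6]

    def test_monotone_background_has_no_peaks(self):
        freqs = np.arange(0.5, 20.0, 0.1)
        assert find_spectral_peaks(freqs, 1.0 / freqs, (0.5, 19.0), 3.0) == []

    def test_band_outside_support_rejected(self):
        freqs = np.arange(0.5, 20.0, 0.1)
        with pytest.raises(InvalidParameterError):
            find_spectral_peaks(freqs, 1.0 / freqs, (0.5, 50.0), 3.0)


class TestAveragingBlendsStates:
    """Welch averaging at random times across broad-peaked states merges the
    two spectral peaks into one low-frequency elevation."""

    def test_peak_count_drops_after_averaging(self):
        freqs = np.arange(0.5, 20.0, 0.1)

        def resonance(f0, width):
            return 1.0 / (1 + ((freqs - f0) / width) ** 2)

        background = 0.05 / freqs
        vA = background + resonance(6.0, 2.0)
        vB = background + resonance(2.0, 2.0)
        labels = np.tile(np.repeat([0, 1], 6), 5)
        power = np.where(labels[:, None] == 0, vA[None, :], vB[None, :])
        S = Spectrogram(power, np.arange(60) * 10.0, freqs, 10.0)
        n_A = len(find_spectral_peaks(freqs, vA, (0.5, 19.0), 1.0))
        n_B = len(find_spectral_peaks(freqs, vB, (0.5, 19.0), 1.0))
        rng = np.random.default_rng(2)
        times = rng.uniform(30.0, 570.0, size=10)
        blended = welch_average_at_times(S, times, 30.0)
        n_blend = len(find_spectral_peaks(freqs, blended, (0.5, 19.0), 1.0))
        assert n_A == 1 and n_B == 1
        assert n_blend < n_A + n_B
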