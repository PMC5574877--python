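"""Preprocessing, spectrograms, dB-deviation normalization, and the two
averaging-pitfall constructions.

The preprocessing chain mirrors standard LFP extraction: an acausal
(forward-backward) Butterworth low-pass followed by integer-factor
downsampling. Spectrograms use non-overlapping Hann-tapered windows so that
successive windows are independent estimates, and are normalized per
recording as decibel deviations from that recording's own mean power
spectrum — the form in which spectral states are visible across subjects.

Two operations demonstrate how averaging destroys metastable structure:
``welch_average_at_times`` (Welch averaging around randomly chosen times
blends distinct state spectra into one broad peak) and
``circular_shift_average`` (averaging circularly time-shifted surrogates of
the same recording washes out the alternation while preserving the mean
spectrum).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateReferenceError,
    EmptySelectionError,
    InvalidParameterError,
)
from .types import DbDeviationSpectrogram, SignalTrace, Spectrogram

__all__ = [
    "zero_phase_lowpass",
    "decimate_to",
    "compute_spectrogram",
    "db_deviation",
    "db_deviation_cohort",
    "welch_average_at_times",
    "circular_shift_average",
    "find_spectral_peaks",
]

DB_FLOOR_REL = 1e-12  # linear powers clipped at this fraction of the max before log
DEFAULT_BAND_HZ = (0.5, 120.0)


def zero_phase_lowpass(
    x: SignalTrace, cutoff_hz: float = 500.0, order: int = 4
) -> SignalTrace:
    """Forward-backward Butterworth low-pass (zero effective phase)."""
    nyq = x.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    if order < 1:
        raise InvalidParameterError("order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=x.sampling_rate_hz, output="sos")
    y = sps.sosfiltfilt(sos, x.samples)
    return SignalTrace(y, x.sampling_rate_hz, x.subject_id, x.condition)


def decimate_to(x: SignalTrace, target_rate_hz: float) -> SignalTrace:
    """Downsample to ``target_rate_hz`` (integer factor, with anti-aliasing)."""
    ratio = x.sampling_rate_hz / target_rate_hz
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise InvalidParameterError(
            f"rate {x.sampling_rate_hz} Hz is not an integer multiple of "
            f"{target_rate_hz} Hz"
        )
    if factor == 1:
        return SignalTrace(x.samples.copy(), x.sampling_rate_hz, x.subject_id, x.condition)
    # FIR anti-alias filter: flat passband, so tone amplitudes below the new
    # Nyquist are preserved to well under 1%
    y = sps.decimate(x.samples, factor, ftype="fir", zero_phase=True)
    return SignalTrace(y, target_rate_hz, x.subject_id, x.condition)


def compute_spectrogram(
    x: SignalTrace,
    window_duration_s: float = 10.0,
    freq_range_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> Spectrogram:
    """Non-overlapping Hann-tapered periodograms, restricted to a band.

    One power spectral density estimate (one-sided, density scaling) per
    window; the number of windows is floor(duration / window_duration) and
    any trailing partial window is dropped.
    """
    lo, hi = freq_range_hz
    if lo >= hi:
        raise InvalidParameterError("freq_range_hz must be (low, high) with low < high")
    if hi > x.sampling_rate_hz / 2.0 + 1e-9:
        raise InvalidParameterError("freq range exceeds Nyquist")
    win = int(round(window_duration_s * x.sampling_rate_hz))
    if win < 16:
        raise InvalidParameterError("window must cover >= 16 samples")
    n_win = x.n_samples // win
    if n_win < 1:
        raise InvalidParameterError("trace shorter than one window")
    segs = x.samples[: n_win * win].reshape(n_win, win)
    taper = sps.get_window("hann", win)
    spec = np.fft.rfft(segs * taper, axis=1)
    # one-sided PSD with density scaling
    scale = 1.0 / (x.sampling_rate_hz * np.sum(taper**2))
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(win, d=1.0 / x.sampling_rate_hz)
    keep = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    times = np.arange(n_win) * window_duration_s
    return Spectrogram(
        psd[:, keep], times, freqs[keep], window_duration_s, x.subject_id, x.condition
    )


def db_deviation(S: Spectrogram) -> DbDeviationSpectrogram:
    """Express each window in dB relative to the recording's mean spectrum.

    db[w, f] = 10 log10(power[w, f] / mean_w power[w, f]); by construction
    the linear ratios average to 1 in every frequency bin.
    """
    if S.n_windows < 2:
        raise InvalidParameterError("need >= 2 windows for a meaningful reference")
    reference = S.power.mean(axis=0)
    if np.any(reference <= 0):
        raise DegenerateReferenceError("reference spectrum has an all-zero bin")
    ratio = S.power / reference[None, :]
    floor = DB_FLOOR_REL * ratio.max()
    db = 10.0 * np.log10(np.maximum(ratio, floor))
    return DbDeviationSpectrogram(
        db=db,
        reference_spectrum=reference,
        times_s=S.times_s.copy(),
        freqs_hz=S.freqs_hz.copy(),
        window_duration_s=S.window_duration_s,
        subject_id=S.subject_id,
        condition=S.condition,
    )


def db_deviation_cohort(spectrograms: list[Spectrogram]) -> list[DbDeviationSpectrogram]:
    """Per-subject dB-deviation across a cohort.

    Each subject's reference is the mean power spectrum over *all* of that
    subject's windows (pooled across conditions), so a recording segment that
    stays in one state still shows that state's signature as a deviation
    from the subject's overall mean. Within one subject the linear ratios
    average to 1 over the pooled windows.
    """
    if not spectrograms:
        raise InvalidParameterError("empty cohort")
    ref_grid = spectrograms[0].freqs_hz
    by_subject: dict[str, list[Spectrogram]] = {}
    for S in spectrograms:
        if S.freqs_hz.shape != ref_grid.shape or not np.allclose(S.freqs_hz, ref_grid):
            raise InvalidParameterError("spectrograms have mismatched frequency grids")
        by_subject.setdefault(S.subject_id, []).append(S)
    out: list[DbDeviationSpectrogram] = []
    for S in spectrograms:
        group = by_subject[S.subject_id]
        pooled = np.vstack([g.power for g in group])
        reference = pooled.mean(axis=0)
        if np.any(reference <= 0):
            raise DegenerateReferenceError("subject reference has an all-zero bin")
        ratio = S.power / reference[None, :]
        floor = DB_FLOOR_REL * max(ratio.max(), 1e-300)
        db = 10.0 * np.log10(np.maximum(ratio, floor))
        out.append(
            DbDeviationSpectrogram(
                db=db,
                reference_spectrum=reference,
                times_s=S.times_s.copy(),
                freqs_hz=S.freqs_hz.copy(),
                window_duration_s=S.window_duration_s,
                subject_id=S.subject_id,
                condition=S.condition,
            )
        )
    return out


def _windows_in_interval(S: Spectrogram | DbDeviationSpectrogram, t0: float, t1: float):
    mid = S.times_s + S.window_duration_s / 2.0
    return np.nonzero((mid >= t0) & (mid <= t1))[0]


def welch_average_at_times(
    S: Spectrogram,
    times_s: list[float] | np.ndarray,
    half_width_s: float = 30.0,
) -> np.ndarray:
    """Welch-style mean spectrum over +/- ``half_width_s`` around given times.

    A window belongs to an interval if its midpoint lies inside; a window is
    counted once per interval containing it. Averaging across intervals that
    straddle different spectral states blends their peaks — the classic
    nonstationarity pitfall.
    """
    times_s = np.atleast_1d(np.asarray(times_s, dtype=float))
    if times_s.size == 0:
        raise EmptySelectionError("no analysis times given")
    total = S.duration_s
    rows = []
    for t in times_s:
        if t - half_width_s < -1e-9 or t + half_width_s > total + 1e-9:
            raise InvalidParameterError(
                f"interval around t={t}s extends outside the recording"
            )
        idx = _windows_in_interval(S, t - half_width_s, t + half_width_s)
        rows.append(idx)
    sel = np.concatenate(rows)
    if sel.size == 0:
        raise EmptySelectionError("no window midpoints fall inside the intervals")
    return S.power[sel].mean(axis=0)


def circular_shift_average(
    S: DbDeviationSpectrogram, start_times_s: list[float] | np.ndarray
) -> np.ndarray:
    """Average of circularly time-shifted copies of a dB-deviation spectrogram.

    For each start time the rows are rotated so the recording begins there
    (wrapping past the end back to the start); the rotated arrays are then
    averaged element-wise. This builds surrogate "subjects" sharing the mean
    spectrogram and transition structure but with independent phases of the
    state alternation; their average suppresses the alternation.
    """
    start_times_s = np.atleast_1d(np.asarray(start_times_s, dtype=float))
    if start_times_s.size == 0:
        raise EmptySelectionError("no start times given")
    n = S.n_windows
    acc = np.zeros_like(S.db)
    for t in start_times_s:
        if t < -1e-9 or t > S.duration_s + 1e-9:
            raise InvalidParameterError(f"start time {t}s outside the recording")
        shift = int(round(t / S.window_duration_s)) % n
        acc += np.roll(S.db, -shift, axis=0)
    return acc / start_times_s.size


def find_spectral_peaks(
    freqs_hz: np.ndarray,
    spectrum: np.ndarray,
    band_hz: tuple[float, float] = (0.5, 20.0),
    min_prominence_db: float = 3.0,
) -> list[tuple[float, float]]:
    """Local maxima of a spectrum (in dB) within a band, by prominence.

    Returns (frequency, height in dB) pairs sorted by frequency. ``spectrum``
    is in linear power units.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = band_hz
    if lo < freqs_hz[0] - 1e-9 or hi > freqs_hz[-1] + 1e-9:
        raise InvalidParameterError("band outside spectrum support")
    mask = (freqs_hz >= lo) & (freqs_hz <= hi)
    f = freqs_hz[mask]
    p = spectrum[mask]
    db = 10.0 * np.log10(np.maximum(p, DB_FLOOR_REL * max(p.max(), 1e-300)))
    idx, _props = sps.find_peaks(db, prominence=min_prominence_db)
    return [(float(f[i]), float(db[i])) for i in idx]
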