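"""Core domain containers shared across modules.

The analysis abstracts a long electrophysiological recording into a sequence
of discrete spectral states: each state is described by a small set of
narrow-band peaks over a 1/f background (:class:`SpectralStateModel`), the
switching between states by a row-stochastic :class:`TransitionMatrix`, and a
realization of the switching by a :class:`StateSequence` of one label per
non-overlapping analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, UnknownStateError

__all__ = [
    "SpectralPeak",
    "SpectralStateModel",
    "TransitionMatrix",
    "StateSequence",
    "SignalTrace",
    "Spectrogram",
    "DbDeviationSpectrogram",
    "CountMatrix",
    "ReportMatrix",
    "DwellRecord",
]


@dataclass(frozen=True)
class SpectralPeak:
    """One narrow-band spectral component of a state.

    Parameters
    ----------
    center_hz
        Peak center frequency (must lie below the Nyquist frequency of the
        signal it will be rendered into).
    bandwidth_hz
        Full width of the resonance; maps to the pole radius of the
        generating resonator.
    relative_power
        Variance contributed by this component, relative to the other
        components of the same state.
    """

    center_hz: float
    bandwidth_hz: float
    relative_power: float

    def __post_init__(self):
        if self.center_hz <= 0:
            raise InvalidParameterError("peak center_hz must be > 0")
        if self.bandwidth_hz <= 0:
            raise InvalidParameterError("peak bandwidth_hz must be > 0")
        if self.relative_power < 0:
            raise InvalidParameterError("peak relative_power must be >= 0")


@dataclass(frozen=True)
class SpectralStateModel:
    """Generative description of one spectral state (one attractor).

    A state renders as a sum of stochastically driven resonators (one per
    peak) on top of 1/f**background_exponent noise.
    """

    state_id: int
    peaks: tuple[SpectralPeak, ...]
    background_exponent: float = 1.0
    background_power: float = 1.0

    def __post_init__(self):
        peaks = tuple(
            p if isinstance(p, SpectralPeak) else SpectralPeak(*p) for p in self.peaks
        )
        object.__setattr__(self, "peaks", peaks)
        if len(self.peaks) < 1:
            raise InvalidParameterError("a spectral state needs at least one peak")
        if self.background_power < 0:
            raise InvalidParameterError("background_power must be >= 0")

    def validate_for_rate(self, sampling_rate_hz: float) -> None:
        nyquist = sampling_rate_hz / 2.0
        for p in self.peaks:
            if p.center_hz >= nyquist:
                raise InvalidParameterError(
                    f"peak at {p.center_hz} Hz is at/above Nyquist ({nyquist} Hz)"
                )


@dataclass
class TransitionMatrix:
    """Row-stochastic k x k matrix of per-window transition probabilities.

    ``unobserved_rows`` marks states with no outgoing observations when the
    matrix was estimated from data; such rows are stored as self-transitions
    so the row-stochastic invariant still holds, and downstream reporting
    floors them.
    """

    states: tuple[int, ...]
    P: np.ndarray
    window_duration_s: float
    unobserved_rows: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.states = tuple(int(s) for s in self.states)
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.states)
        if k < 1:
            raise InvalidParameterError("transition matrix needs k >= 1 states")
        if self.P.shape != (k, k):
            raise InvalidParameterError(f"P must be {k}x{k}, got {self.P.shape}")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise InvalidParameterError("transition probabilities must lie in [0, 1]")
        rowsums = self.P.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise InvalidParameterError(
                f"rows must sum to 1 within 1e-9 (got {rowsums})"
            )

    @property
    def k(self) -> int:
        return len(self.states)

    def index_of(self, state_id: int) -> int:
        try:
            return self.states.index(state_id)
        except ValueError:
            raise UnknownStateError(state_id) from None

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of P for eigenvalue 1, normalized to sum 1."""
        vals, vecs = np.linalg.eig(self.P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def mean_dwell_windows(self) -> np.ndarray:
        """Expected dwell length per state, 1/(1 - p_ii), in windows."""
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 - np.diag(self.P))


@dataclass
class StateSequence:
    """Discrete state label per analysis window for one recording segment."""

    labels: np.ndarray
    window_duration_s: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise InvalidParameterError("labels must be a non-empty 1-D array")

    @property
    def n_windows(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_windows * self.window_duration_s

    def n_transitions(self) -> int:
        """Number of between-state changes along the sequence."""
        return int(np.sum(self.labels[1:] != self.labels[:-1]))


@dataclass
class SignalTrace:
    """A single-channel time series with its sampling rate and provenance."""

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Spectrogram:
    """Windows x frequency-bins power array (linear units), non-overlapping windows."""

    power: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    window_duration_s: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.power.ndim != 2:
            raise InvalidParameterError("power must be 2-D (windows x bins)")
        if self.power.shape != (self.times_s.size, self.freqs_hz.size):
            raise InvalidParameterError("power shape must match times x freqs")
        if np.any(self.power < 0):
            raise InvalidParameterError("power must be non-negative")
        if self.freqs_hz.size > 1 and np.any(np.diff(self.freqs_hz) <= 0):
            raise InvalidParameterError("freqs_hz must be strictly increasing")
        if self.times_s.size > 1:
            steps = np.diff(self.times_s)
            if np.any(np.abs(steps - self.window_duration_s) > 1e-9):
                raise InvalidParameterError(
                    "times_s must advance uniformly by window_duration_s"
                )

    @property
    def n_windows(self) -> int:
        return int(self.times_s.size)

    @property
    def duration_s(self) -> float:
        return self.n_windows * self.window_duration_s


@dataclass
class DbDeviationSpectrogram:
    """Spectrogram re-expressed in dB relative to its own mean power spectrum.

    By construction, for each frequency bin the mean over windows of
    ``10**(db/10)`` equals 1 (before any clipping of silent bins).
    """

    db: np.ndarray
    reference_spectrum: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    window_duration_s: float
    subject_id: str = ""
    condition: str = ""

    @property
    def n_windows(self) -> int:
        return int(self.times_s.size)

    @property
    def duration_s(self) -> float:
        return self.n_windows * self.window_duration_s

    def to_linear(self) -> np.ndarray:
        """Reconstruct linear power: reference * 10**(db/10)."""
        return self.reference_spectrum[None, :] * 10.0 ** (self.db / 10.0)


@dataclass
class CountMatrix:
    """Raw transition counts; sum equals total adjacent pairs across sequences."""

    C: np.ndarray
    total_transitions: int

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.int64)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise InvalidParameterError("C must be square")
        if np.any(self.C < 0):
            raise InvalidParameterError("counts must be non-negative")
        if int(self.C.sum()) != int(self.total_transitions):
            raise InvalidParameterError("total_transitions must equal sum(C)")


@dataclass
class ReportMatrix:
    """Display form of a transition matrix with the reporting floor applied.

    All entries are at least ``floor``; for every state in
    ``unobserved_states`` the entire row and column are set to ``floor``.
    The underlying (pre-floor) estimate is retained for computation.
    """

    P_report: np.ndarray
    floor: float
    unobserved_states: frozenset[int]
    P_underlying: np.ndarray

    def __post_init__(self):
        self.P_report = np.asarray(self.P_report, dtype=float)
        if np.any(self.P_report < self.floor - 1e-15):
            raise InvalidParameterError("report entries must be >= floor")


@dataclass(frozen=True)
class DwellRecord:
    """One maximal constant run of a state sequence.

    ``censored`` marks runs truncated by the start or end of the recording;
    censored runs are excluded from dwell-distribution fits.
    """

    state: int
    duration_s: float
    subject_id: str = ""
    condition: str = ""
    censored: bool = False

    def n_windows(self, window_duration_s: float) -> int:
        return int(round(self.duration_s / window_duration_s))
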