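"""Synthetic cohorts of metastable LFP-like signals with known ground truth.

The generator emulates the statistical structure of multi-subject anesthesia
recordings: each subject's trace alternates between a small set of spectral
states (e.g., a ~6 Hz and a ~2 Hz narrow-band peak over a 1/f background),
with switching governed by a finite-state Markov chain whose mean dwell times
are on the order of minutes. A scalar "concentration" covariate modulates
dwell times (``dwell_multiplier``) and which states are available
(``available_states``), mirroring an anesthetic ladder where not all states
occur at every level.

Because the ground-truth state sequence is returned alongside every trace,
every downstream stage (spectrogram, clustering, transition-matrix
estimation, dwell statistics) can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, InvalidParameterError, UnknownStateError
from .types import (
    SignalTrace,
    SpectralPeak,
    SpectralStateModel,
    StateSequence,
    TransitionMatrix,
)

__all__ = [
    "CohortConfig",
    "ConditionSpec",
    "CohortMember",
    "subject_condition_seed",
    "build_transition_matrix",
    "sample_state_sequence",
    "synthesize_signal",
    "restrict_transition_matrix",
    "simulate_cohort",
    "default_state_models",
    "default_cohort_config",
]

DEFAULT_WINDOW_S = 10.0
CROSSFADE_S = 0.5


@dataclass(frozen=True)
class ConditionSpec:
    """One level of the covariate ladder (one anesthetic concentration)."""

    label: str
    dwell_multiplier: float = 1.0
    available_states: tuple[int, ...] = ()
    duration_s: float = 3600.0

    def __post_init__(self):
        if self.dwell_multiplier <= 0:
            raise InvalidConfigError(
                "dwell_multiplier must be > 0", key=f"{self.label}.dwell_multiplier"
            )


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    ``base_transition`` is the chain at the reference condition; each
    condition restricts it to ``available_states`` (empty tuple = all) and
    rescales the mean dwell by ``dwell_multiplier``.
    """

    n_subjects: int
    conditions: tuple[ConditionSpec, ...]
    base_transition: TransitionMatrix
    state_models: tuple[SpectralStateModel, ...]
    sampling_rate_hz: float = 1000.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1", key="n_subjects")
        if not self.conditions:
            raise InvalidConfigError("need at least one condition", key="conditions")
        wd = self.base_transition.window_duration_s
        for c in self.conditions:
            if c.duration_s < 2 * wd:
                raise InvalidConfigError(
                    "condition duration must cover >= 2 windows",
                    key=f"{c.label}.duration_s",
                )
            avail = c.available_states or self.base_transition.states
            if not set(avail) <= set(self.base_transition.states):
                raise InvalidConfigError(
                    "available_states must be a subset of the base states",
                    key=f"{c.label}.available_states",
                )
            if len(avail) == 0:
                raise InvalidConfigError(
                    "available_states must be non-empty",
                    key=f"{c.label}.available_states",
                )
        for m in self.state_models:
            m.validate_for_rate(self.sampling_rate_hz)
        model_ids = {m.state_id for m in self.state_models}
        if not set(self.base_transition.states) <= model_ids:
            missing = set(self.base_transition.states) - model_ids
            raise InvalidConfigError(
                f"missing spectral models for states {sorted(missing)}",
                key="state_models",
            )


@dataclass
class CohortMember:
    """One subject x condition cell: the rendered trace and its ground truth."""

    trace: SignalTrace
    truth: StateSequence
    effective_transition: TransitionMatrix


def build_transition_matrix(
    k: int,
    mean_dwell_windows: float,
    window_duration_s: float = DEFAULT_WINDOW_S,
    states: tuple[int, ...] | None = None,
) -> TransitionMatrix:
    """Symmetric metastable chain: stay with probability 1 - 1/mean_dwell.

    The off-diagonal mass 1/mean_dwell_windows is split equally among the
    other k-1 states, so every state has geometric dwell lengths with the
    given mean (in windows).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if states is None:
        states = tuple(range(k))
    if k == 1:
        return TransitionMatrix(states, np.ones((1, 1)), window_duration_s)
    if mean_dwell_windows <= 1:
        raise InvalidParameterError("mean_dwell_windows must be > 1 for k > 1")
    p_switch = 1.0 / mean_dwell_windows
    P = np.full((k, k), p_switch / (k - 1))
    np.fill_diagonal(P, 1.0 - p_switch)
    return TransitionMatrix(states, P, window_duration_s)


def sample_state_sequence(
    T: TransitionMatrix,
    n_windows: int,
    initial_state: int | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    subject_id: str = "",
    condition: str = "",
) -> StateSequence:
    """Draw one Markov realization of ``n_windows`` labels.

    ``initial_state=None`` draws the first label from the stationary
    distribution of ``T``; otherwise it must be a member of ``T.states``.
    """
    if n_windows < 1:
        raise InvalidParameterError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    k = T.k
    if initial_state is None:
        current = int(rng.choice(k, p=T.stationary_distribution()))
    else:
        current = T.index_of(initial_state)
    # inverse-CDF sampling from precomputed row CDFs
    cdf = np.cumsum(T.P, axis=1)
    u = rng.random(n_windows - 1)
    idx = np.empty(n_windows, dtype=np.int64)
    idx[0] = current
    for w in range(1, n_windows):
        current = int(np.searchsorted(cdf[current], u[w - 1], side="right"))
        current = min(current, k - 1)  # guard against u == 1.0 edge
        idx[w] = current
    labels = np.asarray(T.states, dtype=np.int64)[idx]
    return StateSequence(labels, T.window_duration_s, subject_id, condition)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _resonator_output(
    n: int, center_hz: float, bandwidth_hz: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """White-noise-driven second-order resonator, normalized to unit variance.

    Pole radius r = exp(-pi * bw / fs) sets the -3 dB width; pole angle sets
    the center frequency.
    """
    r = np.exp(-np.pi * bandwidth_hz / fs)
    theta = 2.0 * np.pi * center_hz / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    drive = rng.standard_normal(n)
    y = sps.lfilter([1.0], a, drive)
    sd = y.std()
    return y / sd if sd > 0 else y


def _render_state_component(
    model: SpectralStateModel, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    x = np.zeros(n)
    for p in model.peaks:
        if p.relative_power > 0:
            x += np.sqrt(p.relative_power) * _resonator_output(
                n, p.center_hz, p.bandwidth_hz, fs, rng
            )
    if model.background_power > 0:
        x += np.sqrt(model.background_power) * _pink_noise(
            n, model.background_exponent, rng
        )
    return x


def synthesize_signal(
    states: StateSequence,
    models: list[SpectralStateModel] | tuple[SpectralStateModel, ...],
    sampling_rate_hz: float,
    seed: int | np.random.SeedSequence | None = 0,
    crossfade_s: float = CROSSFADE_S,
    noise_sd: float = 0.0,
) -> SignalTrace:
    """Render a label sequence into a continuous LFP-like trace.

    A full-length component trace is generated per state (so spectra are
    stationary within a state, with no window-edge transients), then mixed
    with per-window indicator weights whose boundaries between different
    states are joined by a short linear crossfade.
    """
    model_map = {m.state_id: m for m in models}
    present = set(int(s) for s in np.unique(states.labels))
    missing = present - set(model_map)
    if missing:
        raise UnknownStateError(f"no spectral model for states {sorted(missing)}")
    for sid in present:
        model_map[sid].validate_for_rate(sampling_rate_hz)

    fs = sampling_rate_hz
    win = int(round(states.window_duration_s * fs))
    n = win * states.n_windows
    rng = np.random.default_rng(seed)

    # one component per state present, in sorted order for determinism
    components = {
        sid: _render_state_component(model_map[sid], n, fs, rng)
        for sid in sorted(present)
    }

    x = np.zeros(n)
    if len(present) == 1:
        x = components[next(iter(present))].copy()
    else:
        fade = max(2, int(round(crossfade_s * fs)))
        weights = {sid: np.zeros(n) for sid in present}
        for w, sid in enumerate(states.labels):
            weights[int(sid)][w * win : (w + 1) * win] = 1.0
        # linear crossfades centered on each between-state boundary
        ramp = np.linspace(0.0, 1.0, fade)
        for w in range(1, states.n_windows):
            prev, cur = int(states.labels[w - 1]), int(states.labels[w])
            if prev == cur:
                continue
            b = w * win
            lo, hi = b - fade // 2, b - fade // 2 + fade
            lo, hi = max(lo, 0), min(hi, n)
            seg = ramp[: hi - lo]
            weights[prev][lo:hi] = 1.0 - seg
            weights[cur][lo:hi] = seg
        for sid in sorted(present):
            x += weights[sid] * components[sid]

    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return SignalTrace(x, fs, states.subject_id, states.condition)


def restrict_transition_matrix(
    T: TransitionMatrix,
    available_states: tuple[int, ...],
    dwell_multiplier: float = 1.0,
) -> TransitionMatrix:
    """Restrict a chain to a subset of states and rescale its dwell times.

    Rows/columns outside ``available_states`` are dropped; remaining
    off-diagonal entries are renormalized to preserve their relative
    proportions; the diagonal is then adjusted so each state's mean dwell is
    scaled by ``dwell_multiplier``.
    """
    avail = tuple(available_states) or T.states
    if len(avail) == 0:
        raise InvalidConfigError("restriction leaves an empty state set")
    idx = [T.index_of(s) for s in avail]
    sub = T.P[np.ix_(idx, idx)].copy()
    k = len(idx)
    if k == 1:
        return TransitionMatrix(avail, np.ones((1, 1)), T.window_duration_s)
    P = np.empty_like(sub)
    for i in range(k):
        off = sub[i].copy()
        off[i] = 0.0
        off_sum = off.sum()
        p_switch_base = 1.0 - sub[i, i]
        if off_sum <= 0:
            # absorbing row in the base chain stays absorbing
            P[i] = 0.0
            P[i, i] = 1.0
            continue
        # keep the restricted off-diagonal proportions; total switch
        # probability comes from the base diagonal scaled by the multiplier
        p_switch = min(1.0, p_switch_base / dwell_multiplier)
        P[i] = off / off_sum * p_switch
        P[i, i] = 1.0 - p_switch
    return TransitionMatrix(avail, P, T.window_duration_s)


def subject_condition_seed(
    master_seed: int, subject_index: int, condition_index: int
) -> np.random.SeedSequence:
    """Deterministic per-cell stream: SeedSequence(master, spawn_key=(s, c)).

    Documented splitting rule so cohorts are reproducible piecewise: any
    (subject, condition) cell can be regenerated without the others.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(subject_index, condition_index))


def simulate_cohort(config: CohortConfig) -> list[CohortMember]:
    """Generate the full cohort: one (trace, ground truth) per subject x condition."""
    members: list[CohortMember] = []
    wd = config.base_transition.window_duration_s
    for ci, cond in enumerate(config.conditions):
        avail = cond.available_states or config.base_transition.states
        T_eff = restrict_transition_matrix(
            config.base_transition, tuple(avail), cond.dwell_multiplier
        )
        n_windows = int(cond.duration_s // wd)
        for si in range(config.n_subjects):
            ss = subject_condition_seed(config.seed, si, ci)
            seq_seed, sig_seed = ss.spawn(2)
            subject = f"s{si:02d}"
            seq = sample_state_sequence(
                T_eff, n_windows, seed=seq_seed, subject_id=subject,
                condition=cond.label,
            )
            trace = synthesize_signal(
                seq,
                config.state_models,
                config.sampling_rate_hz,
                seed=sig_seed,
                noise_sd=config.noise_sd,
            )
            members.append(CohortMember(trace, seq, T_eff))
    return members


def default_state_models() -> tuple[SpectralStateModel, ...]:
    """The two canonical spectral states: ~6 Hz and ~2 Hz peaks over 1/f.

    Peak powers and bandwidths are chosen so each peak stands roughly 15 dB
    above the background at its center — prominent, as in anesthetized-rat
    LFP, but far from noise-free.
    """
    return (
        SpectralStateModel(
            state_id=0,
            peaks=(SpectralPeak(center_hz=6.0, bandwidth_hz=1.0, relative_power=1.0),),
            background_exponent=1.0,
            background_power=1.0,
        ),
        SpectralStateModel(
            state_id=1,
            peaks=(SpectralPeak(center_hz=2.0, bandwidth_hz=0.6, relative_power=1.0),),
            background_exponent=1.0,
            background_power=1.0,
        ),
    )


def default_cohort_config(
    n_subjects: int = 5,
    n_conditions: int = 5,
    duration_s: float = 3600.0,
    mean_dwell_windows: float = 60.0,
    window_duration_s: float = DEFAULT_WINDOW_S,
    sampling_rate_hz: float = 1000.0,
    seed: int = 0,
) -> CohortConfig:
    """Cohort emulating the study design: 5 subjects, a 5-step concentration
    ladder (1.75% down to 0.75% in 0.25% steps) with >= 60 min per step, two
    spectral states at ~6/~2 Hz, and 10-minute mean dwells at the reference
    level.

    Dwell times shorten as the ladder descends (lighter levels switch
    faster), and the lightest level drops state 0, exercising the
    absent-cluster reporting rule downstream.
    """
    ladder = [1.75, 1.50, 1.25, 1.00, 0.75][:n_conditions]
    conditions = []
    for j, conc in enumerate(ladder):
        mult = 1.0 / (1.0 + 0.25 * j)  # dwells shorten at lighter levels
        avail: tuple[int, ...] = ()
        if j == len(ladder) - 1 and len(ladder) >= 3:
            avail = (1,)
        conditions.append(
            ConditionSpec(
                label=f"iso_{conc:.2f}",
                dwell_multiplier=mult,
                available_states=avail,
                duration_s=duration_s,
            )
        )
    base = build_transition_matrix(2, mean_dwell_windows, window_duration_s)
    return CohortConfig(
        n_subjects=n_subjects,
        conditions=tuple(conditions),
        base_transition=base,
        state_models=default_state_models(),
        sampling_rate_hz=sampling_rate_hz,
        noise_sd=0.1,
        seed=seed,
    )
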