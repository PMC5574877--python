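# Methods

## The model

Brain electrical activity under steady anesthetic administration is treated
as a metastable dynamical system: on short timescales the power spectrum of
the local field potential (LFP) is stationary near one of a small number of
spectral "attractors" (e.g., a ~6 Hz-dominated and a ~2 Hz-dominated
signature), while on timescales of minutes the system jumps spontaneously
between them. The analysis abstracts this into a finite-state Markov chain:
one discrete state per analysis window, a row-stochastic transition matrix
`P` whose diagonal entries are close to 1 (mean dwell in windows is
`1/(1 - p_ii)` under the geometric dwell law the chain implies), and
dwell-time records from run lengths of the label sequence. Metastability is
summarized by the stickiness ratio, `min_i p_ii / max_{i≠j} p_ij`, which is
much greater than 1 when remaining anywhere is far more likely than any
single transition.

## Analysis chain

1. **Preprocessing** — acausal (forward–backward) Butterworth low-pass
   (default 4th order, 500 Hz) followed by integer-factor FIR decimation to
   the working rate (default 1 kHz). The FIR polyphase decimator is used
   because its flat passband preserves tone amplitudes below the new
   Nyquist to well under 1%; a Chebyshev IIR would introduce ~1% droop.
2. **Spectrogram** — non-overlapping Hann-tapered periodograms (default
   10 s windows), one-sided PSD, restricted to 0.5–120 Hz (clamped to
   Nyquist when the working rate is lower). Windows are non-overlapping so
   consecutive windows are independent spectral estimates and "one window"
   is a meaningful Markov time step.
3. **dB-deviation normalization** — each window is expressed in decibels
   relative to a mean reference spectrum, `db = 10·log10(power/ref)`. Two
   scopes exist: the per-recording operation (`db_deviation`, reference =
   that spectrogram's own mean, mean linear ratio exactly 1 per bin) and
   the per-subject cohort operation (`db_deviation_cohort`, reference =
   the subject's mean over all conditions). The pipeline uses the
   per-subject scope: a segment that dwells in a single state throughout
   would otherwise be normalized flat, erasing exactly the signature the
   clustering needs. Linear powers are clipped at 1e-12 of the maximum
   ratio before the log to avoid −∞ in silent bins.
4. **State abstraction** — dB-deviation rows from all subjects and
   conditions are pooled (the normalization removes per-subject offsets, so
   pooling needs no further standardization), reduced by PCA to 3
   components (signs fixed so each component's largest-magnitude loading is
   positive), and clustered by Euclidean k-means (default k = 8 for
   ladder-style cohorts, 20 k-means++ restarts, fixed seed). Windows are
   clustered jointly across all concentrations; per-concentration analyses
   reuse the global labels.
5. **Markov statistics** — transitions are counted within subject ×
   condition sequences only, never across boundaries. The display form
   floors every entry at 10⁻³ (so log-scale displays are defined) and, for
   states absent from a condition, sets that state's whole row and column
   to 10⁻³; the pre-floor estimate is kept for computation. Uncertainty
   uses a leave-one-subject-out jackknife: SE per entry from the standard
   `(n−1)/n` jackknife formula and limits `pooled ± q·SE` clipped into
   [10⁻³, 1]. With five subjects the Student-t quantile (df = n−1) is the
   default: the Gaussian quantile realizes ≈88% coverage at nominal 95%
   (the t₄ tail), while the t quantile is close to nominal; `"normal"` is
   available as an option.
6. **Dwell statistics** — maximal constant runs; the first and last run of
   every sequence are censored (their true durations are only bounded
   below) and excluded from fits. The exponential (memoryless) model is
   fitted as rate = 1/mean; for the model comparison a truncated geometric
   and a discrete power law (Hurwitz-zeta normalization) are both fitted by
   maximum likelihood on dwells of ≥ 2 windows — at 1 window the two
   families are indistinguishable — and the higher log-likelihood is
   preferred (equal parameter counts; no significance claim).

## Synthetic cohorts

The generator emulates the statistical structure of a multi-subject
anesthesia experiment, not its biophysics. Defaults mirror the reference
design: 5 subjects, a 5-step concentration ladder with ≥ 60 min per step,
two spectral states — a 6 Hz peak (1 Hz bandwidth) and a 2 Hz peak (0.6 Hz
bandwidth), each over a 1/f background of equal total variance, putting the
peaks ≈15 dB above background — and 10-minute mean dwells (60 windows of
10 s) at the deepest level. Concentration acts only through a dwell-time
multiplier and the set of available states (the lightest level drops the
6 Hz state, exercising the absent-cluster reporting rule); continuous drift
of peak frequencies with concentration is deliberately out of scope.

Each state is rendered as white-noise-driven second-order resonators (pole
radius `exp(-π·bw/fs)` maps bandwidth, pole angle maps center frequency)
plus FFT-shaped 1/f^β noise; a full-length component is generated per state
and mixed with per-window indicator weights whose between-state boundaries
are joined by a 0.5 s linear crossfade, so transitions appear as spectral
shifts rather than broadband clicks. Seeding: one master seed; the stream
for subject *s* at condition *c* is `SeedSequence(master, spawn_key=(s, c))`,
so any cell is reproducible in isolation and cohorts are byte-identical
under a fixed seed.

What the generator does **not** emulate: attractor drift or new spectral
shapes appearing mid-session, burst-suppression waveforms, multi-channel
volume conduction, artifacts, non-Markov (history-dependent) switching.
Passing parameter-recovery tests therefore shows the analysis chain is
correct and unbiased under its own model class; it does not show the model
class captures every feature of real recordings.

## Dynamical models

The double-well model is the overdamped Langevin equation
`dx = −ψ′(x)dt + sqrt(2D dt)·ξ` with the symmetric quartic
`ψ(x) = b·x⁴ − a·x²` (the functional form is this package's choice; minima
at ±sqrt(a/2b), barrier Δψ = a²/(4b)), integrated by Euler–Maruyama with a
stability guard `dt·ψ″(x_min) = 4a·dt < 0.1`. Committed well membership
uses a hysteresis band (|x| < 0.5·x_min is uncommitted) so barrier-top
re-crossings do not inflate switch counts. The empirical escape rate is
compared with the Kramers asymptotic
`(1/2π)·sqrt(ψ″(x_min)·|ψ″(0)|)·exp(−Δψ/D)`, which is treated as valid only
for Δψ/D ≥ 3; waiting-time CV near 1 confirms the memoryless, two-state
Markov picture of the continuous system.

Recovery of consciousness is modeled as an isotropic Gaussian random walk
that must enter a small target ball in d dimensions. Hitting times are
reported as medians with censoring at a fixed horizon (censored walks count
as the horizon, making the medians lower bounds); the median grows and the
censoring fraction approaches 1 as d increases, the argument that recovery
through an unstructured high-dimensional space would exceed realistic
timescales.

## Numerical and design choices

- Analysis window 10 s, non-overlapping: unstated in the source design;
  chosen to give independent spectral estimates, 360 windows/hour, and a
  natural Markov step. Configurable everywhere.
- Single Hann taper per window; multitaper was considered and omitted as
  the default since per-window variance is immaterial after pooling
  thousands of windows.
- Window selection for interval averaging: a window belongs to an interval
  iff its midpoint lies inside — unambiguous and exactly testable.
- k-means ties are broken toward the lowest cluster index; PCA component
  signs are canonicalized; all stochastic stages take explicit seeds, so
  reruns are byte-identical.
- Peak-location checks in tests read the argmax of a 0.5 Hz boxcar-smoothed
  spectrum and require agreement within the peak's half-bandwidth: a
  stochastically driven resonance of finite bandwidth has per-bin argmax
  jitter of roughly ±0.3 Hz even after averaging tens of windows, so a
  one-bin criterion on the raw periodogram would test the noise, not the
  generator.
- Problem sizes in the test-suite and acceptance computations (e.g., three
  3-hour sessions at 1 kHz for the full-chain dwell recovery, 200 sessions
  for the transitions-per-hour rate, 100 replicate cohorts for jackknife
  coverage) were chosen so each quantity's Monte-Carlo error is small
  relative to the band being checked.

## Known limitations

- The jackknife treats subjects as exchangeable units and entries as
  approximately normal; with 5 subjects the intervals are approximate and
  entries near 0 or 1 are clipped rather than transformed.
- The power-law dwell fit is a likelihood comparison at equal parameter
  count, not a goodness-of-fit test; with few dwells (< 20 uncensored) no
  fit is attempted.
- Uncensored-dwell means from finite sessions are slightly biased downward
  (long dwells are preferentially censored); at 3-hour sessions with
  10-minute dwells the bias is a few percent.
- `run_pipeline` currently drives synthetic cohorts end-to-end; externally
  recorded data enter through `io.read_cohort` (HDF5 + sidecar metadata)
  and `pipeline.analyze_cohort`.
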