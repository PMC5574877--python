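"""Markov-chain statistics over discrete state sequences.

Transition matrices are estimated by counting adjacent label pairs within
sequences (never across subject/condition boundaries), reported with a
display floor of 10^-3 so log-scale plots are well defined, and bounded by a
jackknife over subjects. Dwell-time records (maximal constant runs) support
distribution fits comparing a memoryless (geometric/exponential) model
against a discrete power law, and the stickiness ratio summarizes how much
more likely the system is to stay than to switch — the signature of
metastable dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .errors import InsufficientDataError, InvalidParameterError, UnknownStateError
from .types import CountMatrix, DwellRecord, ReportMatrix, StateSequence, TransitionMatrix

__all__ = [
    "REPORT_FLOOR",
    "estimate_transition_matrix",
    "apply_report_floor",
    "jackknife_bounds",
    "per_concentration_matrices",
    "extract_dwells",
    "DwellFit",
    "dwell_distribution_fit",
    "stickiness_ratio",
]

REPORT_FLOOR = 1e-3
POWERLAW_XMIN = 2  # windows; at 1 window geometric and power law are indistinguishable


def _count_transitions(sequences: list[StateSequence], k: int) -> np.ndarray:
    C = np.zeros((k, k), dtype=np.int64)
    for seq in sequences:
        lab = seq.labels
        if lab.min(initial=0) < 0 or lab.max(initial=0) >= k:
            raise UnknownStateError(
                f"labels outside 0..{k - 1} in sequence {seq.subject_id}/{seq.condition}"
            )
        np.add.at(C, (lab[:-1], lab[1:]), 1)
    return C


def estimate_transition_matrix(
    sequences: list[StateSequence], k: int
) -> tuple[CountMatrix, TransitionMatrix]:
    """Maximum-likelihood transition matrix from adjacent pairs.

    Transitions are never counted across sequence boundaries. Rows with no
    outgoing observations are flagged in ``unobserved_rows`` and stored as
    self-transitions so the matrix remains row-stochastic.
    """
    if not sequences:
        raise InvalidParameterError("no sequences given")
    C = _count_transitions(sequences, k)
    row_sums = C.sum(axis=1)
    P = np.zeros((k, k), dtype=float)
    unobserved = frozenset(int(i) for i in np.nonzero(row_sums == 0)[0])
    for i in range(k):
        if row_sums[i] > 0:
            P[i] = C[i] / row_sums[i]
        else:
            P[i, i] = 1.0
    wd = sequences[0].window_duration_s
    T = TransitionMatrix(tuple(range(k)), P, wd, unobserved_rows=unobserved)
    return CountMatrix(C, int(C.sum())), T


def apply_report_floor(
    P: TransitionMatrix | np.ndarray,
    floor: float = REPORT_FLOOR,
    unobserved_states: frozenset[int] | set[int] = frozenset(),
) -> ReportMatrix:
    """Display form: entries below ``floor`` raised to it; for each state in
    ``unobserved_states`` the whole row and column are set to ``floor``.

    The underlying estimate is retained unmodified for computation, so
    applying the floor is idempotent on the report and lossless underneath.
    """
    if not 0 < floor < 1:
        raise InvalidParameterError("floor must lie in (0, 1)")
    M = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    unobs = frozenset(int(s) for s in unobserved_states)
    if isinstance(P, TransitionMatrix):
        unobs = unobs | P.unobserved_rows
    R = np.maximum(M, floor)
    for s in unobs:
        R[s, :] = floor
        R[:, s] = floor
    return ReportMatrix(R, floor, unobs, M.copy())


def jackknife_bounds(
    per_subject_sequences: dict[str, list[StateSequence]],
    k: int,
    alpha: float = 0.05,
    floor: float = REPORT_FLOOR,
    quantile: str = "t",
) -> tuple[ReportMatrix, ReportMatrix]:
    """Leave-one-subject-out confidence limits on the pooled transition matrix.

    For each entry, the jackknife standard error over the n leave-one-out
    estimates is sqrt[(n-1)/n * sum((theta_i - mean)^2)], and the bounds are
    pooled estimate +/- q * SE clipped into [floor, 1]. With few subjects the
    Student-t quantile with n-1 degrees of freedom (``quantile="t"``, the
    default) gives intervals with close-to-nominal coverage; ``"normal"``
    uses the Gaussian quantile instead.
    """
    subjects = sorted(per_subject_sequences)
    n = len(subjects)
    if n < 2:
        raise InsufficientDataError("jackknife needs >= 2 subjects")
    all_seqs = [s for subj in subjects for s in per_subject_sequences[subj]]
    _, pooled = estimate_transition_matrix(all_seqs, k)

    loo = np.full((n, k, k), np.nan)
    for i, subj in enumerate(subjects):
        rest = [s for other in subjects if other != subj for s in per_subject_sequences[other]]
        C = _count_transitions(rest, k)
        rs = C.sum(axis=1)
        Pi = np.full((k, k), np.nan)
        obs = rs > 0
        Pi[obs] = C[obs] / rs[obs, None]
        loo[i] = Pi

    m = np.sum(~np.isnan(loo), axis=0)  # usable leave-one-out estimates per entry
    mean_loo = np.nanmean(np.where(np.isnan(loo), np.nan, loo), axis=0)
    dev2 = np.nansum((loo - mean_loo[None]) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt((m - 1) / m * dev2)
    se = np.where(m >= 2, se, 0.0)

    if quantile == "t":
        q = stats.t.ppf(1 - alpha / 2, df=n - 1)
    elif quantile == "normal":
        q = stats.norm.ppf(1 - alpha / 2)
    else:
        raise InvalidParameterError("quantile must be 't' or 'normal'")

    lower = np.clip(pooled.P - q * se, floor, 1.0)
    upper = np.clip(pooled.P + q * se, floor, 1.0)
    unobs = pooled.unobserved_rows
    lo_r = apply_report_floor(lower, floor, unobs)
    hi_r = apply_report_floor(upper, floor, unobs)
    return lo_r, hi_r


def per_concentration_matrices(
    sequences_by_condition: dict[str, list[StateSequence]],
    k: int,
    floor: float = REPORT_FLOOR,
) -> dict[str, ReportMatrix]:
    """Per-condition report matrices with the absent-cluster rule.

    States that never occur at a condition get their entire row and column
    set to the floor in that condition's report.
    """
    out: dict[str, ReportMatrix] = {}
    for cond, seqs in sequences_by_condition.items():
        if not seqs:
            raise InvalidParameterError(f"condition {cond!r} has no sequences")
        occupied = set()
        for s in seqs:
            occupied.update(int(v) for v in np.unique(s.labels))
        absent = frozenset(range(k)) - frozenset(occupied)
        _, T = estimate_transition_matrix(seqs, k)
        out[cond] = apply_report_floor(T, floor, absent)
    return out


def extract_dwells(sequences: list[StateSequence]) -> list[DwellRecord]:
    """Maximal constant runs per sequence, with boundary runs flagged censored.

    The first and last run of each sequence are truncated by the start/end of
    the recording; their durations are lower bounds, so they are flagged and
    excluded from distribution fits. Per sequence, the run durations sum to
    the sequence duration.
    """
    if not sequences:
        raise InvalidParameterError("no sequences given")
    records: list[DwellRecord] = []
    for seq in sequences:
        lab = seq.labels
        change = np.nonzero(lab[1:] != lab[:-1])[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lab.size]))
        n_runs = starts.size
        for r, (a, b) in enumerate(zip(starts, ends)):
            records.append(
                DwellRecord(
                    state=int(lab[a]),
                    duration_s=(b - a) * seq.window_duration_s,
                    subject_id=seq.subject_id,
                    condition=seq.condition,
                    censored=(r == 0 or r == n_runs - 1),
                )
            )
    return records


@dataclass
class DwellFit:
    """Exponential vs discrete power-law comparison for one state's dwells.

    Log-likelihoods are computed on the common truncated support
    (dwells >= xmin windows) so the one-parameter models are directly
    comparable; no significance claim is attached.
    """

    rate_per_s: float
    mean_dwell_s: float
    loglik_exponential: float
    powerlaw_exponent: float
    loglik_powerlaw: float
    preferred: str
    n_dwells: int
    n_truncated: int
    xmin_windows: int


def dwell_distribution_fit(
    dwells: list[DwellRecord],
    window_duration_s: float,
    xmin_windows: int = POWERLAW_XMIN,
) -> DwellFit:
    """Fit exponential (memoryless) and discrete power-law dwell models.

    Uncensored dwells only. The exponential rate is 1/mean of the dwell
    durations. For the model comparison, both a geometric (the discrete
    exponential) and a Hurwitz-zeta power law are fitted by maximum
    likelihood on dwells of at least ``xmin_windows`` windows, and the model
    with the higher log-likelihood is preferred (equal parameter counts).
    """
    durations_s = np.array([d.duration_s for d in dwells if not d.censored])
    if durations_s.size < 20:
        raise InsufficientDataError(
            f"need >= 20 uncensored dwells, got {durations_s.size}"
        )
    mean_s = float(durations_s.mean())
    rate = 1.0 / mean_s

    d = np.round(durations_s / window_duration_s).astype(np.int64)
    dt = d[d >= xmin_windows]
    if dt.size < 10:
        raise InsufficientDataError("too few dwells above the power-law minimum")

    # geometric truncated to d >= xmin: d - xmin is geometric starting at 0
    p_hat = 1.0 / (dt.mean() - xmin_windows + 1.0)
    p_hat = min(max(p_hat, 1e-12), 1 - 1e-12)
    ll_geom = float(np.sum((dt - xmin_windows) * np.log1p(-p_hat) + np.log(p_hat)))

    # discrete power law P(d) = d^-a / zeta(a, xmin)
    log_d_sum = float(np.log(dt).sum())

    def nll(a: float) -> float:
        return a * log_d_sum + dt.size * np.log(special.zeta(a, xmin_windows))

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-6, 25.0), method="bounded")
    alpha = float(res.x)
    ll_pl = float(-res.fun)

    preferred = "exponential" if ll_geom >= ll_pl else "powerlaw"
    return DwellFit(
        rate_per_s=rate,
        mean_dwell_s=mean_s,
        loglik_exponential=ll_geom,
        powerlaw_exponent=alpha,
        loglik_powerlaw=ll_pl,
        preferred=preferred,
        n_dwells=int(durations_s.size),
        n_truncated=int(dt.size),
        xmin_windows=xmin_windows,
    )


def stickiness_ratio(P: TransitionMatrix) -> float:
    """min over observed states of p_ii / max observed off-diagonal entry.

    Values much greater than 1 indicate that remaining in any state is far
    more likely than any single between-state transition — metastability.
    """
    k = P.k
    observed = [i for i in range(k) if i not in P.unobserved_rows]
    if not observed:
        raise InvalidParameterError("all rows unobserved")
    diag = np.diag(P.P)[observed]
    off = P.P[np.ix_(observed, observed)].copy()
    np.fill_diagonal(off, -np.inf)
    max_off = off.max()
    if max_off <= 0:
        return float("inf")
    return float(diag.min() / max_off)
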