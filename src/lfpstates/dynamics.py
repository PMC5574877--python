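"""Conceptual dynamical models of metastability and recovery.

Two models: (1) an overdamped particle in a symmetric double-well potential
psi(x) = b*x^4 - a*x^2 driven by additive white noise, whose rare
between-well jumps realize a two-state metastable system and whose escape
rate can be compared against the Kramers closed form; (2) recovery of a
system to a small target region of a d-dimensional phase space modeled as an
isotropic Gaussian random walk, whose hitting times grow rapidly with
dimension — the argument that recovery through an unstructured
high-dimensional space would take implausibly long.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError, UnstableStepError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "DoubleWellConfig",
    "EscapeSummary",
    "double_well_potential",
    "double_well_force",
    "barrier_height",
    "kramers_rate",
    "simulate_langevin",
    "escape_analysis",
    "random_walk_recovery",
    "recovery_time_curve",
]

KRAMERS_VALID_RATIO = 3.0  # barrier/noise ratio below which the asymptotic form is suspect


@dataclass(frozen=True)
class DoubleWellConfig:
    """Symmetric quartic double well with additive noise.

    psi(x) = b*x^4 - a*x^2 has minima at +/-sqrt(a/2b) and barrier height
    a^2/(4b); ``noise_intensity`` is the diffusion constant D in
    dx = -psi'(x) dt + sqrt(2 D dt) xi.
    """

    a: float = 2.0
    b: float = 1.0
    noise_intensity: float = 0.2
    dt: float = 0.01
    duration: float = 1000.0
    x0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError("need a > 0 and b > 0 for two wells")
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidParameterError("dt and duration must be positive")
        if self.noise_intensity < 0:
            raise InvalidParameterError("noise_intensity must be >= 0")

    @property
    def x_min(self) -> float:
        return float(np.sqrt(self.a / (2.0 * self.b)))

    @property
    def barrier(self) -> float:
        return barrier_height(self.a, self.b)


@dataclass
class EscapeSummary:
    """Between-well escape statistics with the Kramers comparison."""

    escape_times: np.ndarray
    empirical_rate: float
    kramers_rate: float
    noise_intensity: float
    barrier: float
    kramers_valid: bool = True

    @property
    def mean_escape_time(self) -> float:
        return float(np.mean(self.escape_times))

    @property
    def cv(self) -> float:
        """Coefficient of variation; ~1 for exponential waiting times."""
        t = self.escape_times
        return float(np.std(t) / np.mean(t))


def double_well_potential(x, a: float = 2.0, b: float = 1.0):
    """psi(x) = b*x^4 - a*x^2 (symmetric; minima at +/-sqrt(a/2b))."""
    x = np.asarray(x, dtype=float)
    return b * x**4 - a * x**2


def double_well_force(x, a: float = 2.0, b: float = 1.0):
    """-psi'(x) = 2*a*x - 4*b*x^3."""
    x = np.asarray(x, dtype=float)
    return 2.0 * a * x - 4.0 * b * x**3


def barrier_height(a: float, b: float) -> float:
    """Delta psi = a^2 / (4 b): well depth relative to the barrier at x=0."""
    return a * a / (4.0 * b)


def kramers_rate(a: float, b: float, D: float) -> float:
    """Asymptotic escape rate for the overdamped symmetric quartic well.

    rate = sqrt(psi''(x_min) * |psi''(0)|) / (2 pi) * exp(-Delta psi / D),
    with psi''(x_min) = 4a and |psi''(0)| = 2a.
    """
    prefactor = np.sqrt(4.0 * a * 2.0 * a) / (2.0 * np.pi)
    return float(prefactor * np.exp(-barrier_height(a, b) / D))


def _em_python(x0, a, b, dt, sqrt_term, noise):
    x = np.empty(noise.size + 1)
    x[0] = x0
    cur = x0
    for i in range(noise.size):
        cur = cur + (2.0 * a * cur - 4.0 * b * cur**3) * dt + sqrt_term * noise[i]
        x[i + 1] = cur
    return x


if _HAVE_NUMBA:
    _em_core = njit(cache=True)(_em_python)
else:  # pragma: no cover
    _em_core = _em_python


def simulate_langevin(cfg: DoubleWellConfig) -> np.ndarray:
    """Euler-Maruyama integration of the noisy double well.

    Returns positions at each step (length n_steps + 1 including x0).
    The step must satisfy dt * psi''(x_min) < 0.1; the maximum curvature on
    the well floor is 4a.
    """
    if cfg.dt * 4.0 * cfg.a >= 0.1:
        raise UnstableStepError(
            f"dt={cfg.dt} too large for curvature 4a={4 * cfg.a} (need dt*4a < 0.1)"
        )
    n = int(round(cfg.duration / cfg.dt))
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(n)
    sqrt_term = np.sqrt(2.0 * cfg.noise_intensity * cfg.dt)
    return _em_core(cfg.x0, cfg.a, cfg.b, cfg.dt, sqrt_term, noise)


def escape_analysis(
    trajectory: np.ndarray,
    cfg: DoubleWellConfig,
    hysteresis_frac: float = 0.5,
    min_escapes: int = 10,
) -> EscapeSummary:
    """Committed between-well switches and their waiting-time statistics.

    Well membership uses a hysteresis band: positions with
    |x| < hysteresis_frac * x_min are uncommitted, so rapid re-crossings at
    the barrier top are not counted as escapes. Escape times are the
    intervals between successive committed well changes; the leading
    interval (from the start of the trajectory) is censored and dropped.
    """
    x = np.asarray(trajectory, dtype=float)
    thr = hysteresis_frac * cfg.x_min
    committed = np.abs(x) >= thr
    idx = np.nonzero(committed)[0]
    if idx.size == 0:
        raise InsufficientDataError("trajectory never commits to a well")
    wells = np.sign(x[idx])
    change = np.nonzero(wells[1:] != wells[:-1])[0] + 1
    switch_steps = idx[change]  # first committed sample in the new well
    if switch_steps.size < min_escapes + 1:
        raise InsufficientDataError(
            f"only {switch_steps.size} escapes observed; need > {min_escapes}"
        )
    escape_times = np.diff(switch_steps) * cfg.dt
    emp_rate = 1.0 / float(np.mean(escape_times))
    kr = kramers_rate(cfg.a, cfg.b, cfg.noise_intensity)
    valid = (
        cfg.noise_intensity > 0
        and cfg.barrier / cfg.noise_intensity >= KRAMERS_VALID_RATIO
    )
    return EscapeSummary(
        escape_times=escape_times,
        empirical_rate=emp_rate,
        kramers_rate=kr,
        noise_intensity=cfg.noise_intensity,
        barrier=cfg.barrier,
        kramers_valid=bool(valid),
    )


def random_walk_recovery(
    dim: int,
    start_distance: float = 1.0,
    target_radius: float = 0.5,
    step_sd: float = 0.5,
    max_steps: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[int, bool]:
    """First hitting time of a target ball by an isotropic Gaussian walk.

    The walker starts at distance ``start_distance`` from the center of a
    ball of radius ``target_radius`` in ``dim`` dimensions and takes
    N(0, step_sd^2 I) steps. Returns (steps, censored): the first step index
    with position inside the ball (0 if the start is already inside), or
    (max_steps, True) if the ball is never hit.
    """
    if dim < 1:
        raise InvalidParameterError("dim must be >= 1")
    if target_radius <= 0:
        raise InvalidParameterError("target_radius must be > 0")
    if start_distance <= target_radius:
        return 0, False
    rng = np.random.default_rng(seed)
    pos = np.zeros(dim)
    pos[0] = start_distance
    r2 = target_radius**2
    for step in range(1, max_steps + 1):
        pos = pos + rng.normal(0.0, step_sd, size=dim)
        if pos @ pos <= r2:
            return step, False
    return max_steps, True


def recovery_time_curve(
    dims: list[int],
    n_reps: int = 500,
    start_distance: float = 1.0,
    target_radius: float = 0.5,
    step_sd: float = 0.5,
    max_steps: int = 1000,
    seed: int = 0,
) -> dict[int, dict[str, float]]:
    """Median hitting time and censoring fraction versus dimension.

    Censored walks contribute ``max_steps`` to the median, so the reported
    medians are lower bounds where censoring is heavy. Walks are vectorized
    across replicates.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[int, dict[str, float]] = {}
    for dim, child in zip(dims, ss.spawn(len(dims))):
        rng = np.random.default_rng(child)
        pos = np.zeros((n_reps, dim))
        pos[:, 0] = start_distance
        hit_at = np.full(n_reps, max_steps, dtype=np.int64)
        alive = np.ones(n_reps, dtype=bool)
        r2 = target_radius**2
        for step in range(1, max_steps + 1):
            if not alive.any():
                break
            pos[alive] += rng.normal(0.0, step_sd, size=(int(alive.sum()), dim))
            inside = np.einsum("ij,ij->i", pos, pos) <= r2
            newly = alive & inside
            hit_at[newly] = step
            alive &= ~inside
        out[dim] = {
            "median_steps": float(np.median(hit_at)),
            "censored_fraction": float(alive.mean()),
            "n_reps": float(n_reps),
        }
    return out
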