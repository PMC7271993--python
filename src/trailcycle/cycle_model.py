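"""Kinematics of the normalized cell-cycle coordinate.

The cell cycle of a single cell is mapped onto a coordinate ``C`` with
``[0, f_g1)`` representing G1, ``[f_g1, 1)`` representing the pooled
S/G2/M phases, division occurring exactly at ``C = 1``, and ``[1, 2)``
repeating the same layout for the daughter generation.  Within a phase a
cell progresses at a constant, cell-specific rate ``g = f / T`` (cycle
fraction per hour), where ``T`` is the cell's lognormally distributed
phase duration.  In an unsynchronized, exponentially growing population
the initial coordinate follows the steady-state age density
``F(C0) = 2**(1 - C0) * ln 2`` on ``[0, 1)``.

TRAIL exposure slows cycle progression.  This is captured
phenomenologically by a per-phase prolongation ``z`` (hours) that turns
the native rate ``g`` into the corrected rate ``g* = f / (f/g + z)``,
i.e. the phase behaves as if its duration were ``T + z``.  Two
conventions for combining pre- and post-exposure progress are supported
(see :func:`phase_length_under_trail`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

G1 = "G1"
SG2M = "SG2M"
PHASES = (G1, SG2M)

#: prolongation conventions: only post-exposure progress is decelerated
#: (default; reproduces the observed negative slope of phase length vs.
#: time of exposure), or the whole phase is stretched by z regardless of
#: when the cell was exposed.
PROLONGATION_MODES = ("post_exposure", "whole_phase")

LN2 = math.log(2.0)


def as_generator(seed) -> np.random.Generator:
    """Return a numpy Generator from a seed, SeedSequence or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def log_corr_for_duration_corr(target_rho: float, sigma1: float, sigma2: float) -> float:
    """Log-scale correlation that yields a given duration-scale Pearson rho.

    For a bivariate lognormal pair the Pearson correlation of the
    durations is ``(exp(rho_log*s1*s2) - 1) / sqrt((exp(s1^2)-1)*(exp(s2^2)-1))``;
    this inverts that relation.
    """
    denom = math.sqrt(math.expm1(sigma1 ** 2) * math.expm1(sigma2 ** 2))
    arg = 1.0 + target_rho * denom
    if arg <= 0:
        raise ValueError("target correlation not attainable for these sigmas")
    rho_log = math.log(arg) / (sigma1 * sigma2)
    if not -1.0 <= rho_log <= 1.0:
        raise ValueError("implied log-scale correlation outside [-1, 1]")
    return rho_log


@dataclass(frozen=True)
class PhaseParams:
    """Lognormal log-scale parameters of the G1 and S/G2/M durations.

    ``mu_*``/``sigma_*`` are the mean and sd of the log phase durations
    (durations in hours).  ``f_g1`` is the fraction of the cycle
    coordinate assigned to G1 (S/G2/M covers ``1 - f_g1``).  ``rho_log``
    is the correlation between the two log-durations of a cell.
    """

    mu_g1: float = 1.96
    sigma_g1: float = 0.27
    mu_s: float = 2.18
    sigma_s: float = 0.19
    f_g1: float = 0.45
    rho_log: float = 0.0

    def __post_init__(self):
        if self.sigma_g1 <= 0 or self.sigma_s <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.f_g1 < 1.0:
            raise ValueError("f_g1 must be in (0, 1)")
        if not -1.0 <= self.rho_log <= 1.0:
            raise ValueError("rho_log must be in [-1, 1]")

    @property
    def f_s(self) -> float:
        return 1.0 - self.f_g1

    @property
    def mean_g1(self) -> float:
        return math.exp(self.mu_g1 + 0.5 * self.sigma_g1 ** 2)

    @property
    def mean_s(self) -> float:
        return math.exp(self.mu_s + 0.5 * self.sigma_s ** 2)

    @property
    def mean_cycle(self) -> float:
        return self.mean_g1 + self.mean_s

    @property
    def g1_fraction(self) -> float:
        """G1 share of the mean total cycle duration."""
        return self.mean_g1 / self.mean_cycle

    def phase_interval(self, phase: str) -> tuple[float, float]:
        """(start, width) of a phase on the cycle coordinate."""
        if phase == G1:
            return 0.0, self.f_g1
        if phase == SG2M:
            return self.f_g1, self.f_s
        raise ValueError(f"unknown phase {phase!r}")

    def log_params(self, phase: str) -> tuple[float, float]:
        if phase == G1:
            return self.mu_g1, self.sigma_g1
        if phase == SG2M:
            return self.mu_s, self.sigma_s
        raise ValueError(f"unknown phase {phase!r}")

    def marginal(self, phase: str):
        """Frozen scipy lognormal distribution of a phase duration."""
        mu, sigma = self.log_params(phase)
        return stats.lognorm(s=sigma, scale=math.exp(mu))

    def with_duration_corr(self, target_rho: float) -> "PhaseParams":
        """Copy with rho_log set to give a duration-scale Pearson rho."""
        rho_log = log_corr_for_duration_corr(target_rho, self.sigma_g1, self.sigma_s)
        return PhaseParams(self.mu_g1, self.sigma_g1, self.mu_s, self.sigma_s,
                           self.f_g1, rho_log)


# ---------------------------------------------------------------------------
# initial positions and phase durations
# ---------------------------------------------------------------------------

def steady_state_pdf(c):
    """Density 2**(1-c) * ln 2 of cycle positions at steady state."""
    c = np.asarray(c, dtype=float)
    out = np.where((c >= 0) & (c < 1), np.power(2.0, 1.0 - c) * LN2, 0.0)
    return out


def steady_state_cdf(c):
    c = np.asarray(c, dtype=float)
    return np.clip(2.0 - np.power(2.0, 1.0 - c), 0.0, 1.0)


def steady_state_ppf(u):
    """Inverse CDF: C0 = 1 - log2(2 - u) for u in [0, 1)."""
    u = np.asarray(u, dtype=float)
    return 1.0 - np.log2(2.0 - u)


def sample_initial_positions(n, rng, scheme: str = "steady_state", window=None):
    """Sample initial cycle positions on [0, 1).

    Parameters
    ----------
    scheme : {"steady_state", "uniform", "window"}
        ``steady_state`` draws from the exponential-growth age density,
        ``uniform`` from U[0, 1); ``window`` is uniform on ``window``.
        A ``window=(a, b)`` may also be combined with ``steady_state``,
        in which case the steady-state density is renormalized on
        ``[a, b)``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = as_generator(rng)
    if window is not None:
        a, b = float(window[0]), float(window[1])
        if not (0.0 <= a < b <= 1.0):
            raise ValueError(f"invalid window bounds ({a}, {b})")
    if scheme == "steady_state":
        u = rng.random(n)
        if window is None:
            return steady_state_ppf(u)
        lo, hi = steady_state_cdf([window[0], window[1]])
        return steady_state_ppf(lo + u * (hi - lo))
    if scheme in ("uniform", "window"):
        if scheme == "window" and window is None:
            raise ValueError("window scheme requires window bounds")
        a, b = (0.0, 1.0) if window is None else window
        return a + (b - a) * rng.random(n)
    raise ValueError(f"unknown scheme {scheme!r}")


def sample_phase_durations(n, params: PhaseParams, rng):
    """Draw n correlated (T_g1, T_s) duration pairs in hours.

    Marginals are lognormal; dependence is imposed on the log scale via a
    bivariate normal with correlation ``params.rho_log``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = as_generator(rng)
    z = rng.standard_normal((int(n), 2))
    rho = params.rho_log
    z2 = rho * z[:, 0] + math.sqrt(max(0.0, 1.0 - rho ** 2)) * z[:, 1]
    t_g1 = np.exp(params.mu_g1 + params.sigma_g1 * z[:, 0])
    t_s = np.exp(params.mu_s + params.sigma_s * z2)
    return t_g1, t_s


# ---------------------------------------------------------------------------
# growth rates and coordinate motion
# ---------------------------------------------------------------------------

@dataclass
class GrowthRates:
    """Per-cell phase progression rates (cycle fraction per hour).

    Fields may be scalars or aligned arrays.  Daughter-generation rates
    are independently resampled counterparts used for ``C >= 1``; they
    default to the mother's rates.
    """

    g_g1: np.ndarray
    g_s: np.ndarray
    f_g1: float = 0.45
    g_g1_d: np.ndarray = None
    g_s_d: np.ndarray = None

    def __post_init__(self):
        if self.g_g1_d is None:
            self.g_g1_d = self.g_g1
        if self.g_s_d is None:
            self.g_s_d = self.g_s

    @classmethod
    def from_durations(cls, t_g1, t_s, f_g1: float = 0.45,
                       t_g1_d=None, t_s_d=None) -> "GrowthRates":
        f_s = 1.0 - f_g1
        g_g1_d = None if t_g1_d is None else f_g1 / np.asarray(t_g1_d, float)
        g_s_d = None if t_s_d is None else f_s / np.asarray(t_s_d, float)
        return cls(g_g1=f_g1 / np.asarray(t_g1, float),
                   g_s=f_s / np.asarray(t_s, float),
                   f_g1=f_g1, g_g1_d=g_g1_d, g_s_d=g_s_d)

    def segments(self, n_generations: int = 6):
        """Ordered (lo, hi, rate) segments of the cycle coordinate.

        Generations beyond the first daughter reuse the daughter rates;
        they only matter for long horizons relative to the cycle time.
        """
        f = self.f_g1
        segs = []
        for k in range(n_generations):
            g1 = self.g_g1 if k == 0 else self.g_g1_d
            gs = self.g_s if k == 0 else self.g_s_d
            segs.append((float(k), float(k) + f, g1))
            segs.append((float(k) + f, float(k) + 1.0, gs))
        return segs


def advance_position(c0, t, rates: GrowthRates):
    """Advance cycle coordinate(s) by t hours at piecewise-constant rates.

    Motion is linear at the rate of the segment currently occupied and
    continuous across phase boundaries and division (``C = 1``).
    """
    c = np.array(np.broadcast_arrays(np.asarray(c0, float),
                                     np.zeros_like(np.asarray(t, float)))[0],
                 dtype=float, copy=True)
    t_rem = np.array(np.broadcast_to(np.asarray(t, float), c.shape),
                     dtype=float, copy=True)
    if np.any(t_rem < 0):
        raise ValueError("t must be >= 0")
    for lo, hi, g in rates.segments():
        g_arr = np.broadcast_to(np.asarray(g, float), c.shape)
        active = (t_rem > 0) & (c >= lo) & (c < hi)
        if not np.any(active):
            continue
        dt_exit = np.where(active, (hi - c) / g_arr, np.inf)
        finishes = active & (t_rem < dt_exit)
        c = np.where(finishes, c + g_arr * t_rem, c)
        t_rem = np.where(finishes, 0.0, t_rem)
        crosses = active & ~finishes
        c = np.where(crosses, hi, c)
        t_rem = np.where(crosses, t_rem - dt_exit, t_rem)
    if c.ndim == 0:
        return float(c)
    return c


# ---------------------------------------------------------------------------
# TRAIL-induced prolongation
# ---------------------------------------------------------------------------

def corrected_growth_rate(g, f, z):
    """TRAIL-corrected rate g* = f / (f/g + z); equals g at z = 0."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("g must be > 0")
    if np.any(np.asarray(z) < 0):
        raise ValueError("z must be >= 0")
    out = f / (f / g + z)
    return float(out) if out.ndim == 0 else out


def _check_mode(mode: str):
    if mode not in PROLONGATION_MODES:
        raise ValueError(f"mode must be one of {PROLONGATION_MODES}")


def phase_length_under_trail(T, d, z, mode: str = "post_exposure"):
    """Total length of a phase of native duration T, exposed at time d.

    In ``post_exposure`` mode the cell progressed at its native rate for
    the first ``d`` hours and at the corrected rate afterwards, giving
    ``p = T + z - d*z/T`` (strictly decreasing in d for z > 0).  In
    ``whole_phase`` mode the entire phase is stretched: ``p = T + z``.
    """
    _check_mode(mode)
    T = np.asarray(T, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > T * (1 + 1e-12)):
        raise ValueError("require 0 <= d <= T")
    if np.any(np.asarray(z) < 0):
        raise ValueError("z must be >= 0")
    if mode == "whole_phase":
        p = T + z + 0.0 * d
    else:
        p = T + z - d * z / T
    return float(p) if p.ndim == 0 else p


def invert_phase_length(p, d, z, mode: str = "post_exposure",
                        return_flags: bool = False):
    """Native phase duration T from observed length p under prolongation z.

    Inverts :func:`phase_length_under_trail`.  post_exposure mode solves
    ``T**2 + (z - p)*T - d*z = 0`` for its positive root; whole_phase
    mode gives ``T = p - z``.  Results are clipped to ``T > d`` (the
    cell had already spent d hours in the phase); clipped entries are
    flagged when ``return_flags`` is set.
    """
    _check_mode(mode)
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(p <= d):
        raise ValueError("require p > d >= 0")
    if np.any(np.asarray(z) < 0):
        raise ValueError("z must be >= 0")
    if mode == "whole_phase":
        T = p - z + 0.0 * d
    else:
        b = p - z
        T = 0.5 * (b + np.sqrt(b * b + 4.0 * d * z))
    floor = np.where(d > 0, d * (1.0 + 1e-6), 0.0)
    flagged = T <= floor
    # degenerate whole_phase inputs (p <= z + d) land here
    T = np.where(flagged & (d > 0), floor, T)
    T = np.where(flagged & (d == 0), np.maximum(T, 1e-9), T)
    if T.ndim == 0:
        T = float(T)
        flagged = bool(flagged)
    if return_flags:
        return T, flagged
    return T
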