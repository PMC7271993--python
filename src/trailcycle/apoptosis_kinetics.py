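"""Point-of-Apoptosis-Deceleration (PAD) model of death kinetics.

After TRAIL exposure an abstract apoptosis-progression level A rises
from 0 with a cell-specific slope m (the reciprocal of a lognormal
draw); the cell dies when A reaches 1.  Progression is decelerated by a
population-level amount p while the cell's cycle coordinate lies beyond
the deceleration point ``pad`` (and before division); A is floored at 0,
so cells with m < p stall until the deceleration is released.  In the
default ``release_at_division`` variant the deceleration is removed at
division (C = 1); the ``extended_second_generation`` variant re-applies
it on (pad + 1, 2] of the daughter generation.

(p, pad) are estimated on a grid by a sampling-based likelihood: large
model cohorts of (C0, t_death) tuples are summarized by a bivariate
Gaussian kernel density, experimental tuples are scored against it, and
chi-square thresholds on the averaged negative log-likelihood surface
give joint and per-parameter confidence regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cycle_model import (
    GrowthRates, PhaseParams, as_generator, sample_initial_positions,
    sample_phase_durations,
)

VARIANTS = ("release_at_division", "extended_second_generation")

CHI2_2_95_HALF = stats.chi2.ppf(0.95, 2) / 2.0   # 2.996, joint region
CHI2_1_95_HALF = stats.chi2.ppf(0.95, 1) / 2.0   # 1.921, profiles
KDE_FLOOR = 1e-9


@dataclass(frozen=True)
class ApoptosisParams:
    """Population-level PAD parameters (per-cell slopes drawn separately)."""

    p: float = 0.2
    pad: float = 0.52
    variant: str = "release_at_division"
    mu_td: float = 1.0
    sigma_td: float = 0.39

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if not 0.0 <= self.pad <= 1.0:
            raise ValueError("pad must be in [0, 1]")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def _breakpoints(f_g1: float, pad: float, n_generations: int) -> np.ndarray:
    pts = set()
    for k in range(n_generations):
        pts.update((k, k + f_g1, k + pad, k + 1.0))
    return np.array(sorted(pts))


def death_times(c0, rates: GrowthRates, m, p: float, pad: float,
                variant: str = "release_at_division",
                horizon: float = np.inf,
                n_generations: int = 6) -> np.ndarray:
    """Closed-form piecewise-linear death times of the PAD model.

    Integrates A(t) exactly across the breakpoints where either the
    cycle rate or the apoptosis slope changes; cells whose A does not
    reach 1 within ``horizon`` get ``inf``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    c0 = np.atleast_1d(np.asarray(c0, float))
    if np.any(c0 < 0) or np.any(c0 >= 1):
        raise ValueError("c0 must lie in [0, 1)")
    shape = c0.shape
    m = np.broadcast_to(np.asarray(m, float), shape)
    g_g1 = np.broadcast_to(np.asarray(rates.g_g1, float), shape)
    g_s = np.broadcast_to(np.asarray(rates.g_s, float), shape)
    g_g1_d = np.broadcast_to(np.asarray(rates.g_g1_d, float), shape)
    g_s_d = np.broadcast_to(np.asarray(rates.g_s_d, float), shape)
    f = rates.f_g1

    c = c0.copy()
    t = np.zeros(shape)
    A = np.zeros(shape)
    td = np.full(shape, np.inf)
    alive = np.ones(shape, dtype=bool)

    bps = _breakpoints(f, pad, n_generations)
    for lo, hi in zip(bps[:-1], bps[1:]):
        if not np.any(alive):
            break
        mid = 0.5 * (lo + hi)
        gen = int(mid)
        within = mid - gen
        if gen == 0:
            rate = g_g1 if within < f else g_s
        else:
            rate = g_g1_d if within < f else g_s_d
        decel = (gen == 0 and within > pad) or \
                (variant == "extended_second_generation"
                 and gen == 1 and within > pad)
        slope = (m - p) if decel else m

        active = alive & (c >= lo) & (c < hi)
        if not np.any(active):
            continue
        dt_seg = np.where(active, (hi - c) / rate, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hit = np.where(slope > 0, (1.0 - A) / slope, np.inf)
        dies = active & (slope > 0) & (t_hit <= dt_seg) & (t + t_hit <= horizon)
        td = np.where(dies, t + t_hit, td)
        alive = alive & ~dies
        moves = active & ~dies
        timeout = moves & (t + dt_seg >= horizon)
        alive = alive & ~timeout
        A = np.where(moves, np.maximum(A + slope * dt_seg, 0.0), A)
        t = np.where(moves, t + dt_seg, t)
        c = np.where(moves, hi, c)

    # beyond the tabulated generations A rises at the native slope m
    rem = (1.0 - A) / m
    late = alive & (t + rem <= horizon)
    td = np.where(late, t + rem, td)
    return td


def death_time(c0: float, rates: GrowthRates, params: ApoptosisParams, m: float,
               horizon: float = np.inf) -> Optional[float]:
    """Scalar convenience wrapper; returns None when no death in horizon."""
    td = death_times(c0, rates, m, params.p, params.pad,
                     variant=params.variant, horizon=horizon)[0]
    return None if np.isinf(td) else float(td)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortBase:
    """Sampled per-cell state shared across a (p, pad) grid scan."""

    c0: np.ndarray
    rates: GrowthRates
    m: np.ndarray


def draw_cohort_base(n: int, phase_params: PhaseParams, rng,
                     c0_scheme: str = "steady_state",
                     mu_td: float = 1.0, sigma_td: float = 0.39,
                     window=None) -> CohortBase:
    """Draw positions, growth rates and apoptosis slopes for a cohort."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_generator(rng)
    c0 = sample_initial_positions(n, rng, scheme=c0_scheme, window=window)
    t_g1, t_s = sample_phase_durations(n, phase_params, rng)
    t_g1_d, t_s_d = sample_phase_durations(n, phase_params, rng)
    rates = GrowthRates.from_durations(t_g1, t_s, phase_params.f_g1,
                                       t_g1_d, t_s_d)
    m = 1.0 / np.exp(rng.normal(mu_td, sigma_td, size=n))
    return CohortBase(c0=c0, rates=rates, m=m)


def simulate_cohort(n: int, phase_params: PhaseParams, rng,
                    params: ApoptosisParams = None,
                    c0_scheme: str = "steady_state",
                    horizon: float = np.inf, window=None):
    """Simulate (c0, t_death) tuples; no-death cells are counted apart.

    Returns ``(c0_dead, t_dead, n_alive)``.
    """
    params = params or ApoptosisParams()
    base = draw_cohort_base(n, phase_params, rng, c0_scheme,
                            params.mu_td, params.sigma_td, window=window)
    td = death_times(base.c0, base.rates, base.m, params.p, params.pad,
                     variant=params.variant, horizon=horizon)
    dead = np.isfinite(td)
    return base.c0[dead], td[dead], int((~dead).sum())


# ---------------------------------------------------------------------------
# KDE likelihood and grid estimation
# ---------------------------------------------------------------------------

def kde_density(exp_c0, exp_t, model_c0, model_t) -> np.ndarray:
    """Bivariate Gaussian KDE of model tuples evaluated at query points.

    Uses Silverman's rule on the model covariance (the same bandwidth
    matrix as ``scipy.stats.gaussian_kde(..., bw_method="silverman")``).
    Kernels whose c0 offset exceeds 6 marginal bandwidths contribute at
    most exp(-18) relative weight and are skipped for speed.
    """
    mc0 = np.asarray(model_c0, float)
    mt = np.asarray(model_t, float)
    if mc0.size < 10:
        raise ValueError("model cohort too small for a density estimate")
    if np.std(mc0) == 0 or np.std(mt) == 0:
        raise ValueError("degenerate model cohort (zero variance)")
    n = mc0.size
    factor = (n * (2 + 2) / 4.0) ** (-1.0 / 6.0)   # Silverman, d = 2
    H = factor ** 2 * np.cov(np.vstack([mc0, mt]))
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (n * 2.0 * np.pi * np.sqrt(np.linalg.det(H)))
    order = np.argsort(mc0)
    mc0_s, mt_s = mc0[order], mt[order]
    win = 6.0 * np.sqrt(H[0, 0])
    xq = np.atleast_1d(np.asarray(exp_c0, float))
    tq = np.atleast_1d(np.asarray(exp_t, float))
    out = np.empty(xq.size)
    for j in range(xq.size):
        lo = np.searchsorted(mc0_s, xq[j] - win, side="left")
        hi = np.searchsorted(mc0_s, xq[j] + win, side="right")
        dx = mc0_s[lo:hi] - xq[j]
        dt = mt_s[lo:hi] - tq[j]
        q = Hinv[0, 0] * dx * dx + 2.0 * Hinv[0, 1] * dx * dt \
            + Hinv[1, 1] * dt * dt
        out[j] = norm * np.exp(-0.5 * q).sum()
    return out


def negll_pad(exp_c0, exp_t, model_c0, model_t,
              floor: float = KDE_FLOOR) -> float:
    """Negative log-likelihood of experimental tuples under a model KDE.

    A bivariate Gaussian kernel density is built over the model
    (c0, t_death) tuples; evaluated densities are floored at ``floor``
    to avoid vanishing likelihoods outside the model support.
    """
    dens = kde_density(exp_c0, exp_t, model_c0, model_t)
    return float(-np.log(np.maximum(dens, floor)).sum())


@dataclass
class PADEstimate:
    p_grid: np.ndarray
    pad_grid: np.ndarray
    surface: np.ndarray              # mean over repetitions, (n_p, n_pad)
    surfaces: np.ndarray             # per repetition, (n_reps, n_p, n_pad)
    p_hat: float
    pad_hat: float
    region: np.ndarray               # 95% joint chi-square region mask
    ci_p: tuple
    ci_pad: tuple
    n_reps: int
    cohort_size: int
    on_boundary: bool = False

    def rep_region(self, r: int) -> np.ndarray:
        s = self.surfaces[r]
        return s - s.min() <= CHI2_2_95_HALF


def _profile_ci(surface: np.ndarray, grid: np.ndarray, axis: int):
    prof = surface.min(axis=axis)
    inside = prof - prof.min() <= CHI2_1_95_HALF
    return float(grid[inside].min()), float(grid[inside].max())


def estimate_pad(exp_c0, exp_t, phase_params: PhaseParams,
                 p_grid=None, pad_grid=None, n_reps: int = 6,
                 cohort_size: int = 80_000, rng=None,
                 variant: str = "release_at_division",
                 c0_scheme: str = "steady_state",
                 mu_td: float = 1.0, sigma_td: float = 0.39,
                 horizon: float = np.inf,
                 kde_floor: float = KDE_FLOOR) -> PADEstimate:
    """Grid estimation of (p, pad) with chi-square confidence regions.

    Per repetition one cohort base (positions, rates, slopes) is drawn
    and reused across the whole grid (common random numbers), so the
    surface differences between grid points are not dominated by
    sampling noise; the surface is then averaged over repetitions.
    """
    rng = as_generator(rng)
    p_grid = np.arange(0.0, 0.401, 0.01) if p_grid is None \
        else np.asarray(p_grid, float)
    pad_grid = np.arange(0.3, 0.901, 0.01) if pad_grid is None \
        else np.asarray(pad_grid, float)
    if p_grid.size == 0 or pad_grid.size == 0:
        raise ValueError("grids must be non-empty")
    exp_c0 = np.asarray(exp_c0, float)
    exp_t = np.asarray(exp_t, float)
    surfaces = np.empty((n_reps, p_grid.size, pad_grid.size))
    for r in range(n_reps):
        base = draw_cohort_base(cohort_size, phase_params, rng,
                                c0_scheme, mu_td, sigma_td)
        for i, p in enumerate(p_grid):
            for j, pad in enumerate(pad_grid):
                td = death_times(base.c0, base.rates, base.m, p, pad,
                                 variant=variant, horizon=horizon)
                dead = np.isfinite(td)
                surfaces[r, i, j] = negll_pad(exp_c0, exp_t,
                                              base.c0[dead], td[dead],
                                              floor=kde_floor)
    surface = surfaces.mean(axis=0)
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    on_boundary = i in (0, p_grid.size - 1) or j in (0, pad_grid.size - 1)
    region = surface - surface[i, j] <= CHI2_2_95_HALF
    return PADEstimate(
        p_grid=p_grid, pad_grid=pad_grid, surface=surface, surfaces=surfaces,
        p_hat=float(p_grid[i]), pad_hat=float(pad_grid[j]), region=region,
        ci_p=_profile_ci(surface, p_grid, axis=1),
        ci_pad=_profile_ci(surface, pad_grid, axis=0),
        n_reps=n_reps, cohort_size=cohort_size, on_boundary=on_boundary)


class PADEstimator(BaseEstimator):
    """Fit the PAD model to (c0, t_death) tuples.

    ``fit`` accepts an (n, 2) array with columns (c0, t_death) or a
    DataFrame with ``c0_hat`` and ``death_h`` columns.

    Attributes
    ----------
    p_hat_, pad_hat_ : float
    ci_p_, ci_pad_ : (low, high) profile intervals
    estimate_ : PADEstimate with the full surface and regions
    """

    def __init__(self, phase_params: Optional[PhaseParams] = None,
                 p_grid=None, pad_grid=None, n_reps: int = 6,
                 cohort_size: int = 80_000,
                 variant: str = "release_at_division",
                 c0_scheme: str = "steady_state",
                 mu_td: float = 1.0, sigma_td: float = 0.39,
                 horizon: float = np.inf, random_state=None):
        self.phase_params = phase_params
        self.p_grid = p_grid
        self.pad_grid = pad_grid
        self.n_reps = n_reps
        self.cohort_size = cohort_size
        self.variant = variant
        self.c0_scheme = c0_scheme
        self.mu_td = mu_td
        self.sigma_td = sigma_td
        self.horizon = horizon
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            sub = X[X["c0_hat"].notna() & X["death_h"].notna()]
            if "fate" in sub.columns:
                sub = sub[sub["fate"] == "apoptotic"]
            c0, t = sub["c0_hat"].to_numpy(float), sub["death_h"].to_numpy(float)
        else:
            arr = np.asarray(X, float)
            c0, t = arr[:, 0], arr[:, 1]
        pp = self.phase_params or PhaseParams()
        self.estimate_ = estimate_pad(
            c0, t, pp, p_grid=self.p_grid, pad_grid=self.pad_grid,
            n_reps=self.n_reps, cohort_size=self.cohort_size,
            rng=as_generator(self.random_state), variant=self.variant,
            c0_scheme=self.c0_scheme, mu_td=self.mu_td,
            sigma_td=self.sigma_td, horizon=self.horizon)
        self.p_hat_ = self.estimate_.p_hat
        self.pad_hat_ = self.estimate_.pad_hat
        self.ci_p_ = self.estimate_.ci_p
        self.ci_pad_ = self.estimate_.ci_pad
        self.n_tuples_ = int(c0.size)
        return self


# ---------------------------------------------------------------------------
# synchronization sweeps and mean trajectories
# ---------------------------------------------------------------------------

def division_times(c0, rates: GrowthRates):
    """Time to first division (C = 1) at the native rates."""
    c0 = np.asarray(c0, float)
    f = rates.f_g1
    in_g1 = c0 < f
    t_g1_part = np.where(in_g1, (f - c0) / rates.g_g1, 0.0)
    t_s_part = np.where(in_g1, (1.0 - f) / rates.g_s, (1.0 - c0) / rates.g_s)
    return t_g1_part + t_s_part


def _prolonged(rates: GrowthRates, f_g1: float, z_g1: float, z_s: float) -> GrowthRates:
    """Corrected rates for motion that happens entirely under TRAIL."""
    f_s = 1.0 - f_g1
    return GrowthRates(
        g_g1=f_g1 / (f_g1 / rates.g_g1 + z_g1),
        g_s=f_s / (f_s / rates.g_s + z_s),
        f_g1=f_g1,
        g_g1_d=f_g1 / (f_g1 / rates.g_g1_d + z_g1),
        g_s_d=f_s / (f_s / rates.g_s_d + z_s))


def synchronization_sweep(windows, phase_params: PhaseParams, rng,
                          params: ApoptosisParams = None,
                          n_per_window: int = 5000,
                          horizon: float = 19.25,
                          z_g1: float = 3.6, z_s: float = 3.4) -> pd.DataFrame:
    """Death-timing statistics for populations synchronized in C0 windows.

    Within each window C0 is sampled uniformly.  All cycle progression
    happens under TRAIL, so the coordinate moves at the corrected rates
    for the fitted per-phase prolongations ``z_g1``/``z_s`` (set both to
    0 for native progression).  Reported per window: median and IQR of
    observed death times, the fraction of cells that divide before dying
    (or before the horizon for non-dying cells), and the fraction
    without death within the horizon.
    """
    params = params or ApoptosisParams()
    rng = as_generator(rng)
    rows = []
    for a, b in windows:
        if not (0.0 <= a < b <= 1.0):
            raise ValueError(f"invalid window ({a}, {b})")
        base = draw_cohort_base(n_per_window, phase_params, rng,
                                c0_scheme="uniform",
                                mu_td=params.mu_td, sigma_td=params.sigma_td,
                                window=(a, b))
        rates = _prolonged(base.rates, phase_params.f_g1, z_g1, z_s) \
            if (z_g1 or z_s) else base.rates
        td = death_times(base.c0, rates, base.m, params.p, params.pad,
                         variant=params.variant, horizon=horizon)
        tdiv = division_times(base.c0, rates)
        dead = np.isfinite(td)
        obs = td[dead]
        divided = tdiv < np.where(dead, td, horizon)
        rows.append({
            "window_lo": a, "window_hi": b,
            "n": n_per_window, "n_deaths": int(dead.sum()),
            "median_t_death": float(np.median(obs)) if obs.size else np.nan,
            "iqr_t_death": float(np.percentile(obs, 75) - np.percentile(obs, 25))
                           if obs.size else np.nan,
            "frac_divided_before_death": float(divided.mean()),
            "frac_surviving_horizon": float((~dead).mean()),
        })
    return pd.DataFrame(rows)


def mean_progression_curve(c0: float, phase_params: PhaseParams,
                           mean_m: float, p: float, pad: float,
                           variant: str = "release_at_division"):
    """Deterministic A(t) trajectory at population-mean parameters.

    Uses the mean phase durations for the coordinate motion and the mean
    apoptosis slope; returns (t, A) arrays of the piecewise-linear
    breakpoints up to the death time (A = 1).
    """
    rates = GrowthRates.from_durations(phase_params.mean_g1,
                                       phase_params.mean_s,
                                       phase_params.f_g1)
    m = float(mean_m)
    bps = _breakpoints(phase_params.f_g1, pad, 6)
    ts, As = [0.0], [0.0]
    t, A, c = 0.0, 0.0, float(c0)
    for lo, hi in zip(bps[:-1], bps[1:]):
        if not (lo <= c < hi):
            continue
        mid = 0.5 * (lo + hi)
        gen = int(mid)
        within = mid - gen
        rate = rates.g_g1 if within < phase_params.f_g1 else rates.g_s
        decel = (gen == 0 and within > pad) or \
                (variant == "extended_second_generation"
                 and gen == 1 and within > pad)
        slope = m - p if decel else m
        dt = (hi - c) / rate
        if slope > 0 and A + slope * dt >= 1.0:
            t_hit = (1.0 - A) / slope
            ts.append(t + t_hit)
            As.append(1.0)
            return np.array(ts), np.array(As)
        if slope < 0 and A > 0 and A + slope * dt < 0:
            # breakpoint where A hits the floor inside the segment
            ts.append(t + A / (-slope))
            As.append(0.0)
        A = max(A + slope * dt, 0.0)
        t += dt
        c = hi
        ts.append(t)
        As.append(A)
    t_hit = (1.0 - A) / m
    ts.append(t + t_hit)
    As.append(1.0)
    return np.array(ts), np.array(As)
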