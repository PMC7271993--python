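"""Virtual single-cell track tables with the statistical structure of
long-term time-lapse experiments.

The generator emulates the design of a Fucci/geminin time-lapse study:
cells are observed for ~19 h before treatment (so the start of the
current phase is known), a TRAIL receptor agonist is added at t = 0, and
cells are followed for another 19.25 h at a 15-min frame interval.  Each
virtual cell carries a cycle position sampled from the steady-state age
density, correlated lognormal phase durations, a phase-specific death
probability, a death time from a configurable death model, and
TRAIL-prolonged phase progression after t = 0.  Events beyond the movie
end are right-censored; event times are optionally snapped to the frame
grid.

Track tables are plain pandas DataFrames with the CSV schema given by
:data:`TRACK_COLUMNS`; times are hours relative to treatment at 0 and
missing values are empty fields with explicit boolean censoring flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cycle_model import (
    G1, SG2M, GrowthRates, PhaseParams, as_generator,
    phase_length_under_trail, sample_initial_positions,
    sample_phase_durations,
)

TRACK_COLUMNS = [
    "cell_id", "parent_id", "phase_at_trail", "d_h",
    "phase_end_h", "phase_end_censored",
    "division_h", "division_censored",
    "death_h", "death_censored",
    "fate", "c0_true",
]

FATES = ("apoptotic", "survivor", "mixed", "censored")

#: duration-scale Pearson correlation between G1 and S/G2/M lengths of a
#: cell, matching the weak coupling seen in control populations.
DEFAULT_DURATION_CORR = 0.33


@dataclass(frozen=True)
class DirectLognormalDeath:
    """Death times drawn directly from a lognormal, independent of C0."""

    mu_d: float = 1.0
    sigma_d: float = 0.39

    def __post_init__(self):
        if self.sigma_d <= 0:
            raise ValueError("sigma_d must be > 0")


@dataclass(frozen=True)
class PADDeath:
    """Death times from the point-of-apoptosis-deceleration model.

    Per-cell apoptosis slope m is the reciprocal of a lognormal
    (mu_td, sigma_td) draw; progression decelerates by p beyond the
    cycle coordinate ``pad`` (see :mod:`trailcycle.apoptosis_kinetics`).
    ``apply_z`` controls whether the TRAIL cycle prolongation also slows
    the coordinate motion inside the death model (off by default).
    """

    mu_td: float = 1.0
    sigma_td: float = 0.39
    p: float = 0.2
    pad: float = 0.52
    variant: str = "release_at_division"
    apply_z: bool = False


DeathModel = Union[DirectLognormalDeath, PADDeath]


def default_phase_params() -> PhaseParams:
    return PhaseParams().with_duration_corr(DEFAULT_DURATION_CORR)


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one virtual time-lapse experiment."""

    n_cells: int = 1000
    pre_obs: float = 19.0
    post_obs: float = 19.25
    frame_interval: float = 0.25
    phase_params: PhaseParams = field(default_factory=default_phase_params)
    z_true: float = 0.0
    death_model: DeathModel = field(default_factory=DirectLognormalDeath)
    death_prob_g1: float = 0.76
    death_prob_s: float = 0.72
    sibling_mode: str = "count_once"
    mixed_fraction: float = 0.03
    c0_scheme: str = "steady_state"
    prolongation_mode: str = "post_exposure"
    snap_to_grid: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("pre_obs", "post_obs", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("death_prob_g1", "death_prob_s", "mixed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.z_true < 0:
            raise ValueError("z_true must be >= 0")
        if self.sibling_mode not in ("count_once", "keep_both"):
            raise ValueError("sibling_mode must be count_once or keep_both")


def _snap(t, dt):
    t = np.asarray(t, dtype=float)
    return np.round(t / dt) * dt


def generate_population(config: ExperimentConfig, rng=None) -> pd.DataFrame:
    """Simulate one virtual cell population as a track table.

    Each row is one tracked mother cell (plus, in ``keep_both`` sibling
    mode, duplicated daughter rows for post-division deaths).  Events are
    right-censored at the movie end and snapped to the frame grid when
    ``config.snap_to_grid`` is set.
    """
    from .apoptosis_kinetics import death_times as _pad_death_times

    rng = as_generator(config.seed if rng is None else rng)
    n = int(config.n_cells)
    pp = config.phase_params
    cols = {c: [] for c in TRACK_COLUMNS}
    if n == 0:
        return pd.DataFrame(cols, columns=TRACK_COLUMNS)

    c0 = sample_initial_positions(n, rng, scheme=config.c0_scheme)
    t_g1, t_s = sample_phase_durations(n, pp, rng)
    t_g1_d, t_s_d = sample_phase_durations(n, pp, rng)
    in_g1 = c0 < pp.f_g1
    z = config.z_true
    mode = config.prolongation_mode

    # time already spent in the current phase (native rate, pre-treatment)
    T_cur = np.where(in_g1, t_g1, t_s)
    frac = np.where(in_g1, c0 / pp.f_g1, (c0 - pp.f_g1) / pp.f_s)
    d = frac * T_cur

    # post-treatment schedule under prolongation z (applies to every
    # phase progressed while TRAIL is present)
    p_cur = phase_length_under_trail(T_cur, d, z, mode)
    rem_cur = p_cur - d                      # time to end of current phase
    # G1-treated cells then traverse a fully exposed S/G2/M phase
    s_full = phase_length_under_trail(t_s, 0.0, z, mode)
    division = np.where(in_g1, rem_cur + s_full, rem_cur)

    # fate labels per phase-specific death probability
    p_die = np.where(in_g1, config.death_prob_g1, config.death_prob_s)
    dies = rng.random(n) < p_die

    t_death = np.full(n, np.inf)
    dm = config.death_model
    if isinstance(dm, DirectLognormalDeath):
        t_death[dies] = np.exp(dm.mu_d + dm.sigma_d * rng.standard_normal(dies.sum()))
    elif isinstance(dm, PADDeath):
        m = 1.0 / np.exp(dm.mu_td + dm.sigma_td * rng.standard_normal(n))
        if dm.apply_z:
            eff_g1 = t_g1 + z
            eff_s = t_s + z
        else:
            eff_g1, eff_s = t_g1, t_s
        rates = GrowthRates.from_durations(eff_g1, eff_s, pp.f_g1,
                                           t_g1_d, t_s_d)
        td_all = _pad_death_times(c0, rates, m, dm.p, dm.pad,
                                  variant=dm.variant)
        t_death[dies] = td_all[dies]
    else:
        raise TypeError(f"unknown death model {dm!r}")

    if config.snap_to_grid:
        dt = config.frame_interval
        d = _snap(d, dt)
        rem_cur = _snap(rem_cur, dt)
        division = _snap(division, dt)
        t_death = np.where(np.isfinite(t_death), _snap(t_death, dt), t_death)

    post = config.post_obs
    rows = []
    next_child = n
    for i in range(n):
        phase = G1 if in_g1[i] else SG2M
        td = t_death[i]
        died_in_phase = td < rem_cur[i]
        row = dict.fromkeys(TRACK_COLUMNS, None)
        row.update(cell_id=i, parent_id=None, phase_at_trail=phase,
                   d_h=float(d[i]), c0_true=float(c0[i]),
                   phase_end_censored=False, division_censored=False,
                   death_censored=False)
        if died_in_phase:
            row["phase_end_h"] = None
            row["phase_end_censored"] = True
            row["division_censored"] = True
            if td <= post:
                row["death_h"] = float(td)
                row["fate"] = "apoptotic"
            else:
                row["death_censored"] = True
                row["fate"] = "censored"
        else:
            # phase completed (possibly censored by movie end)
            if rem_cur[i] <= post:
                row["phase_end_h"] = float(rem_cur[i])
            else:
                row["phase_end_censored"] = True
            if division[i] <= post and not (td < division[i]):
                row["division_h"] = float(division[i])
            elif td >= division[i]:
                row["division_censored"] = division[i] > post
            if np.isinf(td):
                row["fate"] = "survivor"
                if division[i] > post:
                    row["division_censored"] = True
            elif td < division[i]:
                # died after phase end but before division (only possible
                # for G1-treated cells, in S/G2/M of the same generation)
                row["division_censored"] = True
                if td <= post:
                    row["death_h"] = float(td)
                    row["fate"] = "apoptotic"
                else:
                    row["death_censored"] = True
                    row["fate"] = "censored"
            else:
                # death after division: sibling cells die synchronously;
                # count_once records a single death event for the pair
                if td <= post:
                    row["death_h"] = float(td)
                    row["fate"] = "apoptotic"
                    if config.sibling_mode == "keep_both":
                        sib = dict(row)
                        sib["cell_id"] = next_child
                        sib["parent_id"] = i
                        next_child += 1
                        rows.append(sib)
                else:
                    row["death_censored"] = True
                    row["fate"] = "censored"
        rows.append(row)

    table = pd.DataFrame(rows, columns=TRACK_COLUMNS)

    # a small fraction of divided survivors lose one daughter ("mixed")
    if config.mixed_fraction > 0:
        cand = table.index[(table["fate"] == "survivor")
                           & table["division_h"].notna()]
        pick = cand[rng.random(len(cand)) < config.mixed_fraction]
        if len(pick):
            extra = np.exp(rng.normal(1.0, 0.39, size=len(pick)))
            tdm = table.loc[pick, "division_h"].to_numpy() + extra
            if config.snap_to_grid:
                tdm = _snap(tdm, config.frame_interval)
            obs = tdm <= post
            table.loc[pick, "fate"] = "mixed"
            table.loc[pick[obs], "death_h"] = tdm[obs]
            table.loc[pick[~obs], "death_censored"] = True
    return table


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def validate_tracks(table: pd.DataFrame) -> None:
    """Raise ValueError naming the offending row on invariant violations."""
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    for idx, row in table.iterrows():
        if pd.isna(row["d_h"]) or row["d_h"] < 0:
            raise ValueError(f"row {idx}: d_h must be >= 0")
        if row["phase_at_trail"] not in (G1, SG2M):
            raise ValueError(f"row {idx}: unknown phase {row['phase_at_trail']!r}")
        if row["fate"] not in FATES:
            raise ValueError(f"row {idx}: unknown fate {row['fate']!r}")
        if row["fate"] == "apoptotic" and pd.isna(row["death_h"]):
            raise ValueError(f"row {idx}: apoptotic cell without death time")
        if row["fate"] == "survivor" and not pd.isna(row["death_h"]):
            raise ValueError(f"row {idx}: survivor with death time")


def write_tracks(table: pd.DataFrame, path) -> None:
    validate_tracks(table)
    out = table.copy()
    for c in ("phase_end_censored", "division_censored", "death_censored"):
        out[c] = out[c].astype(bool)
    out.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={"phase_at_trail": str, "fate": str},
    )
    if len(table) == 0:
        return pd.DataFrame({c: [] for c in TRACK_COLUMNS},
                            columns=TRACK_COLUMNS)
    for c in ("phase_end_censored", "division_censored", "death_censored"):
        if table[c].dtype != bool:
            table[c] = table[c].astype(str).str.lower().isin(("true", "1"))
    for c in ("d_h", "phase_end_h", "division_h", "death_h", "c0_true"):
        table[c] = pd.to_numeric(table[c], errors="coerce")
    validate_tracks(table)
    return table


# ---------------------------------------------------------------------------
# summaries and extraction helpers
# ---------------------------------------------------------------------------

def summarize_population(table: pd.DataFrame) -> pd.DataFrame:
    """Counts, death fractions and death-time medians per (phase, fate)."""
    records = []
    for phase in (G1, SG2M):
        sub = table[table["phase_at_trail"] == phase]
        n_phase = len(sub)
        n_apo = int((sub["fate"] == "apoptotic").sum())
        for fate in FATES:
            grp = sub[sub["fate"] == fate]
            deaths = grp["death_h"].dropna()
            records.append({
                "phase": phase, "fate": fate, "n": len(grp),
                "death_fraction": n_apo / n_phase if n_phase else 0.0,
                "median_death_h": float(deaths.median()) if len(deaths) else np.nan,
                "iqr_death_h": float(deaths.quantile(0.75) - deaths.quantile(0.25))
                               if len(deaths) else np.nan,
            })
    return pd.DataFrame(records)


def extract_phase_pairs(table: pd.DataFrame, phase: str):
    """(d, p) pairs of cells that completed the treated phase uncensored.

    p is the total phase length: time in phase before treatment plus the
    observed post-treatment time to phase end.
    """
    sub = table[(table["phase_at_trail"] == phase)
                & table["phase_end_h"].notna()
                & ~table["phase_end_censored"].astype(bool)]
    d = sub["d_h"].to_numpy(float)
    p = d + sub["phase_end_h"].to_numpy(float)
    return d, p


def extract_death_times(table: pd.DataFrame, phase: str = None):
    """Uncensored death times (optionally restricted to a treated phase)."""
    sub = table if phase is None else table[table["phase_at_trail"] == phase]
    sub = sub[(sub["fate"] == "apoptotic") & sub["death_h"].notna()]
    return sub["death_h"].to_numpy(float)


def surviving_fraction(table: pd.DataFrame, phase: str) -> float:
    """Fraction of phase-treated cells with known fate that survived."""
    sub = table[table["phase_at_trail"] == phase]
    n_s = int((sub["fate"] == "survivor").sum())
    n_a = int((sub["fate"] == "apoptotic").sum())
    if n_s + n_a == 0:
        raise ValueError(f"no cells with known fate in phase {phase}")
    return n_s / (n_s + n_a)
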