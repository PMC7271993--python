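"""End-to-end analysis pipeline.

Runs the full workflow on a track table (simulated or loaded): phase
characterization (censored fits, BIC ranking, correlations, death-time
statistics), survivor-bias quantification, prolongation (z) estimation
per phase, cycle-position estimation, PAD fitting on the resulting
(c0, t_death) tuples, and a synchronization sweep.  A single master
seed deterministically derives all per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cycle_model import G1, SG2M, PhaseParams
from . import synthetic_data as sd
from .synthetic_data import ExperimentConfig, generate_population
from .phase_fitting import (CensoredSample, bic_rank,
                            proportion_difference, rank_sum_test)
from .survivor_bias import DeathTimeParams, simulate_uncensored_phase_lengths
from .trail_prolongation import ZProlongationEstimator
from .position_estimation import CyclePositionEstimator, fate_vs_position_test
from .apoptosis_kinetics import ApoptosisParams, PADEstimator, synchronization_sweep

logger = logging.getLogger(__name__)

#: printed parameterizations of the two characterized cell lines
CELL_LINE_PRESETS = {
    "NCI-H460": {
        "phase_params": PhaseParams(1.96, 0.27, 2.18, 0.19, f_g1=0.45),
        "pad_variant": "release_at_division",
    },
    "HCT-116": {
        "phase_params": PhaseParams(1.87, 0.34, 2.34, 0.22, f_g1=0.39),
        "pad_variant": "extended_second_generation",
    },
}


def preset_phase_params(cell_line: str,
                        duration_corr: float = sd.DEFAULT_DURATION_CORR) -> PhaseParams:
    pp = CELL_LINE_PRESETS[cell_line]["phase_params"]
    return pp.with_duration_corr(duration_corr)


@dataclass
class PipelineConfig:
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    cell_line_preset: str = "NCI-H460"
    seed: int = 0
    output_dir: Optional[str] = None
    # z estimation
    z_max: float = 8.0
    z_step: float = 0.2
    z_reps: int = 3
    z_cohort: int = 20_000
    # PAD estimation
    p_grid_step: float = 0.04
    pad_grid_step: float = 0.05
    pad_reps: int = 3
    pad_cohort: int = 10_000
    # synchronization sweep
    sync_n: int = 2000

    def __post_init__(self):
        if self.cell_line_preset not in CELL_LINE_PRESETS and \
                self.cell_line_preset != "custom":
            raise ValueError(f"unknown preset {self.cell_line_preset!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: PipelineConfig, tracks: pd.DataFrame = None) -> dict:
    """Execute all stages; returns a JSON-serializable report bundle."""
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ("simulate", "survivor_bias", "z", "positions", "pad", "sync"),
        ss.spawn(6))}
    if config.cell_line_preset != "custom":
        pp = preset_phase_params(config.cell_line_preset)
        variant = CELL_LINE_PRESETS[config.cell_line_preset]["pad_variant"]
    else:
        pp = config.experiment.phase_params
        variant = "release_at_division"

    report = {"config": {"cell_line_preset": config.cell_line_preset,
                         "seed": config.seed,
                         "n_cells": config.experiment.n_cells,
                         "z_true": config.experiment.z_true,
                         "pad_variant": variant}}

    # --- stage 1: tracks ---------------------------------------------------
    if tracks is None:
        exp = config.experiment
        if exp.phase_params != pp:
            from dataclasses import replace
            exp = replace(exp, phase_params=pp)
        tracks = generate_population(exp, seeds["simulate"])
        logger.info("simulated %d tracks", len(tracks))
    report["summary"] = sd.summarize_population(tracks).to_dict("records")

    # --- stage 2: phase characterization ------------------------------------
    fits = {}
    for phase in (G1, SG2M):
        d, p = sd.extract_phase_pairs(tracks, phase)
        if p.size >= 10:
            sample = CensoredSample(p)
            fits[phase] = [
                {"family": f.family, "params": f.params, "loglik": f.loglik,
                 "bic": f.bic, "delta_bic": f.delta_bic}
                for f in bic_rank(sample)]
    report["phase_fits"] = fits
    g1_deaths = sd.extract_death_times(tracks, G1)
    s_deaths = sd.extract_death_times(tracks, SG2M)
    stats_block = {}
    if g1_deaths.size and s_deaths.size:
        stats_block["median_t_death_g1"] = float(np.median(g1_deaths))
        stats_block["median_t_death_sg2m"] = float(np.median(s_deaths))
        stats_block["rank_sum_p"] = rank_sum_test(g1_deaths, s_deaths)
    g1_all = tracks[tracks["phase_at_trail"] == G1]
    s_all = tracks[tracks["phase_at_trail"] == SG2M]
    if len(g1_all) and len(s_all):
        stats_block["death_probability"] = proportion_difference(
            int((g1_all["fate"] == "apoptotic").sum()), len(g1_all),
            int((s_all["fate"] == "apoptotic").sum()), len(s_all))
    report["death_statistics"] = stats_block

    # --- stage 3: survivor bias ---------------------------------------------
    dtp = DeathTimeParams()
    bias = {}
    for phase in (G1, SG2M):
        retained = simulate_uncensored_phase_lengths(
            phase, pp, dtp, 50_000, seeds["survivor_bias"])
        mu, sigma = pp.log_params(phase)
        bias[phase] = float(np.exp(mu + 0.5 * sigma ** 2) - retained.mean())
    report["survivor_bias_h"] = bias

    # --- stage 4: z estimation ----------------------------------------------
    z_hats = {}
    z_block = {}
    for phase in (G1, SG2M):
        try:
            est = ZProlongationEstimator(
                phase=phase, phase_params=pp, z_max=config.z_max,
                z_step=config.z_step, n_reps=config.z_reps,
                cohort_size=config.z_cohort,
                random_state=seeds["z"]).fit(tracks)
        except ValueError as exc:
            logger.warning("z estimation skipped for %s: %s", phase, exc)
            continue
        z_hats[phase] = est.z_hat_
        z_block[phase] = {"z_hat": est.z_hat_, "ci": list(est.ci_),
                          "n_pairs": est.n_pairs_,
                          "on_boundary": est.estimate_.on_boundary}
    report["z_estimates"] = z_block

    # --- stage 5: positions and fate association ----------------------------
    pos = CyclePositionEstimator(
        z_hat={G1: z_hats.get(G1, 0.0), SG2M: z_hats.get(SG2M, 0.0)},
        phase_params=pp, m_resamples=300,
        random_state=seeds["positions"]).fit(tracks).transform(tracks)
    report["fate_vs_position"] = fate_vs_position_test(pos)

    # --- stage 6: PAD fit ----------------------------------------------------
    tuples = pos[(pos["fate"] == "apoptotic") & pos["c0_hat"].notna()
                 & pos["death_h"].notna()]
    if len(tuples) >= 50:
        pad_est = PADEstimator(
            phase_params=pp,
            p_grid=np.arange(0.0, 0.401, config.p_grid_step),
            pad_grid=np.arange(0.3, 0.901, config.pad_grid_step),
            n_reps=config.pad_reps, cohort_size=config.pad_cohort,
            variant=variant, horizon=config.experiment.post_obs,
            random_state=seeds["pad"]).fit(tuples)
        report["pad_estimate"] = {
            "p_hat": pad_est.p_hat_, "pad_hat": pad_est.pad_hat_,
            "ci_p": list(pad_est.ci_p_), "ci_pad": list(pad_est.ci_pad_),
            "n_tuples": pad_est.n_tuples_,
            "on_boundary": pad_est.estimate_.on_boundary}
        pad_params = ApoptosisParams(p=pad_est.p_hat_, pad=pad_est.pad_hat_,
                                     variant=variant)
    else:
        logger.warning("too few (c0, t_death) tuples for PAD fitting")
        pad_params = ApoptosisParams(variant=variant)
        report["pad_estimate"] = None

    # --- stage 7: synchronization sweep --------------------------------------
    windows = [(0.1 * k, 0.1 * (k + 1)) for k in range(10)]
    sweep = synchronization_sweep(windows, pp, seeds["sync"],
                                  params=pad_params,
                                  n_per_window=config.sync_n,
                                  horizon=config.experiment.post_obs,
                                  z_g1=z_hats.get(G1, 0.0),
                                  z_s=z_hats.get(SG2M, 0.0))
    report["synchronization"] = sweep.to_dict("records")

    report = _jsonable(report)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        sd.write_tracks(pos, outdir / "tracks_with_positions.csv")
        sweep.to_csv(outdir / "synchronization.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def report_text(report: dict) -> str:
    """Human-readable summary of a pipeline report bundle."""
    lines = ["trailcycle pipeline report", "=" * 26]
    if not report:
        return "\n".join(lines + ["(empty report)"])
    cfg = report.get("config", {})
    lines.append(f"preset: {cfg.get('cell_line_preset')}  "
                 f"seed: {cfg.get('seed')}  n_cells: {cfg.get('n_cells')}")
    for phase, block in (report.get("z_estimates") or {}).items():
        lines.append(f"z_hat[{phase}] = {block['z_hat']:.2f} h "
                     f"(95% CI {block['ci'][0]:.2f}-{block['ci'][1]:.2f})")
    pad = report.get("pad_estimate")
    if pad:
        lines.append(f"PAD fit: p = {pad['p_hat']:.3f} 1/h, "
                     f"PAD = {pad['pad_hat']:.2f} "
                     f"(CI {pad['ci_pad'][0]:.2f}-{pad['ci_pad'][1]:.2f})")
    ds = report.get("death_statistics", {})
    if "median_t_death_g1" in ds:
        lines.append(f"median t_death: G1 {ds['median_t_death_g1']:.2f} h, "
                     f"S/G2/M {ds['median_t_death_sg2m']:.2f} h "
                     f"(rank-sum p = {ds['rank_sum_p']:.2e})")
    return "\n".join(lines)
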