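# trailcycle

Sampling-based modeling of the bidirectional interplay between
cell-cycle progression and TRAIL-induced extrinsic apoptosis in
single-cell time-lapse data.

## The problem

Long-term time-lapse microscopy of Fucci/geminin reporter cells yields,
per tracked cell, the phase it occupied when a TRAIL receptor agonist
was added (G1 or S/G2/M), the time `d` it had already spent in that
phase, and either the completion time of the phase or the time from
exposure to apoptosis (`t_death`) — each possibly right-censored by the
movie end. Two questions are entangled in such data: does TRAIL slow
cycle progression, and does cycle position shape death timing and fate?
Naive phase-length comparisons are confounded by survivorship bias
(cells with long phases die before completing them), and the cycle
position at exposure is never observed directly.

`trailcycle` addresses both with a common modeling core. The cell cycle
is a coordinate `C ∈ [0, 1)` (G1 = `[0, 0.45)`, S/G2/M = `[0.45, 1)`,
division at 1) traversed at cell-specific rates `g = f/T`, with
lognormal phase durations `T` and steady-state initial positions
`F(C₀) = 2^(1−C₀) ln 2`. On top of it:

- **Censored distribution fitting** — maximum likelihood for
  lognormal/gamma/weibull/normal under right-censoring, ranked by BIC,
  plus Pearson/rank-sum/proportion statistics.
- **Survivorship-bias quantification** — Monte Carlo over
  `(C₀, T, t_death)` gives the expected shortening of retained phase
  lengths and the mixture reference distribution for treated
  populations.
- **Prolongation estimation** — TRAIL stretches a phase by `z` hours
  (corrected rate `g* = f/(f/g + z)`); `z` is estimated by scoring
  observed `(d, p)` pairs against large virtual cohorts across a `z`
  grid (binned lognormal likelihood, degree-5 polynomial smoothing,
  χ²-based confidence interval).
- **Position estimation** — each cell's `Ĉ₀` from truncated resampling
  of the control duration distribution (cells dying in phase) or by
  inverting the prolongation model (phase completers).
- **PAD model** — apoptosis progression `A(t)` rises at a per-cell
  slope `m` (reciprocal lognormal, mean 0.4 /h) and is decelerated by
  `p` while `C` lies beyond the Point of Apoptosis Deceleration (PAD),
  released at division; `(p, PAD)` are fitted on a grid via a bivariate
  KDE likelihood over `(C₀, t_death)` with χ² confidence regions.
- **Synthetic data** — a first-class generator of virtual track tables
  with the full experimental structure (19 h pre-observation, treatment
  at t = 0, 19.25 h follow-up, 15-min frames, phase-specific death
  probabilities, sibling-death handling, movie-end censoring).

Estimation components follow scikit-learn conventions
(`ZProlongationEstimator`, `PADEstimator`, `CyclePositionEstimator`,
`CensoredDurationFitter` with `fit`/`transform`, `get_params`, fitted
`*_` attributes).

## Worked example

```python
from trailcycle import (ExperimentConfig, generate_population,
                        ZProlongationEstimator, PADEstimator,
                        CyclePositionEstimator, PhaseParams)

pp = PhaseParams(1.96, 0.27, 2.18, 0.19, f_g1=0.45).with_duration_corr(0.33)
tracks = generate_population(
    ExperimentConfig(n_cells=5000, z_true=3.6, phase_params=pp, seed=201))

z = ZProlongationEstimator(phase="G1", phase_params=pp,
                           n_reps=6, cohort_size=100_000,
                           random_state=202).fit(tracks)
print(f"z_hat = {z.z_hat_:.2f} h, 95% CI ({z.ci_[0]:.2f}, {z.ci_[1]:.2f})")
```

Output:

```
z_hat = 3.57 h, 95% CI (3.35, 3.80)
```

The population was simulated with a true prolongation of 3.6 h; the
sampling-based estimator recovers it from the 1182 completed-phase
`(d, p)` pairs, with a confidence interval width comparable to the
3–4.3 h scale seen in experimental data. Appending `Ĉ₀` positions and
fitting the PAD model continues the same way:

```python
pos = CyclePositionEstimator(z_hat=3.6, phase_params=pp,
                             random_state=0).fit(tracks).transform(tracks)
pad = PADEstimator(phase_params=pp, n_reps=4, cohort_size=20_000,
                   horizon=19.25, random_state=1).fit(pos)
print(pad.p_hat_, pad.pad_hat_)
```

A full pipeline (`simulate → fit-phases → survivor-bias → estimate-z →
positions → fit-pad → synchronize`) is available programmatically via
`trailcycle.run_pipeline` and from the shell:

```bash
trailcycle simulate --n-cells 2000 --z-true 3.6 --seed 1 --out tracks.csv
trailcycle estimate-z --tracks tracks.csv --phase G1 --seed 2
trailcycle run-all --out-dir results/ --seed 3
```

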