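# Methods

## Cycle coordinate and population model

A cell's position in the cycle is a coordinate `C` on `[0, 2)`:
`[0, f_g1)` is G1, `[f_g1, 1)` is S/G2/M (`f_g1 = 0.45` for the
NCI-H460 parameterization, `0.39` for HCT-116), division occurs exactly
at `C = 1`, and `[1, 2)` repeats the layout for the daughter
generation. Within a phase the coordinate moves at the constant rate
`g = f/T`, where the phase duration `T` is lognormal:
`ln T_G1 ~ N(mu_G1, sigma_G1²)`, `ln T_SG2M ~ N(mu_S, sigma_S²)`. The
two log-durations of a cell are coupled through a bivariate normal
whose correlation defaults to the value that produces a duration-scale
Pearson correlation of 0.33 (`rho_log ≈ 0.336` for the NCI-H460
sigmas), matching the weak phase coupling observed in control
populations. Daughter-generation durations are resampled independently;
mother–daughter inheritance is out of scope.

In an unsynchronized, exponentially growing population the initial
coordinate has density `F(C0) = 2^(1-C0) ln 2` on `[0, 1)` (younger
cells are over-represented because every division creates two of them).
Sampling uses the closed-form inverse CDF `C0 = 1 - log2(2 - u)`;
restriction to a phase or window renormalizes the same density on the
subinterval. Uniform sampling is available for estimator-validation
studies and synchronization windows.

Phase intervals are half-open (`[0, 0.45)`, `[0.45, 1)`) so every
coordinate belongs to exactly one phase; division happens at exactly 1.

## TRAIL-induced prolongation

TRAIL slows cycle progression. Phenomenologically a phase of native
duration `T` behaves as if it lasted `T + z` hours, i.e. the rate
becomes `g* = f/(f/g + z)`. Two conventions relate an exposure at time
`d` into the phase to the total observed length `p`:

- `post_exposure` (default): progress before exposure at the native
  rate, after it at the corrected rate, giving `p = T + z - d·z/T`.
  This is strictly decreasing in `d` for fixed `T`, which is exactly
  the negative trend of phase length versus exposure time seen in
  treated cells — the physical reading is that only post-exposure
  progression can be decelerated.
- `whole_phase`: `p = T + z` regardless of `d`, kept as a config
  option.

The inverse map (needed by the position estimator) solves
`T² + (z - p)T - d·z = 0` for its positive root in `post_exposure`
mode and is `T = p - z` in `whole_phase` mode. Results are clipped to
`T > d` — the cell demonstrably spent `d` hours in the phase — and
degenerate `whole_phase` inputs (`p ≤ z + d`) return `T = d(1+1e-6)`
with a flag, keeping the estimator total. Whether the prolongation also
applies to phases entered after exposure (including the daughter
generation) is not identifiable from one-generation tracks; the
generator applies it to all progression while TRAIL is present.

All times are continuous reals; snapping to the 15-minute imaging grid
happens only in the data generator.

## Synthetic track tables

The generator emulates the time-lapse design: ~19 h pre-treatment
observation (so `d` is known), treatment at `t = 0`, 19.25 h
post-treatment follow-up, 15-min frames. Per cell it samples `C0`
(steady state by default), correlated durations for both generations,
assigns a fate by phase-specific death probability (defaults 0.76 in
G1, 0.72 in S/G2/M), draws a death time from either a direct lognormal
(default `mu_d = 1, sigma_d = 0.39`, the early-G1 calibration) or the
PAD model, advances phases under the configured prolongation, censors
events beyond the movie end and snaps event times to the frame grid.
Sibling deaths after division are synchronous; in the default
`count_once` mode one death event is recorded per pair so first-
generation deaths are not double-weighted (`keep_both` emits duplicate
daughter rows instead). A small configurable fraction of divided
survivors (default 3%) is relabeled "mixed" (one daughter died) so that
fate-handling code paths are exercised; mixed cells are excluded from
PAD fitting.

What the generator does *not* emulate: segmentation/tracking errors,
fluorescence intensity noise, interval censoring at frame resolution
(events are snapped, not binned into observation intervals),
mother–daughter duration correlation, and density-dependent effects.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated statistical model, not robustness
to every artifact of real microscopy data.

## Censored fitting and descriptive statistics

Phase lengths not fully observed enter the likelihood through the
survival function: `log L = Σ_obs log pdf + Σ_cens log(1 - CDF)`.
Four families (lognormal, gamma, weibull, normal) are fitted by
Nelder-Mead on unconstrained parameterizations and ranked by
`BIC = k ln n - 2 log L`; a difference above 2 is taken as positive
evidence. The parameter count defaults to 2 for every family, with an
override so alternative counting conventions can be reproduced.
Pearson correlations carry Fisher-z 95% intervals; group comparisons
use the two-sided Wilcoxon rank-sum test. For proportion differences
two labeled criteria are reported side by side — the standard pooled
two-proportion z-test and a margin-of-error criterion
`|p1 - p2| > 1.96·sqrt(p̄(1-p̄)/(n1+n2))` — because they use different
null standard errors and can disagree (the margin criterion is the more
permissive at these sample sizes); neither is silently preferred.
No outlier removal is applied by default.

## Survivorship bias

Cells that die before completing their phase are missing from measured
phase lengths, biasing the retained distribution short. The bias is
quantified by drawing `(C0, T, t_death)` (position restricted to the
phase via the renormalized steady-state density, duration from the
phase marginal, death time lognormal) and retaining cells whose death
time exceeds their remaining time in phase. With the early-G1
death-time calibration (`mu_d = 1, sigma_d = 0.39` — the only printed
death-time parameterization, used as default) the retained G1 mean is
about 0.5 h short of the control mean and S/G2/M about 0.3 h; the bias
grows monotonically as deaths get faster (smaller `mu_d`) and vanishes
as deaths become late. Mixture references for treated-vs-control
comparisons combine never-dying cells (native durations) and
apoptotic-but-completing cells (biased durations) at the observed
surviving fraction, with a lognormal fitted to the mixture.

## Prolongation (z) estimation

For each candidate `z` on a grid (default 0–8 h, step 0.2 h) a virtual
cohort is built: steady-state positions in the phase, native durations,
death times resampled from the observed death times of that phase's
apoptotic cells, survivors added at the observed surviving fraction,
and cells dying before their (z-prolonged) phase end discarded —
mirroring the experimental selection. Experimental `d` values are
binned at the frame interval (0.25 h; observed `d` values are frame
multiples anyway); per bin a lognormal is fitted to the cohort's `p`
values (log-moment MLE) and the experimental `p` values are scored; the
grand negative log-likelihood sum is averaged over repetitions
(default 6) of independent cohorts. Bins with fewer than 10 virtual
cells widen symmetrically until supported, so no bin contributes an
infinite score. A degree-5 polynomial is fitted to the mean curve; its
minimizer is `ẑ` and the 95% CI is the profile-likelihood region
`negll ≤ min + 1.92` (χ², 1 df). A minimizer on the grid boundary is
flagged as unbracketed. Censored phase lengths are excluded (completed
phases only). Default cohort size is 10⁵ per grid point — the
estimator's Monte Carlo error at this size is already far below the CI
width, so desk-scale cohorts replace the much larger sampling runs a
cluster would permit.

## Position estimation

Three strategies produce `Ĉ0`:

- dying-in-phase cells: `Ĉ0 = start + f · mean(d/p_u)` over
  `m = 1000` draws `p_u` from the control phase-length distribution
  truncated below at `d` (the cell's duration was at least `d`);
  `m` is chosen so the resampling error is well below the
  frame-resolution uncertainty;
- phase completers (`hybrid_I`): invert the prolongation model at `ẑ`
  to recover `T`, then `Ĉ0 = start + f·d/T`;
- `truncated_II` applies truncated resampling to everyone,
  `untruncated_III` normalizes by unconditioned control draws; both are
  retained as the baselines the hybrid estimator is validated against
  (their error is strictly larger on virtual populations with known
  positions, at every prolongation level tested).

Estimates are clipped into the treated phase's interval. Cells censored
by the movie end before completing the phase or dying have no
applicable branch and are excluded from position-dependent analyses.
Fate association compares `Ĉ0` between apoptotic and surviving cells
per phase with the rank-sum test.

## PAD model and estimation

Apoptosis progression `A(t)` starts at 0, rises at a per-cell slope
`m` (the reciprocal of a lognormal(1, 0.39) draw; population mean
0.4 /h, matching a 2.9 h mean early-G1 death time), and the cell dies
when `A = 1`. While the cycle coordinate lies in `(PAD, 1]` the slope
is `m - p`; `A` is floored at 0, so cells with `m < p` stall until the
deceleration is released at division (`release_at_division`). The
`extended_second_generation` variant re-applies the deceleration on
`(PAD+1, 2]`, the parameterization used for HCT-116. Death times are
computed in closed form by walking the breakpoints where either the
motion rate or the `A` slope changes; a forward-Euler integrator serves
as test oracle. Beyond the tabulated generations `A` rises at `m`.

`(p, PAD)` are estimated on a grid (defaults `p ∈ [0, 0.4]` step 0.01,
`PAD ∈ [0.3, 0.9]` step 0.01) by evaluating experimental
`(Ĉ0, t_death)` tuples against a bivariate Gaussian KDE of model
cohorts, with densities floored at 1e-9 to avoid rounding-driven
infinities. The KDE bandwidth is Silverman's rule on the cohort
covariance; the evaluation truncates kernels beyond six marginal
bandwidths in the `C0` direction (relative error below `e^-18`,
verified against `scipy.stats.gaussian_kde` in the tests). Per
repetition one cohort base (positions, rates, slopes) is drawn and
reused across the entire grid — common random numbers, so surface
differences between neighboring grid points reflect the parameters
rather than resampling noise — and the surface is averaged over
repetitions. The best point is the surface argmin; the 95% joint region
is `negll - min ≤ χ²₂,0.95/2 = 2.996` and per-parameter intervals come
from profiling at `χ²₁,0.95/2 = 1.921`. Cohort positions default to the
steady-state density (matching an unsynchronized treated population);
the cycle prolongation `z` is not applied inside PAD cohorts by
default, consistent with treating the death model on native rates, and
the data generator exposes a flag to turn it on. Model cohorts exclude
cells without death inside the observation horizon, as the experimental
tuples do. With `p* = 0` the deceleration point is structurally
unidentifiable and the confidence region correctly spans the full PAD
grid at `p ≈ 0`.

A null-model comparison (cycle-independent lognormal/gamma/weibull/
normal fitted to the pooled death times, ranked by BIC) is available
through the censored-fitting module.

## Synchronization sweep

For windows `C0 ∈ (a, b)` the sweep samples positions uniformly in the
window and simulates PAD death times. Because a synchronization
experiment exposes cells to TRAIL for their entire subsequent
progression, the coordinate moves at the corrected rates for the fitted
per-phase prolongations (defaults `z_G1 = 3.6 h`, `z_SG2M = 3.4 h`;
set to 0 for native progression). Reported per window: median and IQR
of death times observed within the horizon, the fraction of cells
dividing before death, and the fraction surviving the horizon. At the
fitted scale (`p = 0.2 /h`, `PAD = 0.52`) the first three windows give
the fastest deaths, and the 50–70% windows the slowest and most
variable — the bimodal split of cells just below PAD into fast deaths
and post-mitotic delayed deaths drives the variance.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and the acceptance script were
chosen so every stochastic check has Monte Carlo error well inside its
assertion band on a single CPU: duration/death calibrations at 10⁶
draws, survivor-bias runs at 1.2–3×10⁵, z recovery with 5000-cell
track tables, 10⁵-cell cohorts and 6 repetitions, PAD recovery with
900 tuples, 2×10⁴-cell cohorts, 4 repetitions and 0.02-step grids, and
6000 cells per synchronization window. Optimizer: Nelder-Mead with
tight tolerances on unconstrained parameterizations; lognormal per-bin
fits use closed-form log moments with a 1e-3 sigma floor. Ties and
degenerate inputs (empty bins, all-censored samples, zero-variance
cohorts, truncation beyond numerical support) raise or widen explicitly
rather than returning silent infinities.

## Known limitations

Single-generation lineage structure only (one division tracked);
prolongation `z` is constant in time and per phase rather than jointly
estimated; point estimates of `C0` (no posterior uncertainty); the
deceleration is a step function of the coordinate, not a continuous
profile; the pipeline recomputes every stage on each run (no stage
caching, which keeps the orchestration simple at the cost of redundant
work when only late stages change).
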