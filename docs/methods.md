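# Methods

This note documents the models implemented in `circatiming`, the defaults
and the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Pacemaker-accumulator core (`circatiming.clock`)

The mechanistic account is verbal in the literature; this package commits
to one concrete algebraic composition:

```
rate(t)   = r_ref · [1 + h_amp·(1 − exp(−t⁺/τ_h)) + c_amp·cos(2π/period·(t − c_phase))]
gain(d)   = exp(−κ·d)
R_eff     = r_ref + gain(d)·(rate(t) − r_ref)
estimate  = d·R_eff/r_ref        production = d·r_ref/R_eff
```

with `t` in hours from DLMO, `t⁺ = max(t − t_wake_offset, 0)`, `d` the
stimulus duration in seconds. Design choices, made where the mechanism is
verbally specified but algebraically open:

* **Additive modulation.** Homeostatic and circadian terms add on a
  dimensionless scale around `r_ref`, mirroring the additive fixed-effects
  structure of the trajectory model that the data analysis fits.
* **Exponential leakage gain.** Only monotone-increasing pulse loss with
  duration is demanded by the attentional account; `exp(−κd)` is the
  simplest one-parameter form with `gain(0)=1`.
* **Leakage acts on the rate deviation**, not the absolute rate, so an
  unmodulated clock is veridical at every duration and leakage produces
  duration-specific *trajectories* rather than duration-specific baselines.
* **Homeostatic time origin.** Time is measured from DLMO throughout; the
  homeostatic term is clamped at its onset value before `t_wake_offset`
  (default 0, i.e. buildup from DLMO-referenced time zero). The offset is
  configurable for protocols where wake onset and DLMO are far apart.
* A time-varying κ (circadian/homeostatic modulation of attention itself)
  is deliberately not defaulted; the observed stimulus-by-cosine phase
  shift hints at it, but no claim is built in.

Exact invariants (tested to machine precision): `estimate·production = d²`;
the ratio identities; gain monotonicity; 24-h periodicity of the circadian
term; the widening 10-s vs 40-s estimation gap under positive κ and a
rising rate.

## Synthetic cohorts (`circatiming.cohort`)

The generator reproduces the study geometry: 18 subjects × 2 constant
routines of 38.67 h × 20 two-hourly occasions (t = 0, 2, …, 38 h; the
38.67-h window admits exactly 20 points) × {estimation, production} ×
{10 s, 40 s} × 3 trials, plus hourly melatonin (39 samples per epoch).

* **LMM backend** draws occasion outcomes directly from the trajectory
  model: `y = Xβ + Zb_i + ε`, default β = the reference coefficient set,
  random-effect SDs (10, 5, 5) ratio units (uncorrelated by default),
  residual SDs by cell (production/10 s: 8, production/40 s: 10,
  estimation/10 s: 12, estimation/40 s: 15). The original analysis reports
  that between-subject and between-cell heterogeneity was significant but
  not its magnitudes; these defaults were chosen once to span a visually
  plausible spread of subject trajectories and are overridable.
* **Mechanistic backend** drives trial responses through the clock core
  with subject-perturbed modulation parameters (SDs 0.05/0.02/1.0 h for
  `h_amp`/`c_amp`/`c_phase`; invalid draws are rejected, redrawn and
  counted). Trial noise is lognormal on the response so responses stay
  positive; per-cell ratio-scale SDs map to log-SDs via /100. Population
  defaults `h_amp=0.15, c_amp=0.05, c_phase=16 h, κ=0.01/s` give ratio
  excursions of roughly ±10 units, comparable to the fitted trajectories.
* **Melatonin** is `10 + 8·cos(2π(t − (DLMO+6))/24)` pg/ml — a nocturnal
  peak 6 h after DLMO whose upward mesor crossing is the DLMO itself —
  with optional multiplicative lognormal noise, floored at the 2.8 pg/ml
  assay sensitivity. True DLMOs are drawn N(14, 1²) h after CR start
  (≈22:00 for an 08:00 start). This is a smooth idealisation: real
  profiles are pulsatile and asymmetric, so DLMO-recovery results here
  bound cosinor behaviour under well-behaved rhythms only.

What passing tests therefore show: the estimator recovers truth under the
model's own assumptions (correct likelihood, correct design, calibrated
tests). What they do not show: robustness to assay pulsatility, missing
data, non-Gaussian outcomes or subject non-compliance, none of which the
generator emulates.

## DLMO estimation (`circatiming.dlmo`)

Per subject-epoch, concentrations are z-scored, the linear model
`z(t) = M + a·cos(2πt/24) + b·sin(2πt/24) + c·cos(2πt/12) + d·sin(2πt/12)`
is solved by least squares, amplitudes/acrophases are derived via
`A·cos(ωt−P) = s·sin(ωt) + c·cos(ωt)`, and the fitted curve is
back-transformed (`mean + sd·z`) to pg/ml before thresholding — the
reading under which fitting on z-scores and thresholding at 10 pg/ml are
both literally true. The DLMO is the earliest upward 10 pg/ml crossing
within the observed span (no extrapolation) preceded by ≥1 h below
threshold, located on a 0.01-h grid and refined by bisection to ≤0.001 h.
A series with no qualifying crossing yields an explicit no-DLMO result
(`None`/NaN), distinct from fitting errors. Tested: exact recovery of pure
basis functions, agreement with an independent OLS solve, time-shift
equivariance, threshold monotonicity on a rising limb, and round-trip
recovery of generator truth (≤0.1 h noiseless, ≤0.25 h at default noise;
the small noiseless residual comes from the assay floor clipping the
profile trough).

## Preprocessing (`circatiming.preprocess`)

Occasion outcome = 100 × mean(trial responses)/target per
subject × epoch × occasion × task × stimulus cell (arithmetic mean; cells
may hold 1–3 trials). Outcomes ≥ 250 are removed before fitting. The
removal rule is applied to the ratio itself — the outcome is already
standardised to its target, so 250 means a response 2.5× its target; an
alternative within-cell z-score rule is selectable (`rule="zscore"`), as
the original wording ("standardized value") admits either reading.
Occasion clock times are re-referenced to each epoch's own DLMO; epochs
without a DLMO are dropped with a warning.

## Mixed-model engine (`circatiming.lmm`)

The 15-column fixed design uses treatment coding with **production**,
**10 s** and **CR1** as reference levels. The task reference was chosen by
checking the published coefficient pattern against the described
trajectories: with production as reference the fitted coefficients
reproduce a rising estimation trajectory (negative task-by-exponential
coefficient on the decaying `exp(−t/18.2)` basis) and a falling production
trajectory, as observed; the opposite coding inverts both. All sign
interpretations in docs and examples follow this coding.

Estimation maximises the profiled deviance over (i) the log-Cholesky
factor of the scaled random-effect covariance `G = Ψ/σ²` (6 parameters;
positive-definiteness holds by construction) and (ii) log residual-SD
multipliers for the non-reference task × stimulus cells (reference
multiplier ≡ 1; the reference cell is the alphabetically first group
label). At each iterate β is profiled out by GLS and σ² in closed form;
per-subject inverses of `V0_i = Z_i G Z_iᵀ + diag(w²)` use the Woodbury
identity, so one likelihood evaluation is O(n). The optimiser is L-BFGS-B
with numerical gradients (ftol 1e−12, gtol 1e−7) from two dispersed
starting points, with a Nelder-Mead polish on non-success; non-convergence
is flagged on the returned fit, never silent. The four-cell variance
structure nests the two-factor multiplicative reading ("different
variances by tasks and stimuli"); both are selectable
(`variance_groups="cell" | "task-stim" | "none"`).

Wald table: SEs from the GLS covariance `σ²(XᵀV0⁻¹X)⁻¹`; denominator df by
the containment rule `n_obs − n_subjects − p_within`, where `p_within`
counts fixed terms varying within subjects, the intercept included — under
the full design every term is within-subject, giving a single shared df,
consistent with the single-df reporting convention of the original
analysis. ML is used for likelihood-ratio comparison of fixed effects;
REML is available for final variance reporting. BLUPs
`b̂_i = Ψ Z_iᵀ V_i⁻¹ r̂_i` support subject-level prediction.

Verified against independent routes: a dense joint-Gaussian log-density
and closed-form GLS on ≤200-row instances (agreement ≤1e−6), and
statsmodels' MixedLM on the homoscedastic random-intercept reduction
(≤1e−4). The optimizer's stopping point is data-continuous to ~1e−4 in β,
which is why stage-file round-trips are compared at that tolerance rather
than machine precision.

## Model comparison (`circatiming.compare`)

The candidate ladder (constant, exponential-only, sinusoid-only,
sinusoid+exponential, equal exponentials across stimuli, full) is fitted
by ML with the random-effects and variance structure held fixed, matching
the sequencing in which fixed-effect form is selected first; LRT statistic
`2(ℓ_full − ℓ_reduced)` with χ² df = parameter-count difference. Negative
statistics beyond 1e−6 raise rather than being clipped silently. AIC uses
the full parameter count (fixed + variance parameters + σ²). The null
calibration suite (200 cohorts under a constant-trajectory truth,
random-intercept homoscedastic pair, df = 2) keeps the rejection rate
inside the binomial 95% band around 0.05; calibration runs use an
8-subject, 5-occasion design so that 400 fits complete in seconds — the
χ² reference is an asymptotic claim the small design already exercises.

## Recovery experiments and problem sizes

The headline experiment simulates 20 full-design cohorts (2880 occasion
outcomes each) from the reference coefficients and refits each by ML
(~1 s per fit). Reported per term: replicate mean, Monte-Carlo SE of the
mean, bias in MC-SE units (acceptance: ≤2 for the targeted terms), and
coverage of value ± 2·SE Wald intervals (acceptance: ≥0.85). Seeds are
spawned per replicate from a single `SeedSequence`, so results are
reproducible given one integer. Scaled-down designs used elsewhere in the
test suite (4–10 subjects, 4–8-h occasion spacing) were chosen as the
smallest instances that still exercise every code path — both constant
routines, all four cells, ≥2 occasions — while keeping the full suite
around a minute.

## Known limitations

* The mechanistic backend draws subject variation only in the modulation
  parameters; it has no subject-level response bias disjoint from the
  clock, so its fitted random-intercept SD is small by construction.
* The melatonin generator's single-harmonic shape makes the 12-h cosinor
  component nearly superfluous; it earns its place only on real,
  asymmetric profiles.
* Containment df is a convention; no Satterthwaite/Kenward-Roger
  correction is implemented (with ~2850 df the difference is immaterial).
* No missing-data handling beyond dropping epochs without a DLMO; no
  autocorrelated residuals, crossed random effects or non-Gaussian
  responses.
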