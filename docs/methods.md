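# Methods

## Movement model

The velocity of a swimming cell is modelled as a complex-valued
Ornstein–Uhlenbeck process: with V = vx + i·vy,

    dV = (iω − 1/τ)(V − μ) dt + white noise,

whose stationary law is circularly-symmetric Gaussian with mean μ and
total variance η². Parameters and units:

| parameter | meaning | units | typical value |
|---|---|---|---|
| τ | velocity-autocorrelation timescale | s | 0.04–0.13 |
| η | RMS of the stochastic velocity component about μ | µm/s | 75–290 |
| ω | constant angular velocity (rotation) | rad/s | ±2–4 |
| μ | constant advection velocity | µm/s | 0–200 |

τ is the e-folding time of the velocity autocorrelation
η²·exp((iω − 1/τ)h); small τ gives Brownian-like motion, large τ nearly
straight paths, which is why it is read as "movement linearity". The
reported movement speed is the stationary RMS speed √(η² + |μ|²),
which reduces to η for the unbiased variants; whether the advective
component should count toward "speed" is a convention, and this one is
chosen because it equals the stationary second moment of the speed for
every variant.

Over a uniform frame interval dt the process has an *exact*
discretization

    V_{k+1} = μ + a·(V_k − μ) + ε_k,   a = exp((iω − 1/τ)·dt),

with ε_k complex Gaussian of total variance η²(1 − e^{−2dt/τ}).
Both the simulator and the likelihood use this same recursion, so the
two are mutually consistent by construction and the simulator is exact
at any dt (no Euler error). Positions integrate the piecewise-constant
velocity: X_{k+1} = X_k + V_k·dt; consequently the finite-difference
velocities recover V exactly and the "velocity likelihood" is the exact
likelihood of the finite-difference series. Non-uniform time steps are
rejected rather than interpolated: video data are uniformly sampled and
the discretization assumes it.

Four nested variants are fitted per trajectory — UCVM (μ=0, ω=0; k=2
free parameters), RCVM (ω free; k=3), ACVM (μ free; k=4), RACVM (both;
k=5) — and compared by AIC = 2k − 2·logL. Ties are broken toward fewer
parameters, then the fixed order UCVM < RCVM < ACVM < RACVM.

### Numerical choices

* Optimization over (log τ, log η[, ω][, μx, μy]) with L-BFGS-B inside
  box bounds τ ∈ [dt/10, 100·T] (T = trajectory duration),
  η ∈ [10⁻³, 10·max empirical speed], ω ∈ [−π/dt, π/dt], μ components
  within twice the largest empirical speed. The bounds are wide enough
  that interior optima are unaffected; a fit touching any bound is
  flagged `boundary`.
* Starting values are moment estimators (deterministic, data-driven):
  η₀ = empirical RMS about the mean velocity, μ₀ = mean velocity,
  τ₀ = −dt/log|ρ₁| from the lag-1 autocorrelation ρ₁ of the centred
  series, ω₀ = arg(ρ₁)/dt.
* The likelihood includes the stationary log-density of the first
  velocity. This matters in degenerate cases: on a noise-free straight
  line the conditional terms push η → 0 but the stationary term
  penalises it, so η settles at ≈ speed/√(n+1) while τ runs to its
  upper bound (flagged). η = 0 with non-degenerate data returns −∞ by
  contract rather than raising.
* Optimizer failure is reported via `converged=False`, never silently;
  a variant whose fit raises is excluded from model selection and
  logged, and selection fails only if all four variants fail.
* Minimum trajectory length for fitting: 10 points (configurable),
  comfortably above the 5-parameter maximum.

## Screening and aggregation

* **Moving cell:** duration strictly > 1 s and *net* (first-to-last)
  displacement strictly > 50 µm (≈ one body length). Net rather than
  gross displacement, so a cell jittering in place never counts as a
  mover; the thresholds are configurable.
* **Activity:** moving / total trajectories per tube, computed before
  any subsampling.
* **Subsampling:** 23 moving trajectories per tube, uniform without
  replacement, seeded; if fewer are available all are used and a
  warning logged.
* **Outlier exclusion:** scaled MAD rule |x − med| / (1.4826·MAD) ≤ 3,
  applied pooled across all trajectories of a run, separately to fitted
  RMS speed and τ, on the natural scale; a trajectory flagged on either
  parameter is dropped from both means (keeps the speed–τ pairing
  intact). If the scaled MAD is zero the rule is degenerate and
  everything is kept. Whether such screening should pool across
  genotypes or work within groups is a genuinely open choice; pooling
  is the simplest and is the package default.
* **Tube summaries:** means of ln(RMS speed) and ln(τ) over retained
  trajectories (ln first, then average), plus pass-through morphology
  (mean cell area µm², elongation ≥ 1) and density. Dispersal rate is
  target/(start+target) with densities averaged over replicate images
  *before* the ratio (ratio of means, not mean of ratios).

## Inference

**Q1 — three-way nested ANOVA.** One observation per tube; genotype and
dispersal status crossed fixed effects; replicate a random effect
nested in genotype and crossed with status. The design is saturated
(zero residual df), so the two random strata serve as error terms:
genotype is tested over replicate(genotype); status and
genotype×status over replicate×status(genotype); the strata themselves
carry no F. Sums of squares are sequential (type I) in that row order,
computed by incremental least-squares projections; with at most one
missing system the design is near-balanced and the SS type is
immaterial, but it is recorded in the table metadata. Systems missing
one status are dropped with a warning. The implementation was verified
against R's `aov` with an `Error(genotype:replicate +
genotype:replicate:status)` specification (exact agreement) and against
closed-form identities on the per-system disperser−resident
differences. Speed and τ enter ln-transformed; p-values come from the
F distribution with the listed df and no multiplicity correction is
applied.

**Q2 — ANCOVA with AICc parsimony.** Candidate set: all additive
combinations of status, size and shape plus marginality-respecting
status×size and status×shape interactions, plus the intercept-only
model (13 candidates). Each is fitted by OLS; k counts coefficients
plus the residual variance; AICc = AIC + 2k(k+1)/(n−k−1). The selected
model is the smallest-k candidate within 2 AICc units of the best
(ties by lower AICc); Akaike weights are reported over the whole set.
A candidate with zero residual variance has unbounded Gaussian
likelihood; it is treated as AICc = −∞ and the parsimony rule falls
back to the parameter count (this arises in the all-differences-zero
limit of the Δ-models). Rank-deficient candidates are dropped with a
warning. The same machinery runs on within-replicate
disperser−resident differences (Δ ln speed, Δ ln τ on Δ size, Δ shape).

**Q3 — dispersal R² decomposition.** Movement metrics are averaged to
one value per genotype (over statuses and replicates; speed and τ are
averaged on the natural scale after back-transforming tube means), and
genotype-mean dispersal rate is regressed on activity, τ, speed, and
all three; R² and AIC (same k convention, matching R's `AIC` for `lm`)
are reported per model.

**Covariation.** τ is regressed on RMS speed across genotype×status
means (2 points per genotype; the observation level is configurable —
the right observation level is itself a modelling choice). The common
slope comes
from the additive model τ ~ speed + status; the status-difference tests
(intercept and slope) from the interaction model.

## Synthetic experiments

The generator emulates the hierarchical structure the analyses assume,
with defaults calibrated once to the published genotype-level ranges
and status contrasts for this organism (activity 0.39–0.70, RMS speed
75–289 µm/s, τ 0.039–0.13 s, dispersal 0.07–0.71; dispersers vs
residents 0.62 vs 0.57, 171 vs 139 µm/s, 0.0804 vs 0.0602 s):

* Genotype latents on transformed scales (ln speed, ln τ, logit
  activity, ln size) from a correlated Gaussian: size→speed loading
  0.5 ("larger cells move faster"), speed–τ correlation 0.7 (fast cells
  swim straighter), activity–speed 0.3. Status-averaged back-transforms
  are truncated to the observed ranges, so a default panel always lies
  inside them.
* Disperser offsets on ln speed (0.207), ln τ (0.289) and activity
  logit (0.207) equal the published contrasts, with genotype-specific
  N(0, 0.08) deviations supplying the genotype×status interaction.
* Dispersal logit = logit(0.25) + 0.40·z_act + 0.35·z_speed +
  0.15·z_τ + N(0, 0.65), clipped to the observed range. The
  coefficients were calibrated (variance calculation plus a 50-seed
  check) so the genotype-level R² decomposition centres near the
  published values (full model ≈ 0.47–0.50); per-seed values scatter
  with sd ≈ 0.10 at 44 genotypes, which is why the calibration target
  is the across-seed mean.
* Replicate(genotype) and tube-level noise are N(0, 0.1) per response.
  Replicate- vs tube-level variance components are not separately
  observable from published summaries of such assays, so these are
  calibration choices set from the scale of reported ln-speed mean
  squares; they give the status test near-exact 5%
  size under the null and >90% power at the published effect size.
* Rendering: each system splits the 300,000 cells/mL inoculum by its
  realized dispersal rate into start/target densities (5-image
  lognormal measurement error, CV 3%). Each tube renders
  `cells_per_tube` trajectories over 1,000 frames at 25 fps: movers
  (binomial at the tube's activity) get per-trajectory speed and τ with
  20% lognormal scatter about the tube mean and a CVM variant from a
  configurable mix (default ACVM 0.45 / UCVM 0.35 / RCVM 0.10 /
  RACVM 0.10, advective |μ| = 0.7·RMS, ω ~ ±N(3, 1) rad/s), simulated
  by the exact-discretization batch simulator; non-movers perform
  sub-threshold random-walk jitter (net displacement scale 10 µm over
  the video — real non-movers are characterised only by failing the
  activity thresholds, so any sub-threshold kinematics would do).
* `render="summary"` skips trajectory rendering and emits tube-level
  observations directly from the latent model (binomial activity;
  ln-speed/ln-τ estimation noise at the 23-trajectory scale,
  sd = 0.2/√23). This fidelity level is statistically equivalent for
  inference-scale simulation studies (ANOVA calibration, R² band) at a
  tiny fraction of the cost; the trajectory level is used wherever the
  fitting chain itself is under test.

### What the generator does and does not emulate

It reproduces the hierarchical variance structure, the status
contrasts, morphology–movement coupling and movement–dispersal
coupling. It does *not* simulate the two-patch geometry (dispersal is
drawn from the latent logit model, not from corridor crossings — the
corridor is not parameterized in the source), cell division or
starvation morphs during the 6 h assay, cells swimming in/out of the
imaged field, or tracking errors. Passing tests therefore demonstrate
that the estimation and inference chain is correct and well calibrated
for data with this structure, not that the biological model generating
real data is this one.

## Problem sizes used in the shipped checks

Parameter recovery uses 100 trajectories of 1,000 steps per variant;
model-selection consistency 50 per variant; the ANOVA type-I
calibration 1,200 reduced-scale (10×3×2) summary-mode experiments
(enough to pin the rate to ±0.6%) and the power check 60 full-scale
ones; the end-to-end run is one full 44×3×2 experiment with ~26,000
rendered trajectories and all 6,026 subsampled fits; the R² band uses
50 full-scale summary-mode experiments. These sizes were chosen so each
statistic's Monte-Carlo error is small relative to the band it is
checked against.

## Known limitations

* The velocity likelihood conditions on finite-difference velocities;
  position-level ("exact") likelihoods and Kalman smoothing are out of
  scope, as are within-trajectory behavioural change points.
* AIC comparison across CVM variants uses the velocity likelihood for
  all four; exact position-likelihood fitting (available in reference R
  tooling only for the unbiased variant) is not replicated here.
* The ω estimate's sign is identifiable only from the data (clockwise
  vs counter-clockwise); recovery checks compare signed values at a
  fixed generating sign.
* Genotype-level truncation to the published ranges slightly compresses
  the latent variance for extreme draws; at the default SDs fewer than
  ~5% of draws are clipped.
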