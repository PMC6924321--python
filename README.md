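# cvmove

Movement → dispersal analysis for two-patch microcosm experiments with
actively swimming cells (built around the *Tetrahymena thermophila*
two-tube dispersal assay, but generic over any trajectory table).

Microbial dispersal experiments connect three observation scales: raw
cell trajectories from short videos, tube-level summaries of movement
behaviour, and the genotype-level dispersal rate across a two-patch
system. `cvmove` covers the full chain:

* **Correlated velocity models (CVM).** A cell's planar velocity,
  written as a complex number V, follows a mean-reverting
  Ornstein–Uhlenbeck process
  dV = (iω − 1/τ)(V − μ)dt + noise, with τ the velocity-autocorrelation
  timescale ("linearity": τ → 0 is Brownian-like, large τ is straight
  swimming), η the RMS of the stochastic velocity component, ω a
  constant angular velocity and μ a constant advection. The four nested
  variants UCVM (μ=0, ω=0), RCVM (ω free), ACVM (μ free) and RACVM
  (both free) are simulated by exact discretization, fitted by maximum
  velocity likelihood, and compared per trajectory by AIC. The reported
  movement speed is the stationary root-mean-square speed
  √(η² + |μ|²).
* **Screening and aggregation.** Activity (fraction of trajectories
  with duration > 1 s and net displacement > 50 µm ≈ one body length),
  random subsampling of 23 moving trajectories per tube, median-
  absolute-deviation outlier exclusion (threshold 3) on fitted speed
  and τ, tube-level means of ln(speed) and ln(τ), and the dispersal
  rate target/(start + target) from tube densities.
* **Inference.** Three-way nested ANOVA (genotype and dispersal status
  crossed fixed effects; replicate random, nested in genotype, crossed
  with status; F-tests against the correct random strata in the
  saturated design), ANCOVA candidate sets over status/size/shape with
  AICc and the ΔAICc < 2 parsimony rule, within-replicate
  disperser−resident difference models, genotype-level R²/AIC
  decomposition of dispersal rate on activity/speed/linearity, the
  speed–linearity covariation regression, and per-genotype CVM
  model-frequency tables.
* **Synthetic experiments.** A calibrated hierarchical generator
  renders complete in-silico experiments (44 genotypes × 3 replicates ×
  2 tubes by default, 1,000-frame videos at 25 fps) with known latent
  truth, so every stage of the pipeline is testable without raw video.

## Worked example

Run a small synthetic experiment (8 genotypes × 2 replicates, 30 cells
per tube, 10-second videos) end to end:

```python
from cvmove.pipeline import RunConfig, run_pipeline
from cvmove.synthetic import ExperimentConfig

cfg = RunConfig(
    seed=5, outdir="demo",
    experiment=ExperimentConfig(n_genotypes=8, n_replicates=2,
                                cells_per_tube=30, frames=250,
                                drop_systems=()),
    subsample_n=6,
)
run_pipeline(cfg)
```

or equivalently `cvmove run --config demo.yaml --seed 5 --out demo`.
The run directory contains `fits.csv` (per-trajectory, per-model CVM
fits), `tubes.csv` (tube-level summaries), the ANOVA/ANCOVA/selection
tables as CSV, and `report.txt`, which for this seed prints (excerpt):

```
ANOVA — response: ln_speed (transform: identity, sequential SS, n = 32)
Effect                  Denominator                              df   SS      MS     F      p
Genotype                Replicate (genotype)                      7  1.2571  0.1796  4.38  0.02737
Dispersal status        Replicate x dispersal status (genotype)   1  0.2195  0.2195 10.28  0.01251
Genotype x dispersal status  Replicate x dispersal status (genotype)  7  0.2889  0.0413  1.93  0.188
Replicate (genotype)    Error                                     8  0.3277  0.0410     -     -
Replicate x dispersal status (genotype)  Error                    8  0.1709  0.0214     -     -

Speed-linearity covariation: b = 0.00026758 (t = 4.892, p = 0.000294)

Dispersal-rate R^2 decomposition (genotype level):
    model             predictors  k       r2       aic
 activity               activity  3 0.262495 -3.422370
linearity                    tau  3 0.108253 -1.903089
    speed                  speed  3 0.131629 -2.115595
     full activity + speed + tau  5 0.404482 -1.133091
```

Reading this: genotypes differ significantly in ln movement speed
(F₇,₈ = 4.38 against the replicate-within-genotype stratum), dispersers
move significantly faster than residents (F₁,₈ = 10.28 against the
replicate×status stratum), speed and linearity co-vary positively
across genotypes (b = 2.7·10⁻⁴ s per µm/s), and activity + speed +
linearity jointly explain ~40% of the genotype-level variation in
dispersal rate in this small demo.

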