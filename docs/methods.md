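# Methods

## Scenario calibration

Each causal scenario is a directed structure in which exactly one weight
measurement (age 0 in A, 1 in B, 2 in C) has a direct standardised effect
`d` on HbA1c; latent growth and the unmeasured common cause of birthweight
and growth are never represented explicitly — the package works with the
reduced-form joint Gaussian over the four observed variables. Under a
single direct arrow, d-separation factorises every non-causal weight's
outcome correlation as `corr(W_j, H) = d · corr(W_j, W_causal)`, so the
three per-scenario target correlation vectors over-determine the three
between-age weight correlations. `derive_weight_correlations` solves the
stacked system by least squares, requires every residual to stay below 0.01
on the correlation scale, and requires the result to be positive definite;
with the default targets the solution is ρ01 = 0.040, ρ02 = −0.151,
ρ12 = 0.327 and `d = 0.70`. The weight block of the joint covariance is
therefore identical across scenarios; only the outcome column moves. The
alternative — picking one scenario's ratios — would reproduce that scenario
exactly and the others only approximately; the least-squares pooling treats
the three targets symmetrically and fails loudly if they ever become
inconsistent.

Moments: mean weight 4/8/12 kg at ages 0/1/2 (SD 2 kg each), HbA1c mean
5.8% (SD 1%). Diabetes is the indicator `HbA1c > 6.5` (strict), so the
expected prevalence is `1 − Φ(0.7) ≈ 0.242`. HbA1c stays continuous in the
cohort table — the correlation summaries need it — with diabetes as a
derived column.

## Simulation

Cohorts are i.i.d. draws from the scenario's joint Gaussian
(`Generator.multivariate_normal`, Cholesky factorisation for bit-stable
determinism). Age is centred at 1 year, so the long format carries times
(−1, 0, 1). Seeding: `SeedSequence([master_seed, scenario_index,
replicate])` gives every replicate an independent, individually
reproducible stream; re-running any configuration is byte-identical.
Defaults are the study conditions: n = 1000 per cohort; 1000 replicates in
the full study, 300 in the bundled drivers, acceptance script and tests
(Monte-Carlo SE of every reported mean is then at least an order of
magnitude below the differences of interest, e.g. ~0.007 for the
interaction terms).

What the generator deliberately does not emulate: nonlinear growth,
missing data, loss to follow-up, competing events, measurement error, and
time-varying confounding. Passing tests therefore show that the methods
disagree *under ideal conditions for both of them*; they say nothing about
robustness to those real-data features, where all three methods would do
worse.

## Mixed model

Both mixed-model analyses share one engine: random intercept and slope
with AR(1) residual correlation over occasions,
`V = Z G Zᵀ + σ²_e R(ρ)`, `Z = [1, t]`, `R_st = ρ^|s−t|`. The marginal
Gaussian likelihood is computed directly; fixed effects are profiled out by
GLS at every variance-parameter value. Variance parameters are optimised on
an unconstrained scale — log variances, Fisher-z (atanh) for the
intercept–slope correlation and for ρ — which avoids boundary failures
while still allowing the correlation to saturate at ±1. REML is the
default (matching standard mixed-model software); ML is selectable on the
model-specification object and agrees with REML to well under 1% at large n.

Because every design here is balanced, one likelihood evaluation needs
only per-covariate-group counts, sums and cross-product matrices; cost is
independent of the number of subjects, which is what makes the replicate
loop cheap.

Numerical choices. With three occasions the five variance parameters are
only just identified and the likelihood can be extremely flat — in
particular along the intercept–slope correlation, which often saturates at
+1 (the outcome-covariate fits reproduce nlme's near-unity value there).
Optimisation runs L-BFGS-B and, whenever the central-difference gradient at
its stopping point exceeds tolerance, a Nelder–Mead polish; convergence is
declared when the central-difference gradient max-norm on the unconstrained
scale falls below 1e-3 (at a likelihood magnitude of ~6·10³,
forward-difference noise alone is ~1e-4, so a much tighter cut would reject
true optima). Up to three jittered restarts (fixed internal jitter stream,
so fits stay deterministic) precede declaring failure; non-converged fits
are flagged and the Monte-Carlo harness discards them per model — a z-score
profile has no convergence concept, so a failed mixed model never discards
the whole replicate. Singular covariances during search return a penalty
value rather than propagating.

Individual growth rates are empirical-Bayes (BLUP) conditional means
`γ1 + u1j` with `u_j = G Zᵀ V⁻¹ (y_j − X_j β̂)`; the GLS normal equations
force the EB deviations to average to zero exactly, so the mean extracted
slope equals the fixed slope. A dense stacked-covariance implementation of
the same likelihood, and `nlme::lme` run through Rscript, serve as
independent cross-checks in the tests (agreement to 1e-8 and to optimizer
precision respectively; identical REML constant conventions verified
numerically).

## The three analyses

Z-scores use the per-age, within-cohort sample mean and SD (ddof = 1 —
immaterial at n = 1000, fixed for bit-reproducibility). The
prevalence-weighted sum of the two group means is zero by construction;
the test suite checks the group means against the truncated-normal closed
form `±ρ·φ(0.7)/Φ(∓0.7)`.

The outcome-covariate model adds diabetes and diabetes×age to the fixed
effects. Its interaction approximates half the difference between the
age-2 and age-0 group-mean separations, `(ΔE[W₂] − ΔE[W₀])/2` with
`ΔE[W_j] = corr(W_j,H)·2·1.7024` kg — the closed form the acceptance tests
require alongside the simulation estimate.

The two-step analysis passes only id/time/weight into step 1 (the
interface cannot see the outcome), rescales the extracted slope by 0.1 so
the exponentiated coefficient is an OR per 0.1 kg/yr, and fits ordinary
maximum-likelihood logistic regression with an intercept and a birthweight
covariate. Perfect separation or a failed IRLS is reported as
non-convergence. Step 2 treats the estimated growth rates as observed, so
its standard errors are understated; the study relies on empirical
(across-replicate) intervals instead, and no estimated-regressor
correction is attempted.

## Known limitations

* Only single-direct-arrow causal structures are supported — this is a
  calibration for the three scenarios, not a DAG compiler.
* Only balanced designs (every subject measured at the same occasions) are
  accepted by the likelihood; the study needs nothing else.
* Discarded-fit counts are optimizer-specific and are reported but not
  matched to any external reference.
* The two-step empirical CIs still understate uncertainty in single-dataset
  use; latent-variable formulations (growth-curve or mixture models) avoid
  treating the slope estimate as data but are out of scope here, as are
  g-methods for time-varying confounding.
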