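# Methods

## Model

The response model links log10 molar agonist concentration x to effect in
percent of the system maximal effect:

    E(x) = 100 · q·ε·γ·10^(n·x) / [ (q·ε·γ − q·ε + 1)·10^(n·x) + 10^(n·logKd) ]

Parameters, units and defaults:

| parameter | meaning | domain used | notes |
|---|---|---|---|
| ε | receptor-activation efficacy (dimensionless) | (0, 10] | 1 for a full agonist; constrained to 1 in final-phase fits |
| γ | post-receptor gain (dimensionless) | (0, 1e6] | γ ≫ 1 creates receptor reserve |
| n | Hill-type coefficient of post-receptor signaling | (0, 5] | constrained to 1 in final-phase fits |
| logKd | log10 dissociation constant (molar) | [−12, 0] | the quantity of pharmacological interest |
| q | fraction of operable receptors | [0, 1] | 1 for controls; shared across pretreated curves |

The domain bounds enclose all plausible pharmacological values with wide
margins and serve as the optimizer's box constraints.  Validation also
requires q·ε·γ − q·ε + 1 > 0, which guards the γ < 1 corner where the
denominator could change sign.

Closed forms used throughout: apparent maximum
E_max^app = 100·q·ε·γ/(q·ε·γ − q·ε + 1) and apparent
EC50 = 10^logKd/(q·ε·γ − q·ε + 1)^(1/n).  With ε = 1 and γ = 85.43,
dropping q from 1 to 0.22 moves the apparent maximum only from 100% to
96.0% while shifting the EC50 4.36-fold to the right — the regime where
affinity estimation from functional data is hard, and the regime the
default synthetic design deliberately reproduces.

Numerical evaluation divides through by 10^(n·x) and clips the remaining
exponent to ±300 so that the extreme trial values an optimizer explores
cannot overflow.

## The unified (multiline) regression

A *plan* binds one equation to each dataset and declares every parameter
fixed, or free with a sharing scope.  The preset for the paired
multi-agonist design shares γ and n across all curves, ε_agonist and
logKd_agonist within each agonist's control/pretreated pair, and q across
the pretreated curves only (control curves use the q = 1 form).  Two phases
are exposed: *preliminary* (ε, n free and shared; 9 free parameters for
three agonists) and *final* (ε = n = 1 fixed; 5 free parameters).  Only
final-phase results are normally reported; the preliminary phase exists to
seed or sanity-check the constrained fit, and either fresh defaults or
preliminary estimates may start the final phase.

The plan is compiled to index arrays (one gather per free parameter), so
one objective evaluation over all datasets is a handful of vectorized
operations.  Estimation minimizes the unweighted pooled sum of squared
residuals with scipy's bounded trust-region-reflective least squares.
Choices that matter:

- **Unweighted residuals over all replicate points.**  Matches an additive
  homoscedastic error model in percent units; per-concentration-mean
  fitting is available as an option but changes the degrees of freedom.
- **Starting values.**  logKd starts at the control curve's interpolated
  midpoint crossing plus log10(γ₀), with γ₀ = 10, q₀ = 0.5, ε₀ = n₀ = 1 —
  on the correct decade without user input.
- **Multistart, default 5.**  The q/γ trade-off can create local optima;
  restarts jitter γ and ε log-uniformly over one decade, logKd by ±1 log
  unit, q uniformly, all seed-controlled and clipped to the box.
- **Convergence.**  Relative cost tolerance 1e−10 — far below the 2–4
  significant digits at which estimates are meaningfully reported.
- **Covariance.**  ssr/dof · (JᵀJ)⁻¹ at the optimum, pseudo-inverse with a
  rank-deficiency flag when the Jacobian loses rank.
- **Determinism.**  Datasets are ordered by label and points by (x, y)
  before assembly, so results are bit-identical under input reordering.

## Diagnostics

**Profile-likelihood ("asymmetric") CIs.**  The interval for parameter θ
is {v : SSR(v) ≤ SSR_min·(1 + F(level; 1, dof)/dof)}, where SSR(v) refits
all other free parameters with θ fixed at v.  Ends are located by outward
walking with warm-started inner refits followed by bisection on the
bracketed crossing; if the threshold is not crossed before the domain
bound, that end is reported *open* (rendered "?").  On quadratic (linear
-model) SSR surfaces this reproduces the textbook t-based interval exactly,
and for nonlinear fits it is never materially narrower than the Wald
interval.

**Dependency.**  From the estimate correlation matrix R,
dependency_i = 1 − 1/(R⁻¹)_ii, clipped to [0, 1]: 0 for an independent
parameter, r² for two correlated parameters, 1 for a redundant one.  A tiny
ridge keeps the inverse defined under exact collinearity so affected
parameters report ≈1 while unaffected ones stay meaningful.  This
variance-inflation form is the standard definition consistent with the
0–1 redundancy semantics of the commercial tool it emulates; the original
tool's exact formula is unpublished, so agreement is treated as
approximate, not bit-exact.  Thresholds: > 0.9 "high", > 0.99 "unacceptably
high", > 0.9999 flags the parameter (and hence the fit) ambiguous.

**R² family.**  Individual R² per dataset about that dataset's own mean;
global R² pools all observations about the grand mean of all Y (stated
explicitly because other poolings exist); adjusted global
R² = 1 − (1 − R²)·(N − 1)/(N − K − 1), which falls visibly below the global
value when redundant parameters inflate K.  Constant data (SST = 0) yields
an explicit undefined marker, never a number.

**Bands.**  Delta method on the global fit: ŷ ± t(level, dof)·√(gᵀΣg) for
the confidence band and ŷ ± t·√(gᵀΣg + ssr/dof) for the prediction band,
with g the response gradient in the free parameters (central differences
kept inside the bounds box) and dof = N − K of the unified fit, since the
bands derive from that single regression.  The prediction band strictly
contains the confidence band; both collapse onto the curve as noise
vanishes.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes: for
each agonist a control (q = 1) and a pretreated (q = design.q) curve whose
mean function is *the same implementation* of the response equation, plus
additive Gaussian noise in percent units.  Defaults: three agonists with
logKd −5.84, −6.09, −5.38 and ε = 1; γ = 85.43; n = 1; q = 0.22; 12
half-log concentrations from −9 to −3.5 (covering both the control EC50
≈ 1.7·10⁻⁸ M and the pretreated ≈ 7.4·10⁻⁸ M transitions); 5 replicates
per concentration; noise SD 4% — a few-percent error consistent with SEM
bars on isolated-atrium inotropy data.  Noise streams are keyed by (master
seed, dataset index, replicate), so any subset regenerates identically in
isolation and adding replicates never perturbs existing ones.

What the generator does **not** emulate: the upstream normalization from
raw contractile force to E/E_max %, heteroscedastic or non-Gaussian error,
between-preparation (atrium-level) random effects, and the original
studies' exact replicate structure.  Passing recovery tests therefore
demonstrate correctness of the estimator under its assumed error model, not
robustness to those real-data features.

Recovery studies repeat simulate → plan → fit → diagnostics over
deterministically spawned child seeds and aggregate per-parameter bias,
RMSE, profile-CI coverage and mean dependency, excluding (and counting)
failed fits.  At the default design, 200 replicates put profile-CI coverage
for all five parameters in the low-to-mid 90s (slight undercoverage is
expected for profile intervals on nonlinear models at finite samples), q
bias within ±0.002, and q's mean dependency near 0.62 against ~0.98 for γ —
the gain is the weakly identified parameter, q the strong one.

## Problem sizes

Desk-scale defaults keep every study small enough to run interactively:
single fits use 360 points (6 × 12 × 5), recovery studies 150–200
replicates, the brute-force optimizer check a 400 × 400 grid, and the
noise-variance calibration 40 seeds at N = 288.

## Known limitations

- The published parameter table of the motivating laboratory study can only
  be reproduced from its deposited dataset, which has no printed accession
  and is not redistributed here; the corresponding benchmark runs only when
  that file is supplied (`data/deposited_ec_curves.csv`).
- Dependency values approximate the emulated commercial software's output;
  they agree in range, ordering and interpretation but are not guaranteed
  to its last digit.
- No robust-loss, Bayesian or heteroscedastic estimation; no biphasic or
  allosteric model extensions; wide-layout spreadsheet import is out of
  scope (long/tidy CSV only).
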