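# Methods

This note documents the models, estimation procedures, numerical choices
and known limitations of `thermotk`, in the spirit of a model-description
chapter: what is computed, under which assumptions, and what the synthetic
validation studies do and do not demonstrate.

## Compartment models and their closed forms

The parent model treats the organism as a single well-mixed compartment
exchanging a chemical with the surrounding water: uptake proportional to
the water concentration (`k_u`, L kg_ww⁻¹ d⁻¹, covering dermal and
respiratory routes) and first-order loss (`k_e`, d⁻¹, covering excretion
and biotransformation together). The exposure design is a rectangular
pulse: a constant (averaged) water concentration during the uptake phase,
zero afterwards — measured medium residues during elimination are assumed
negligible and forced to zero. Growth dilution and dietary uptake are not
modelled (the emulated experiments are short and unfed during uptake), and
no second compartment is available: compounds with pronounced two-phase
elimination are outside this package's scope and must be flagged by the
analyst.

The biotransformation model splits `k_e` into excretion `k_e,p` and primary
biotransformation `k_m,1st` and appends two pooled product states (total
primary and total secondary BTPs) with their own loss rates. Pooling keeps
the parameter count at six; it assumes the pooled products share broadly
similar kinetics. Stoichiometry is molar, so tissue concentrations must be
in molar units for the cascade to conserve mass; unit tags on the exposure
design and dataset carry this through, and conversion from mass units is
the caller's responsibility.

Both models are linear with piecewise-constant forcing and therefore have
exact solutions. The implementation evaluates them by eigendecomposition of
the (lower-triangular) rate matrix — sums of exponentials when the three
loss rates are pairwise distinct. When two loss rates coincide within a
relative 1e-8 the partial-fraction coefficients blow up, so the evaluation
switches to the matrix exponential of an augmented (state + constant
forcing) system, which is equally exact and unconditionally stable, at a
modest speed cost. The `k_e → 0` limit of the parent model uses the linear
uptake formula below 1e-12 d⁻¹. Concentrations are reported at machine
precision; relative comparisons in the validation suite are floored at
1e-6 of the trajectory peak because below that both the closed form and
any reference integrator are dominated by floating-point cancellation.

## Estimation

All rate constants are fitted simultaneously to all measured tissue states
by minimising the weighted sum of squared residuals, weights equal to the
number of animals pooled per sample. This realises an error model of
independent additive normal errors with variance inversely proportional to
the number of pooled animals. The water concentration entering the model
is the arithmetic mean of the measured uptake-phase medium values.

Optimisation is a deterministic multi-start in log10-rate space: a fixed
Latin-hypercube of eight starts over [1e-3, 1e3] plus a data-driven
heuristic start, each refined by bounded trust-region least squares
(`scipy.optimize.least_squares`). Positivity is enforced by the log
parameterisation. Reproducibility is preferred over raw speed; a parent fit
takes ~50 ms.

Model comparison uses the least-squares AIC, `n·ln(SSQ_w/n) + 2(K+1)`,
counting the error variance as a parameter. The lowest AIC wins; among
candidates within two AIC units the fit with the higher mean R² over the
parent and primary-BTP states is selected (the secondary-BTP pool carries
the largest measurement uncertainty and is excluded from the tie-break).
When no secondary-BTP observations exist, `k_m,2nd` and `k_e,2nd` are fixed
at zero and excluded from K.

Confidence intervals are profile likelihoods: the focal parameter walks
outward from the estimate on a multiplicative grid (factor 1.6), all other
parameters re-optimised at each value with warm-start continuation, until
the profiled deviance `n·ln(SSQ_prof/SSQ_best)` crosses the χ²₁ 95 %
quantile (3.84); the bound is then refined by log-space bisection. A
profile still below the threshold 10⁴-fold away from the estimate is
reported as unbounded (0 or ∞) with a flag — typical for the excretion rate
when biotransformation dominates total elimination. Below-LOQ observations
are dropped by default (with a logged count); LOQ/2 substitution is
available as a policy switch.

### Calibration of the profile intervals

A simulation study at the emulated design (four temperatures, duplicate
samples of pooled animals, 20 % multiplicative lognormal noise) shows the
95 % profile interval for `k_u` covering the true value in roughly 85 % of
datasets. This is a deliberate, documented consequence of the error-model
mismatch: the data-generating noise is multiplicative (variance ∝ mean²)
while the fitting likelihood is additive with constant variance, so the
χ²-calibrated likelihood-ratio bound is anticonservative — a sandwich
analysis predicts per-temperature coverages of ~87–97 % for this design,
and finite-sample effects (22 observations; χ² rather than F calibration;
lognormal skewness) remove a few further points. With noise matched to the
likelihood the same machinery attains 94 % coverage, and even an exactly
matched log-space likelihood reaches only ~89 % at this sample size.
Practitioners should read the profile intervals as approximate at
realistic noise levels; rate estimates themselves are nearly unbiased
(median relative bias well under 1 %).

## Arrhenius analysis

`ln k` is regressed on `1/T` by ordinary least squares; `T_A` is minus the
slope and `ln A` the intercept. The regression is unweighted by default
(optional 1/se² weighting via the delta method on `ln k` is provided);
slope standard errors are reported only for three or more temperatures.
Rates at or below 1e-6 d⁻¹ are excluded with a logged reason before
fitting — such estimates arise when another elimination route dominates and
carry no temperature signal. Reference physiological Arrhenius temperatures
(Add-my-Pet database values of 10,560 K for *G. pulex* and 10,830 K for
*H. azteca*, and the respirometry-derived 8030 K for *H. azteca*) ship as
constants for report overlays only; they never enter any fit.

The BCF trend test regresses `BCF_kin` (untransformed) on absolute
temperature and applies the two-sided t-test of zero slope at α = 0.05; the
verdict is invariant to the °C/K offset. Classic Arrhenius behaviour is
assumed throughout — no high-temperature deactivation term, no Q10
parameterisation.

## Scenario simulation

The scenario integrator advances `dC/dt = C_w(t)·k_u(T(t)) − C·k_e(T(t))`
with fixed-step Heun (explicit trapezoidal): an Euler predictor followed by
averaging the endpoint slopes, with temperature, exposure and the
Arrhenius-scaled rates re-evaluated at both stage times. The method is
second-order on smooth profiles (measured convergence order 2.01 by
Richardson step-halving against a tight adaptive solve). Profiles are
piecewise linear between breakpoints (temperature) with an optional
previous-value hold (step-function exposure series). Across an exposure
discontinuity a fixed-step scheme is locally first-order — one step
straddling the jump integrates half the forcing — so the default step of
0.001 day keeps pulse trajectories within 0.1 % of the closed form;
simulation runs log a one-time step-halving self-check, and a step larger
than the smallest profile segment raises a warning. Negative excursions
beyond round-off are clipped to zero with a warning.

The daily-temperature-fluctuation (DTF) generator produces a sinusoid of
given mean, peak-to-peak range, period and initial phase, discretised at
48 breakpoints per period; its trapezoidal time average matches the mean to
< 0.01 K. The sinusoid is a stand-in for field temperature records —
arbitrary breakpoint profiles are accepted whenever a measured series is
available. Scenario comparison reports peak concentrations, peak times,
pairwise peak ratios and the first post-peak crossing time (warm
trajectories overtake cold ones during uptake and fall below them during
elimination when rates share a positive T_A). Scenarios use the parent
model only; no toxicodynamics.

## Synthetic data

The generator emulates a multi-temperature amphipod bioconcentration study:
four temperatures at the measured values 6.1, 11.0, 15.4 and 21.2 °C;
50 µg/L exposure for one day followed by three days of elimination;
duplicate tissue and medium samples at regular intervals (default five
uptake and six elimination occasions); 4 (*G. pulex*) or 15 (*H. azteca*)
animals pooled per tissue sample, which also sets the fitting weight. True
rates follow a configurable Arrhenius law or are fixed per temperature.

Noise is multiplicative lognormal with mean exactly one (σ² correction on
the log scale), default CV 20 % for tissue and 5 % for medium — the real
study does not report replicate CVs, so these are assumptions recorded with
the output. Values below a configurable LOQ are flagged rather than
removed. Optional features mirror reported artefacts: a linear decline of
the uptake-phase medium concentration (up to ~20 %), and
temperature-increasing mortality as progressive loss of late sampling
occasions (off by default). Cascade presets cover the two observed
biotransformation regimes — a minor share (< 7 % of total parent
elimination) and a dominant share (> 90 %, leaving excretion near zero and
its profile lower bound at 0). Demo truths are chosen so a fast compound
equilibrates within a day at 21 °C while a slow one needs more than four
days at 6 °C, exercising the kinetic-versus-equilibrium BCF distinction.

Everything is a pure function of (configuration, seed). What passing tests
on these data show: correctness of the solvers, estimator and test
machinery under the stated noise model, and end-to-end recoverability of
Arrhenius structure at realistic noise. What they do not show: robustness
to real-world features the generator omits — matrix effects and ionisation
artefacts in quantification, inter-individual variability beyond pooling,
correlated replicate errors, medium depletion kinetics, or model
misspecification beyond the one-compartment family.

## Validation studies and problem sizes

`scripts/acceptance.py` (seeded) re-runs: a 100-point random-rate sweep of
the closed forms against a piecewise Radau reference solve (agreement to
~1e-5 %); a 200-dataset recovery study (bias and profile coverage as
discussed above); Arrhenius recovery noise-free (machine precision) and
over 100 noisy tables of eight chamber rows per temperature (~94 % within
two regression SEs); 100 replicates of the BCF null study (~95–96 % judged
not temperature-dependent at the nominal 5 % test size); and the scenario
property checks (peak ordering across temperatures with a ~3.3-fold
cold-to-warm range, post-peak crossing, DTF excess over the constant-mean
trajectory, convergence order, closed-form agreement). These replicate
counts keep the full validation under two minutes of compute while holding
Monte-Carlo standard errors on the reported percentages near two points.
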