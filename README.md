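# thermotk

Temperature-dependent toxicokinetics of aquatic invertebrates.

Ectotherms such as the amphipods *Gammarus pulex* and *Hyalella azteca* take
up and eliminate waterborne organic contaminants faster in warmer water.
`thermotk` is a Python library for analysing that temperature dependence
end to end: it fits one-compartment toxicokinetic models to bioconcentration
time series, scales the fitted rate constants across temperature with the
Arrhenius equation, tests whether bioconcentration factors depend on
temperature, and simulates body burdens under time-varying field scenarios
(exposure peaks, daily temperature fluctuations).

## Models

**Parent model.** The internal (tissue) concentration `C_p` (µmol/kg wet
weight) of a parent compound follows first-order kinetics

```
dC_p/dt = C_w(t)·k_u − C_p·k_e
```

with uptake rate `k_u` (L kg⁻¹ d⁻¹), total elimination rate `k_e` (d⁻¹) and
water concentration `C_w(t)` (constant during a 1-day uptake phase, zero
during elimination).

**Biotransformation model.** Total elimination splits into excretion
`k_e,p` and primary biotransformation `k_m,1st`; biotransformation products
(BTPs) are pooled into a primary and a secondary state:

```
dC_p/dt   = C_w·k_u − C_p·(k_e,p + k_m,1st)
dC_m1/dt  = C_p·k_m,1st − C_m1·(k_e,1st + k_m,2nd)
dC_m2/dt  = C_m1·k_m,2nd − C_m2·k_e,2nd
```

All solutions are closed-form (sums of exponentials; exact matrix
exponential when loss rates coincide). Parameters are estimated by weighted
least squares (weights = animals pooled per sample), all rates
simultaneously, with 95 % profile-likelihood confidence intervals, AIC-based
model selection (ΔAIC < 2 resolved by the parent/primary-BTP R²), and the
derived quantities

```
BCF_kin = k_u/k_e   (or k_u/(k_e,p + k_m,1st))
BCF_24h = C_p(24 h)/C_w
t_1/2   = ln 2 / k_e          t_ss,95 = ln 20 / k_e
```

**Arrhenius analysis.** Any positive rate `k` measured at several absolute
temperatures is summarised by `ln k = −T_A·(1/T) + ln A`; the Arrhenius
temperature `T_A` (K) is minus the OLS slope. A linear regression of
`BCF_kin` on temperature with a two-sided zero-slope t-test (α = 0.05)
decides whether the bioconcentration factor itself is temperature-dependent
(it is not when `k_u` and `k_e` share a common `T_A`).

**Scenario simulation.** `dC/dt = C_w(t)·k_u(T(t)) − C·k_e(T(t))` with
`k(T) = A·e^(−T_A/T)`, temperature/exposure given as breakpoint profiles
(linear or hold interpolation), integrated with fixed-step Heun
(second-order predictor–corrector).

A synthetic-data module generates complete studies with known truth — four
temperatures (6.1, 11.0, 15.4, 21.2 °C), 50 µg/L exposure, duplicate
samples of 4 (*G. pulex*) or 15 (*H. azteca*) pooled animals, lognormal
measurement noise, LOQ censoring, Arrhenius-structured true rates — so
every stage of the pipeline is testable without external data.

## Worked example

`python examples/fit_bioconcentration.py` fits the parent model at each of
the four study temperatures of a synthetic experiment (truth: common
T_A = 8000 K, `k_u` = 20 L/kg/d and `k_e` = 1/d at 11 °C, 20 % noise):

```
 T (C)     k_u             CI95    k_e           CI95  BCF_kin  t1/2 (d) t_ss95 (d)
   6.1   12.93 [ 11.89,  14.03]  0.626 [0.542, 0.719]    20.66      1.11       4.79
  11.0   19.16 [ 17.07,  21.51]  1.042 [0.869, 1.256]    18.39      0.67       2.88
  15.4   30.59 [ 27.35,  34.34]  1.479 [1.250, 1.766]    20.68      0.47       2.03
  21.2   46.81 [ 40.66,  54.85]  2.455 [2.018, 3.054]    19.07      0.28       1.22
```

Both rates roughly double per 10 °C while their ratio — the kinetic
bioconcentration factor — stays near the true 20 L/kg: with a common
Arrhenius temperature the rate effects cancel. Note that equilibrium is
reached within a day at 21 °C but takes almost five days at 6 °C.

`python examples/exposure_scenarios.py` runs a 7-hour 50 µg/L run-off pulse
at four constant temperatures and prints the peak body burdens
(165.6 → 541.0, a 3.3-fold increase from 6 to 21 °C, with the warm
trajectory crossing below the cold one at t ≈ 1.1 d once elimination takes
over), and a daily-temperature-fluctuation scenario that runs ~2 % ahead of
the constant-mean trajectory during the first, pre-equilibrium day.

`python examples/arrhenius_analysis.py` recovers the Arrhenius temperature
from a synthetic respirometry table and from fitted uptake rates, and runs
the BCF trend test.

There is also a thin CLI (`thermotk generate | fit | arrhenius | simulate |
report`) for batch use; every run writes a JSON manifest with its
configuration hash and seed.

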