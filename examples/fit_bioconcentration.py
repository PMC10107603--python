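"""Fit the one-compartment model to a synthetic bioconcentration experiment.

Generates a four-temperature uptake/elimination study (1-day uptake at
50 ug/L, 3-day elimination, duplicate samples, 20 % measurement noise) from
a known Arrhenius truth, fits uptake and elimination rates at each
temperature, and prints the estimates with 95 % profile-likelihood CIs and
the derived quantities (kinetic BCF, half-life, time to 95 % steady state).
"""

import math

import thermotk as tk

truth = {
    # (T_A in K, ln A): rates anchored to k_u = 20 L/kg/d, k_e = 1/d at 11 C
    "k_u": (8000.0, math.log(20.0) + 8000.0 / 284.15),
    "k_e": (8000.0, 8000.0 / 284.15),
}
config = tk.TruthConfig(arrhenius=truth, species="H. azteca",
                        compound="demo", cv_tissue=0.2, cv_medium=0.05,
                        seed=11)
datasets, true_params = tk.generate_experiment(config)

print(f"{'T (C)':>6} {'k_u':>7} {'CI95':>16} {'k_e':>6} {'CI95':>14} "
      f"{'BCF_kin':>8} {'t1/2 (d)':>9} {'t_ss95 (d)':>10}")
for ds in datasets:
    fit = tk.fit_parent(ds)
    lo_u, hi_u = tk.profile_ci(fit, ds, "k_u")
    lo_e, hi_e = tk.profile_ci(fit, ds, "k_e")
    p = fit.estimates
    print(f"{ds.temperature_C:6.1f} {p.k_u:7.2f} "
          f"[{lo_u:6.2f}, {hi_u:6.2f}] {p.k_e:6.3f} "
          f"[{lo_e:5.3f}, {hi_e:5.3f}] {tk.bcf_kin(p):8.2f} "
          f"{tk.half_life(p.k_e):9.2f} {tk.time_to_ss95(p.k_e):10.2f}")

print("\nRates roughly double per 10 C (T_A = 8000 K) while BCF_kin stays "
      "near 20 L/kg:\nboth rates share the same temperature scaling, so "
      "their ratio is temperature-stable.")
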