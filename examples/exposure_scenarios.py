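"""Internal concentrations under environmental exposure scenarios.

Two scenarios driven by Arrhenius-scaled rates (Heun integration):

1. A short run-off exposure pulse (50 ug/L for ~7 h) compared across the
   four study temperatures: warmer water takes up more during the pulse
   (higher peak) but also eliminates faster afterwards, so the warm
   trajectory crosses below the cold one.
2. A daily temperature fluctuation (DTF, 11-21 C) around a 16 C mean at
   constant exposure, compared with a constant 16 C scenario: the convex
   temperature dependence of the rates makes the fluctuating trajectory run
   ahead of the constant-mean one before equilibration.
"""

import math

import thermotk as tk

T_A = 8000.0
ku = (T_A, math.log(20.0) + T_A / 284.15)  # 20 L/kg/d at 11 C
ke = (T_A, T_A / 284.15)                   # 1 /d at 11 C

# --- scenario 1: exposure pulse at four constant temperatures
span = (0.0, 3.0)
pulse = tk.pulse_exposure_profile(c_peak=50.0, t_on=0.2, t_off=0.5,
                                  t0=0.0, t1=3.0, ramp=0.002)
specs = [tk.ScenarioSpec(ku, ke, tk.constant_profile(T + 273.15, 0.0, 3.0),
                         pulse, span, step=0.002, label=f"{T:.0f} C")
         for T in (6.0, 11.0, 16.0, 21.0)]
cmp = tk.compare_scenarios(specs)
print("pulse exposure, peak internal concentration by temperature:")
for r in cmp.results:
    print(f"  {r.label}: peak {r.peak:7.1f} at t = {r.t_peak:.2f} d")
print(f"warm/cold peak ratio: {cmp.peak_ratio[(3, 0)]:.2f}x; "
      f"warm curve falls below cold at t = {cmp.crossing_time[(3, 0)]:.2f} d")

# --- scenario 2: daily temperature fluctuation vs constant mean
span = (0.0, 2.0)
expo = tk.constant_profile(50.0, *span, kind="exposure")
const = tk.constant_profile(289.15, *span)
dtf = tk.dtf_profile(mean_T=289.15, range_T=10.0, t_span=span,
                     phase="warming-first")
r_const = tk.simulate(tk.ScenarioSpec(ku, ke, const, expo, span, step=0.001))
r_dtf = tk.simulate(tk.ScenarioSpec(ku, ke, dtf, expo, span, step=0.001))
i_day1 = int(1.0 / 0.001)
print("\nDTF vs constant 16 C (constant 50 ug/L exposure):")
print(f"  internal concentration after 1 d: "
      f"DTF {r_dtf.concentration[i_day1]:.1f}, "
      f"constant {r_const.concentration[i_day1]:.1f} "
      f"({r_dtf.concentration[i_day1] / r_const.concentration[i_day1]:.3f}x)")
print("The fluctuating scenario accumulates faster before equilibrium — "
      "uptake gains during\nwarm periods outweigh losses during cool ones.")
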