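"""Whole-pipeline self-checks on synthetic data with known truth.

Each function here runs one seeded simulation study end to end — generate,
fit, analyse — and reports summary statistics (biases, coverages, rejection
rates, integration errors).  The closed-form solutions are always checked
against an independent adaptive Runge-Kutta solve (scipy ``solve_ivp``),
never against themselves.

Problem sizes default to the scale of the emulated study design (four
temperatures, duplicate samples, 20 % measurement CV); the replicate counts
are chosen so every study finishes in minutes on one core.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from . import arrhenius as arr
from . import fitting, scenario, synthetic, tk_models

__all__ = [
    "oracle_sweep",
    "recovery_study",
    "arrhenius_study",
    "bcf_null_study",
    "scenario_checks",
    "default_truth",
]

REL_FLOOR = 1e-6  # relative errors evaluated above this fraction of the peak


def default_truth(T_A: float = 8000.0, k_u_ref: float = 20.0,
                  k_e_ref: float = 1.0, T_ref: float = 284.15) -> dict:
    """Common-T_A Arrhenius truth anchored at the reference temperature."""
    return {
        "k_u": (T_A, math.log(k_u_ref) + T_A / T_ref),
        "k_e": (T_A, math.log(k_e_ref) + T_A / T_ref),
    }


def _rel_err(got: np.ndarray, oracle: np.ndarray) -> float:
    scale = np.maximum(np.abs(oracle), REL_FLOOR * np.max(np.abs(oracle)))
    return float(np.max(np.abs(got - oracle) / np.maximum(scale, 1e-300)))


def _piecewise_solve(rhs, n_states, t_eval, d, rtol=1e-11):
    """Adaptive implicit solve split at the exposure discontinuity.

    Integrating the uptake and elimination phases separately keeps the
    reference solution accurate for stiff rate combinations; Radau handles
    loss rates up to the sweep's upper bound without stability loss.
    """
    td = d.t_depuration_start
    out = np.empty((len(t_eval), n_states))
    t_up = t_eval[t_eval <= td]
    grid_up = np.unique(np.append(t_up, td))
    sol = solve_ivp(lambda t, y: rhs(t, y, d.c_water_uptake), (0.0, td),
                    np.zeros(n_states), t_eval=grid_up, rtol=rtol,
                    atol=1e-14, method="Radau")
    for i, t in enumerate(t_up):
        out[i] = sol.y[:, np.searchsorted(grid_up, t)]
    y_td = sol.y[:, -1]
    t_el = t_eval[t_eval > td]
    if len(t_el):
        sol = solve_ivp(lambda t, y: rhs(t, y, 0.0), (td, float(t_el[-1])),
                        y_td, t_eval=t_el, rtol=rtol, atol=1e-14,
                        method="Radau")
        out[len(t_up):] = sol.y.T
    return out


def oracle_sweep(n_points: int = 100, seed: int = 0) -> dict:
    """Closed forms vs an adaptive Runge-Kutta solve over random rates.

    Draws ``n_points`` parameter sets with rates log-uniform in
    [1e-3, 1e2] and returns the worst relative error (percent) of the
    parent and cascade solutions against ``solve_ivp``.
    """
    rng = np.random.default_rng(seed)
    d = tk_models.ExposureDesign(1.0, 1.0, 4.0)
    t_eval = np.array([0.25, 0.75, 1.0, 1.5, 2.5, 4.0])
    worst_parent = 0.0
    worst_cascade = 0.0
    for _ in range(n_points):
        rates = 10.0 ** rng.uniform(-3, 2, size=6)
        p = tk_models.ParentParams(rates[0], rates[1])

        def rhs_p(t, y, cw, p=p):
            return [cw * p.k_u - y[0] * p.k_e]

        oracle = _piecewise_solve(rhs_p, 1, t_eval, d)
        worst_parent = max(worst_parent, _rel_err(
            tk_models.parent_conc(t_eval, p, d), oracle[:, 0]))

        bp = tk_models.BiotransParams(*rates)
        lp, l1, l2 = bp.loss_rates

        def rhs_c(t, y, cw, bp=bp, lp=lp, l1=l1, l2=l2):
            return [cw * bp.k_u - y[0] * lp,
                    y[0] * bp.k_m_1st - y[1] * l1,
                    y[1] * bp.k_m_2nd - y[2] * l2]

        oracle = _piecewise_solve(rhs_c, 3, t_eval, d)
        worst_cascade = max(worst_cascade, _rel_err(
            tk_models.cascade_conc(t_eval, bp, d), oracle))
    return {
        "max_rel_err_parent_pct": 100.0 * worst_parent,
        "max_rel_err_cascade_pct": 100.0 * worst_cascade,
        "n": n_points,
    }


def recovery_study(n_datasets: int = 200, cv: float = 0.2,
                   seed: int = 0) -> dict:
    """Parameter recovery and profile-CI coverage at the study design.

    Generates ``n_datasets`` single-temperature experiments (cycling through
    the four study temperatures, duplicate samples, lognormal noise of the
    given CV), fits the parent model to each, profiles k_u, and reports the
    median relative biases (percent) and the fraction of 95 % profile
    intervals covering the true k_u (percent).
    """
    truth_arr = default_truth()
    temps = synthetic.DEFAULT_TEMPERATURES_C
    bias_ku, bias_ke, cover = [], [], []
    for i in range(n_datasets):
        T_C = temps[i % len(temps)]
        tc = synthetic.TruthConfig(
            arrhenius=truth_arr, temperatures_C=(T_C,), cv_tissue=cv,
            cv_medium=0.05, seed=seed + i)
        datasets, truth = synthetic.generate_experiment(tc)
        ds, p_true = datasets[0], truth[T_C]
        fr = fitting.fit_parent(ds)
        bias_ku.append(fr.estimates.k_u / p_true.k_u - 1.0)
        bias_ke.append(fr.estimates.k_e / p_true.k_e - 1.0)
        lo, hi = fitting.profile_ci(fr, ds, "k_u")
        cover.append(lo <= p_true.k_u <= hi)
    return {
        # bias = systematic error: magnitude of the median signed deviation
        "median_rel_bias_ku_pct": 100.0 * abs(float(np.median(bias_ku))),
        "median_rel_bias_ke_pct": 100.0 * abs(float(np.median(bias_ke))),
        "profile_ci_coverage_ku_pct": 100.0 * float(np.mean(cover)),
        "n": n_datasets,
    }


def arrhenius_study(n_rep: int = 100, sigma: float = 0.1,
                    T_A: float = 8000.0, n_chambers: int = 8,
                    seed: int = 0) -> dict:
    """Arrhenius-temperature recovery from noise-free and noisy rate tables.

    Noise-free: the regression must return the generating T_A to floating-
    point accuracy.  Noisy: ``n_rep`` tables (four temperatures,
    ``n_chambers`` replicate rows each, multiplicative lognormal noise of
    log-scale ``sigma``) are fitted and the fraction with |T_A_hat - T_A|
    within two regression SEs is reported (percent).
    """
    temps = arr.celsius_to_kelvin(np.array(synthetic.DEFAULT_TEMPERATURES_C))
    ln_A = 2.0 + T_A / 284.15
    exact = arr.arrhenius_fit(arr.RateTable(
        temps, np.exp(ln_A - T_A / temps)))
    rng = np.random.default_rng(seed)
    T_rep = np.repeat(temps, n_chambers)
    hits = 0
    for _ in range(n_rep):
        rates = np.exp(ln_A - T_A / T_rep + rng.normal(0, sigma, T_rep.size))
        af = arr.arrhenius_fit(arr.RateTable(T_rep, rates))
        hits += abs(af.T_A - T_A) <= 2.0 * af.se_T_A
    return {
        "noise_free_rel_err": abs(exact.T_A - T_A) / T_A,
        "within_2se_pct": 100.0 * hits / n_rep,
        "n": n_rep,
    }


def bcf_null_study(n_rep: int = 100, cv: float = 0.2, seed: int = 0) -> dict:
    """False-detection rate of the BCF trend test under the common-T_A null.

    With the same Arrhenius temperature for uptake and elimination the true
    BCF_kin is constant across temperatures; each replicate generates the
    four-temperature experiment, fits every temperature, computes BCF_kin
    and applies the trend test.  Returns the percentage of replicates judged
    not temperature-dependent (nominal 95 %).
    """
    truth_arr = default_truth()
    not_dep = 0
    for i in range(n_rep):
        tc = synthetic.TruthConfig(arrhenius=truth_arr, cv_tissue=cv,
                                   cv_medium=0.05, seed=seed + i)
        datasets, _ = synthetic.generate_experiment(tc)
        pairs = []
        for ds in datasets:
            fr = fitting.fit_parent(ds)
            pairs.append((ds.temperature_K, tk_models.bcf_kin(fr.estimates)))
        res = arr.bcf_trend(pairs)
        not_dep += res.verdict == "not temperature-dependent"
    return {"not_temperature_dependent_pct": 100.0 * not_dep / n_rep,
            "n": n_rep}


def scenario_checks(T_A: float = 8000.0, step: float = 0.002) -> dict:
    """Qualitative and numerical properties of the scenario integrator.

    Runs a rectangular exposure pulse at the four study temperatures
    (common-T_A rates), a DTF-versus-constant-mean comparison, a Richardson
    step-halving estimate of the convergence order, and a constant-condition
    comparison against the closed form.
    """
    truth_arr = default_truth(T_A)
    span = (0.0, 3.0)
    expo = scenario.pulse_exposure_profile(50.0, 0.2, 0.5, 0.0, 3.0,
                                           ramp=step)
    specs = []
    for T_C in synthetic.DEFAULT_TEMPERATURES_C:
        temp = scenario.constant_profile(T_C + 273.15, 0.0, 3.0)
        specs.append(scenario.ScenarioSpec(
            truth_arr["k_u"], truth_arr["k_e"], temp, expo, span, step=step,
            label=f"{T_C} C"))
    cmp = scenario.compare_scenarios(specs)
    peaks = cmp.peak
    coldest, warmest = 0, len(peaks) - 1
    crossing = cmp.crossing_time[(warmest, coldest)]

    # DTF vs constant mean over the first (pre-equilibrium) day
    dtf_span = (0.0, 1.0)
    expo_c = scenario.constant_profile(50.0, 0.0, 1.0, kind="exposure")
    const = scenario.constant_profile(289.15, 0.0, 1.0)
    dtf = scenario.dtf_profile(289.15, 10.0, t_span=dtf_span)
    r_const = scenario.simulate(scenario.ScenarioSpec(
        truth_arr["k_u"], truth_arr["k_e"], const, expo_c, dtf_span,
        step=0.001))
    r_dtf = scenario.simulate(scenario.ScenarioSpec(
        truth_arr["k_u"], truth_arr["k_e"], dtf, expo_c, dtf_span,
        step=0.001))

    # convergence order on a smooth profile, Richardson against a tight
    # adaptive solve
    temp_s = scenario.dtf_profile(289.15, 10.0, t_span=(0.0, 2.0),
                                  breakpoints_per_period=480)
    expo_s = scenario.constant_profile(1.0, 0.0, 2.0, kind="exposure")

    def final(h):
        return scenario.simulate(scenario.ScenarioSpec(
            truth_arr["k_u"], truth_arr["k_e"], temp_s, expo_s, (0.0, 2.0),
            step=h)).concentration[-1]

    def rhs(t, y):
        T = scenario.interpolate(temp_s, t)
        return [scenario.interpolate(expo_s, t)
                * arr.rate_at_temperature(truth_arr["k_u"], T)
                - y[0] * arr.rate_at_temperature(truth_arr["k_e"], T)]

    exact = solve_ivp(rhs, (0.0, 2.0), [0.0], rtol=1e-11, atol=1e-13,
                      max_step=0.01, method="DOP853").y[0, -1]
    e1, e2 = abs(final(0.004) - exact), abs(final(0.002) - exact)
    order = math.log2(e1 / e2)

    # constant conditions vs closed form (smooth case, step 0.01)
    d_up = tk_models.ExposureDesign(1.0, 4.0, 4.0)
    p_ref = tk_models.ParentParams(10.0, 1.0)
    res = scenario.simulate(scenario.ScenarioSpec(
        (0.0, math.log(10.0)), (0.0, 0.0),
        scenario.constant_profile(289.15, 0.0, 4.0),
        scenario.constant_profile(1.0, 0.0, 4.0, kind="exposure"),
        (0.0, 4.0), step=0.01))
    closed = tk_models.parent_conc(res.times, p_ref, d_up)
    closed_err = float(np.max(np.abs(res.concentration[1:] - closed[1:])
                              / closed[1:]))

    return {
        "peaks_by_temperature": peaks,
        "peaks_strictly_increasing": bool(np.all(np.diff(peaks) > 0)),
        "peak_fold_range": peaks[warmest] / peaks[coldest],
        "post_peak_crossing_exists": crossing is not None,
        "crossing_time_day": crossing,
        "dtf_exceeds_constant_mean": bool(r_dtf.concentration[-1]
                                          > r_const.concentration[-1]),
        "dtf_over_constant_ratio": float(r_dtf.concentration[-1]
                                         / r_const.concentration[-1]),
        "convergence_order": order,
        "closed_form_max_rel_err_pct": 100.0 * closed_err,
    }
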