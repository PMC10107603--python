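"""Weighted simultaneous fitting, profile likelihoods and model selection."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import thermotk as tk
from thermotk.fitting import InsufficientDataError, _collect, _design_for_fit
from thermotk.synthetic import BIOTRANS_PRESETS


def make_parent_dataset(k_u=20.0, k_e=2.0, cv=0.0, seed=0, **kw):
    tc = tk.TruthConfig(
        rates_per_temperature={11.0: tk.ParentParams(k_u, k_e)},
        temperatures_C=(11.0,), cv_tissue=cv, cv_medium=0.0, seed=seed, **kw)
    datasets, truth = tk.generate_experiment(tc)
    return datasets[0], truth[11.0]


class TestFitParent:
    def test_noise_free_recovery(self, parent_truth_dataset):
        ds, truth = parent_truth_dataset
        fr = tk.fit_parent(ds)
        assert fr.converged
        assert fr.estimates.k_u == pytest.approx(truth.k_u, rel=1e-4)
        assert fr.estimates.k_e == pytest.approx(truth.k_e, rel=1e-4)

    def test_all_zero_tissue_gives_zero_uptake(self, parent_truth_dataset):
        ds, _ = parent_truth_dataset
        obs = [tk.TKObservation(o.time, o.state, 0.0 if o.state == "parent"
                                else o.concentration, o.replicate_id,
                                o.n_animals) for o in ds.observations]
        ds0 = tk.TKDataset(ds.species, ds.compound, ds.temperature_K,
                           ds.design, obs)
        fr = tk.fit_parent(ds0)
        assert fr.estimates.k_u == 0.0

    def test_weights_scale_invariance(self):
        ds, _ = make_parent_dataset(cv=0.2, seed=5)
        fr1 = tk.fit_parent(ds)
        obs = [tk.TKObservation(o.time, o.state, o.concentration,
                                o.replicate_id, o.n_animals * 7,
                                o.below_loq, o.loq)
               for o in ds.observations]
        ds7 = tk.TKDataset(ds.species, ds.compound, ds.temperature_K,
                           ds.design, obs)
        fr7 = tk.fit_parent(ds7)
        assert fr7.estimates.k_u == pytest.approx(fr1.estimates.k_u, rel=1e-6)
        assert fr7.estimates.k_e == pytest.approx(fr1.estimates.k_e, rel=1e-6)

    def test_objective_invariant_to_observation_order(self):
        ds, _ = make_parent_dataset(cv=0.2, seed=11)
        rng = np.random.default_rng(0)
        shuffled = list(ds.observations)
        rng.shuffle(shuffled)
        ds_sh = tk.TKDataset(ds.species, ds.compound, ds.temperature_K,
                             ds.design, shuffled)
        assert tk.fit_parent(ds_sh).weighted_ssq == pytest.approx(
            tk.fit_parent(ds).weighted_ssq, rel=1e-9)

    def test_insufficient_phase_coverage_refused(self, design):
        obs = [tk.TKObservation(t, "parent", 1.0) for t in (0.2, 0.8)]
        ds = tk.TKDataset("sp", "c", 284.15, design, obs)
        with pytest.raises(InsufficientDataError):
            tk.fit_parent(ds)

    def test_uptake_cw_is_mean_of_measured_medium(self):
        ds, _ = make_parent_dataset(cv=0.0, seed=0, medium_drift=0.2)
        meas = [o.concentration for o in ds.observations
                if o.state == "medium" and o.time <= 1.0]
        assert _design_for_fit(ds).c_water_uptake == pytest.approx(
            np.mean(meas))


class TestFitBiotrans:
    def test_noise_free_recovery_all_six_rates(self):
        truth = tk.BiotransParams(20.0, 1.0, 0.8, 0.5, 0.3, 0.6)
        tc = tk.TruthConfig(rates_per_temperature={11.0: truth},
                            temperatures_C=(11.0,), cv_tissue=0.0,
                            cv_medium=0.0, seed=1)
        dss, _ = tk.generate_btp_cascade(tc)
        fr = tk.fit_biotrans(dss[0])
        for name in fr.free_params:
            assert getattr(fr.estimates, name) == pytest.approx(
                getattr(truth, name), rel=1e-3), name

    def test_without_btp2_rates_fixed_and_excluded(self):
        truth = tk.BiotransParams(20.0, 1.0, 0.8, 0.5, 0.0, 0.0)
        tc = tk.TruthConfig(rates_per_temperature={11.0: truth},
                            temperatures_C=(11.0,), cv_tissue=0.0,
                            cv_medium=0.0, seed=1)
        dss, _ = tk.generate_btp_cascade(tc)
        # drop all btp2 rows (they are identically zero anyway)
        obs = [o for o in dss[0].observations if o.state != "btp2"]
        ds = tk.TKDataset(dss[0].species, dss[0].compound,
                          dss[0].temperature_K, dss[0].design, obs)
        fr = tk.fit_biotrans(ds)
        assert fr.n_params == 4
        assert fr.estimates.k_m_2nd == 0.0
        assert fr.estimates.k_e_2nd == 0.0

    def test_nested_consistency_with_parent_model(self):
        # cascade generated without biotransformation: total elimination of
        # the cascade fit must reproduce the parent fit within its CI
        tc = tk.TruthConfig(
            rates_per_temperature={11.0: BIOTRANS_PRESETS["none"]},
            temperatures_C=(11.0,), cv_tissue=0.2, cv_medium=0.0, seed=9,
            loq=0.05)
        dss, _ = tk.generate_btp_cascade(tc)
        ds = dss[0]
        pf = tk.fit_parent(ds)
        bf = tk.fit_biotrans(ds, loq_policy="half")
        lo, hi = tk.profile_ci(bf, ds, "k_m_1st", loq_policy="half")
        assert lo <= 0.05  # biotransformation share compatible with zero
        assert bf.estimates.k_total == pytest.approx(pf.estimates.k_e,
                                                     rel=0.15)

    def test_biotrans_share_recovery_under_noise(self):
        # biotransformation share k_m1/(k_ep + k_m1) recovered within 0.1
        truth = BIOTRANS_PRESETS["dominant"]
        share_true = truth.k_m_1st / truth.k_total
        shares = []
        for seed in range(12):
            tc = tk.TruthConfig(rates_per_temperature={11.0: truth},
                                temperatures_C=(11.0,), cv_tissue=0.2,
                                cv_medium=0.0, seed=seed)
            dss, _ = tk.generate_btp_cascade(tc)
            fr = tk.fit_biotrans(dss[0])
            shares.append(fr.estimates.k_m_1st / fr.estimates.k_total)
        assert abs(np.median(shares) - share_true) < 0.1


class TestGoodnessOfFit:
    def test_perfect_fit_r2_is_one(self, parent_truth_dataset):
        ds, truth = parent_truth_dataset
        fr = tk.fit_parent(ds)
        assert fr.r2["parent"] == pytest.approx(1.0, abs=1e-9)

    def test_mean_model_r2_is_zero(self):
        ds, _ = make_parent_dataset(cv=0.2, seed=3)
        t, c, w = ds.tissue("parent")
        cbar = np.sum(w * c) / np.sum(w)
        # a constant model at the weighted mean has R^2 exactly 0 by the
        # independently coded formula
        ss_res = np.sum(w * (c - cbar) ** 2)
        ss_tot = np.sum(w * (c - cbar) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.0)

    def test_matches_independent_recomputation(self):
        ds, _ = make_parent_dataset(cv=0.2, seed=13)
        fr = tk.fit_parent(ds)
        t, c, w = ds.tissue("parent")
        pred = tk.parent_conc(t, fr.estimates, _design_for_fit(ds))
        cbar = np.sum(w * c) / np.sum(w)
        expect = 1 - np.sum(w * (c - pred) ** 2) / np.sum(w * (c - cbar) ** 2)
        assert fr.r2["parent"] == pytest.approx(expect, rel=1e-12)

    def test_underdetermined_state_flagged_nan(self, parent_truth_dataset):
        ds, _ = parent_truth_dataset
        fr = tk.fit_parent(ds)
        obs = [o for o in ds.observations if o.state == "parent"][:1]
        tiny = tk.TKDataset(ds.species, ds.compound, ds.temperature_K,
                            ds.design, obs)
        assert math.isnan(tk.goodness_of_fit(fr, tiny)["parent"])


class TestProfileCI:
    def test_matches_brute_force_grid(self):
        # independent oracle: profile deviance over a fine k_u grid with a
        # scalar inner minimization over k_e, crossing located by bisection
        ds, _ = make_parent_dataset(cv=0.15, seed=21)
        fr = tk.fit_parent(ds)
        lo, hi = tk.profile_ci(fr, ds, "k_u")

        t, c, w, _ = _collect(ds, ("parent",), "drop")
        d = _design_for_fit(ds)
        n = len(c)

        def ssq_at(ku):
            def inner(log_ke):
                p = tk.ParentParams(ku, 10.0 ** log_ke)
                return float(np.sum(w * (tk.parent_conc(t, p, d) - c) ** 2))
            res = minimize_scalar(inner, bounds=(-6, 3), method="bounded",
                                  options={"xatol": 1e-10})
            return res.fun

        ssq0 = ssq_at(fr.estimates.k_u)

        def dev(ku):
            return n * math.log(ssq_at(ku) / ssq0)

        from scipy.optimize import brentq
        lo_oracle = brentq(lambda ku: dev(ku) - 3.8415, fr.estimates.k_u / 3,
                           fr.estimates.k_u, xtol=1e-6)
        hi_oracle = brentq(lambda ku: dev(ku) - 3.8415, fr.estimates.k_u,
                           fr.estimates.k_u * 3, xtol=1e-6)
        assert lo == pytest.approx(lo_oracle, rel=0.01)
        assert hi == pytest.approx(hi_oracle, rel=0.01)

    def test_quadratic_case_matches_analytic_interval(self):
        # near-zero noise keeps the objective quadratic across the interval;
        # the profile bound then equals the linearized +-z*SE interval with
        # z^2 = n (exp(3.84/n) - 1)
        ds, truth = make_parent_dataset(cv=0.01, seed=2, n_replicates=10)
        fr = tk.fit_parent(ds)
        lo, hi = tk.profile_ci(fr, ds, "k_u")

        t, c, w, _ = _collect(ds, ("parent",), "drop")
        d = _design_for_fit(ds)
        n = len(c)
        # numerical Jacobian of the weighted residuals at the optimum
        theta = np.array([fr.estimates.k_u, fr.estimates.k_e])
        eps = 1e-6

        def resid(th):
            return np.sqrt(w) * (tk.parent_conc(t, tk.ParentParams(*th), d) - c)

        J = np.column_stack([
            (resid(theta + eps * np.eye(2)[j]) - resid(theta - eps * np.eye(2)[j]))
            / (2 * eps * theta[j]) * theta[j]
            for j in range(2)])
        sigma2 = fr.weighted_ssq / n
        cov = sigma2 * np.linalg.inv(J.T @ J)
        z = math.sqrt(n * (math.exp(3.8415 / n) - 1.0))
        se = math.sqrt(cov[0, 0])
        assert hi - lo == pytest.approx(2 * z * se, rel=0.01)

    def test_zero_noise_interval_collapses(self, parent_truth_dataset):
        ds, truth = parent_truth_dataset
        fr = tk.fit_parent(ds)
        lo, hi = tk.profile_ci(fr, ds, "k_u")
        assert (hi - lo) / truth.k_u < 1e-3

    def test_unidentifiable_excretion_flagged_unbounded_low(self):
        # elimination dominated by biotransformation: the excretion rate's
        # profile is flat towards zero and the lower bound is reported as 0
        tc = tk.TruthConfig(
            rates_per_temperature={11.0: BIOTRANS_PRESETS["dominant"]},
            temperatures_C=(11.0,), cv_tissue=0.2, cv_medium=0.0, seed=4)
        dss, _ = tk.generate_btp_cascade(tc)
        fr = tk.fit_biotrans(dss[0])
        lo, hi = tk.profile_ci(fr, dss[0], "k_e_p")
        assert lo == 0.0
        assert fr.ci_flags["k_e_p"].startswith("unbounded-low")


class TestSelectModel:
    def _fit(self, model, aic, r2):
        return tk.FitResult(model, tk.ParentParams(1, 1), 1.0, 10, 2, aic,
                            r2, True)

    def test_single_candidate_returned(self):
        f = self._fit("parent", 10.0, {"parent": 0.9})
        assert tk.select_model(f, []) is f

    def test_clear_aic_winner_ignores_r2(self):
        a = self._fit("parent", 10.0, {"parent": 0.5})
        b = self._fit("biotrans", 15.0, {"parent": 0.99, "btp1": 0.99})
        assert tk.select_model(a, [b]) is a

    def test_tie_break_prefers_parent_and_primary_btp_r2(self):
        a = self._fit("biotrans", 10.0, {"parent": 0.9, "btp1": 0.8,
                                         "btp2": 0.99})
        b = self._fit("biotrans", 11.0, {"parent": 0.95, "btp1": 0.85,
                                         "btp2": 0.1})
        chosen = tk.select_model(None, [a, b])
        assert chosen is b  # secondary BTP R^2 plays no role
        assert any("tie-break" in s for s in chosen.selection_trace)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            tk.select_model(None, [])


class TestAIC:
    def test_aic_formula(self):
        ds, _ = make_parent_dataset(cv=0.2, seed=1)
        fr = tk.fit_parent(ds)
        n, k = fr.n_obs, fr.n_params
        assert fr.aic == pytest.approx(
            n * math.log(fr.weighted_ssq / n) + 2 * (k + 1))
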