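import numpy as np
import pytest

import thermotk as tk


@pytest.fixture
def design():
    """1-day uptake at unit concentration, 4-day experiment."""
    return tk.ExposureDesign(c_water_uptake=1.0, t_depuration_start=1.0,
                             t_end=4.0)


@pytest.fixture
def parent_params():
    return tk.ParentParams(k_u=10.0, k_e=1.0)


@pytest.fixture
def cascade_params():
    return tk.BiotransParams(k_u=10.0, k_e_p=0.5, k_m_1st=0.5, k_e_1st=0.3,
                             k_m_2nd=0.2, k_e_2nd=0.4)


def ode_parent(t_eval, p, d, rtol=1e-11):
    """Independent adaptive implicit solve of the parent ODE (piecewise at
    the exposure discontinuity, stiffness-safe)."""
    from thermotk.validation import _piecewise_solve

    def rhs(t, y, cw):
        return [cw * p.k_u - y[0] * p.k_e]

    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    return _piecewise_solve(rhs, 1, t_eval, d, rtol=rtol)[:, 0]


def ode_cascade(t_eval, p, d, rtol=1e-11):
    """Independent adaptive implicit solve of the three-state cascade."""
    from thermotk.validation import _piecewise_solve

    lp, l1, l2 = p.loss_rates

    def rhs(t, y, cw):
        return [
            cw * p.k_u - y[0] * lp,
            y[0] * p.k_m_1st - y[1] * l1,
            y[1] * p.k_m_2nd - y[2] * l2,
        ]

    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    return _piecewise_solve(rhs, 3, t_eval, d, rtol=rtol)


@pytest.fixture
def parent_truth_dataset():
    """Noise-free single-temperature dataset from known parent rates."""
    tc = tk.TruthConfig(
        rates_per_temperature={11.0: tk.ParentParams(20.0, 2.0)},
        temperatures_C=(11.0,), cv_tissue=0.0, cv_medium=0.0, seed=7)
    datasets, truth = tk.generate_experiment(tc)
    return datasets[0], truth[11.0]
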