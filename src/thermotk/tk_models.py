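"""One-compartment toxicokinetic models for aquatic invertebrates.

Internal (tissue) concentrations of a waterborne contaminant are described by
first-order kinetics: uptake from the surrounding medium at rate ``k_u``
(L/kg_ww/day) and loss at a total elimination rate ``k_e`` (1/day).  The
*parent model* tracks the parent compound only,

    dC_p/dt = C_water(t) * k_u - C_p * k_e,

while the *biotransformation model* splits total elimination into excretion
``k_e_p`` and primary biotransformation ``k_m_1st`` and adds two pooled
metabolite states (total primary and total secondary biotransformation
products, BTPs):

    dC_p/dt  = C_water * k_u - C_p * (k_e_p + k_m_1st)
    dC_m1/dt = C_p * k_m_1st - C_m1 * (k_e_1st + k_m_2nd)
    dC_m2/dt = C_m1 * k_m_2nd - C_m2 * k_e_2nd

The exposure design is a one-phase pulse: during the uptake phase the medium
holds a constant (average measured) concentration; during the elimination
phase the medium concentration is identically zero.  BTP accounting assumes
molar concentration units so that one mole of parent yields one mole of
primary BTP.

All solutions here are exact (sums of exponentials, or a matrix-exponential
evaluation when loss rates coincide); the numerical integrator lives in
:mod:`thermotk.scenario` and is reserved for time-varying conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ExposureDesign",
    "ParentParams",
    "BiotransParams",
    "StateTrajectory",
    "parent_conc",
    "cascade_conc",
    "bcf_kin",
    "bcf_24h",
    "half_life",
    "time_to_ss95",
    "NotComputable",
]

#: relative tolerance below which two cascade loss rates are treated as equal
#: (the partial-fraction closed form degenerates there)
EIGENVALUE_RTOL = 1e-8

#: below this, k_e is treated as exactly zero and the linear-uptake limit used
K_ZERO_FLOOR = 1e-12


class NotComputable(ValueError):
    """A derived quantity has no defined value for these parameters.

    Raised e.g. for a kinetic BCF when the total elimination rate is zero
    (elimination dominated by processes outside the model).
    """


@dataclass(frozen=True)
class ExposureDesign:
    """Pulse exposure: constant medium concentration, then clean water.

    Parameters
    ----------
    c_water_uptake
        Average medium concentration during the uptake phase.  Units are
        carried as a tag (``unit``) and must match the tissue unit family
        (molar units for biotransformation accounting).
    t_depuration_start
        Time (day) at which uptake ends and the medium concentration drops
        to zero.
    t_end
        End of the experiment (day).
    """

    c_water_uptake: float
    t_depuration_start: float = 1.0
    t_end: float = 4.0
    unit: str = "umol/L"

    def __post_init__(self) -> None:
        if not 0.0 < self.t_depuration_start <= self.t_end:
            raise ValueError(
                "require 0 < t_depuration_start <= t_end, got "
                f"{self.t_depuration_start} and {self.t_end}"
            )
        if self.c_water_uptake < 0:
            raise ValueError("c_water_uptake must be >= 0")

    def c_water(self, t):
        """Medium concentration at time ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        return np.where(t <= self.t_depuration_start, self.c_water_uptake, 0.0)


@dataclass(frozen=True)
class ParentParams:
    """Rates of the parent (one-compartment) model."""

    k_u: float  # L/kg_ww/day
    k_e: float  # 1/day

    def __post_init__(self) -> None:
        if self.k_u < 0 or self.k_e < 0:
            raise ValueError(f"rates must be >= 0, got k_u={self.k_u}, k_e={self.k_e}")

    @property
    def k_total(self) -> float:
        return self.k_e


@dataclass(frozen=True)
class BiotransParams:
    """Rates of the biotransformation-cascade model.

    ``k_e_p`` and ``k_m_1st`` partition the parent's total elimination;
    ``k_e_1st``/``k_m_2nd`` do the same for the primary BTP pool and
    ``k_e_2nd`` eliminates the secondary pool.
    """

    k_u: float
    k_e_p: float
    k_m_1st: float
    k_e_1st: float = 0.0
    k_m_2nd: float = 0.0
    k_e_2nd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_u", "k_e_p", "k_m_1st", "k_e_1st", "k_m_2nd", "k_e_2nd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def k_total(self) -> float:
        """Total parent elimination rate (excretion + biotransformation)."""
        return self.k_e_p + self.k_m_1st

    @property
    def loss_rates(self) -> tuple[float, float, float]:
        """Per-state loss rates (lambda_p, lambda_1, lambda_2)."""
        return (
            self.k_e_p + self.k_m_1st,
            self.k_e_1st + self.k_m_2nd,
            self.k_e_2nd,
        )


@dataclass
class StateTrajectory:
    """Tissue concentration time series, one column per model state."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_states)
    states: tuple[str, ...] = ("parent",)
    unit: str = "umol/kg_ww"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        if self.concentrations.shape[0] != self.times.shape[0]:
            self.concentrations = self.concentrations.T
        if self.concentrations.shape != (len(self.times), len(self.states)):
            raise ValueError("trajectory shape inconsistent with states")

    def state(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.states.index(name)]

    def to_frame(self):
        """Long-format DataFrame (time_day, state, concentration, unit)."""
        import pandas as pd

        rows = []
        for j, s in enumerate(self.states):
            rows.append(
                pd.DataFrame(
                    {
                        "time_day": self.times,
                        "state": s,
                        "concentration": self.concentrations[:, j],
                        "unit": self.unit,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _check_time(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("time must be >= 0")


def parent_conc(t, p: ParentParams, d: ExposureDesign):
    """Closed-form parent tissue concentration at time(s) ``t``.

    Uptake phase: ``C(t) = C_w * (k_u/k_e) * (1 - exp(-k_e t))``, with the
    linear limit ``C_w * k_u * t`` as ``k_e -> 0``.  Elimination phase:
    first-order decay from the concentration reached at the end of uptake.
    Continuous at the phase switch.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    _check_time(t)

    ku, ke = p.k_u, p.k_e
    cw = d.c_water_uptake
    td = d.t_depuration_start

    tu = np.minimum(t, td)
    if ke < K_ZERO_FLOOR:
        c_up = cw * ku * tu
        decay = np.ones_like(t)
    else:
        c_up = cw * (ku / ke) * -np.expm1(-ke * tu)
        decay = np.exp(-ke * np.maximum(t - td, 0.0))
    out = c_up * decay
    return float(out[0]) if scalar else out


def _phi(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """phi(lam, t) = (1 - exp(-lam t)) / lam, with the limit t at lam = 0."""
    lam = np.asarray(lam, dtype=float)
    shape = np.broadcast_shapes(lam.shape, np.shape(t))
    lam_b = np.broadcast_to(lam, shape)
    t_b = np.broadcast_to(t, shape)
    zero = lam_b == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(zero, t_b, -np.expm1(-lam_b * t_b) / np.where(zero, 1.0, lam_b))


def _rate_matrix(p: BiotransParams) -> np.ndarray:
    lp, l1, l2 = p.loss_rates
    return np.array(
        [
            [-lp, 0.0, 0.0],
            [p.k_m_1st, -l1, 0.0],
            [0.0, p.k_m_2nd, -l2],
        ]
    )


def _degenerate(p: BiotransParams) -> bool:
    lams = np.array(p.loss_rates)
    scale = max(lams.max(), 1.0e-30)
    d01 = abs(lams[0] - lams[1])
    d12 = abs(lams[1] - lams[2])
    d02 = abs(lams[0] - lams[2])
    # only pairs that actually couple matter, but be conservative: any near-tie
    return min(d01, d12, d02) < EIGENVALUE_RTOL * scale


def _cascade_closed(t: np.ndarray, p: BiotransParams, d: ExposureDesign) -> np.ndarray:
    """Sums-of-exponentials solution via eigendecomposition (distinct rates).

    The rate matrix is lower triangular with eigenvalues -lambda_i, so when
    the loss rates are pairwise distinct it diagonalizes exactly and the
    inhomogeneous solution is V diag(phi(lam, t)) V^-1 b, the homogeneous one
    V diag(exp(-lam t)) V^-1 C0.
    """
    M = _rate_matrix(p)
    lam, V = np.linalg.eig(M)  # lam = -loss rates (triangular)
    Vinv = np.linalg.inv(V)
    b = np.array([d.c_water_uptake * p.k_u, 0.0, 0.0])
    td = d.t_depuration_start

    tu = np.minimum(t, td)[:, None]  # time spent in the uptake phase
    te = np.maximum(t - td, 0.0)[:, None]  # time spent in the elimination phase

    beta = Vinv @ b
    # uptake-phase state at time tu: V phi(-lam, tu) beta
    up = (V @ (_phi(-lam[None, :], tu) * beta[None, :]).T).T
    # then decay of that state over te: V exp(lam te) Vinv C(td...)
    alpha = (Vinv @ up.T).T
    out = (V @ (np.exp(lam[None, :] * te) * alpha).T).T
    return np.real(out)


def _cascade_expm(t: np.ndarray, p: BiotransParams, d: ExposureDesign) -> np.ndarray:
    """Exact solution via the matrix exponential of an augmented system.

    Robust to coincident loss rates (degenerate eigenvalues), where the
    partial-fraction form is numerically unstable.
    """
    M = _rate_matrix(p)
    b = np.array([d.c_water_uptake * p.k_u, 0.0, 0.0])
    A = np.zeros((4, 4))
    A[:3, :3] = M
    A[:3, 3] = b
    td = d.t_depuration_start

    out = np.empty((len(t), 3))
    for i, ti in enumerate(t):
        tu = min(ti, td)
        x = expm(A * tu) @ np.array([0.0, 0.0, 0.0, 1.0])
        c = x[:3]
        te = ti - td
        if te > 0:
            c = expm(M * te) @ c
        out[i] = c
    return out


def cascade_conc(t, p: BiotransParams, d: ExposureDesign):
    """Tissue concentrations of (parent, btp1, btp2) at time(s) ``t``.

    Returns an array of shape ``(3,)`` for scalar ``t`` or ``(len(t), 3)``
    otherwise.  Molar units are assumed for the BTP stoichiometry.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    _check_time(t)

    if _degenerate(p):
        out = _cascade_expm(t, p, d)
    else:
        out = _cascade_closed(t, p, d)
    # clip tiny negative round-off
    out[(out < 0) & (out > -1e-12)] = 0.0
    return out[0] if scalar else out


def bcf_kin(p: ParentParams | BiotransParams) -> float:
    """Kinetic bioconcentration factor, k_u over total parent elimination.

    Raises
    ------
    NotComputable
        If the total elimination rate is zero: the kinetic BCF is undefined
        (elimination dominated by other processes).
    """
    k_total = p.k_total
    if k_total <= 0:
        raise NotComputable(
            "BCF_kin not computable; elimination dominated by other processes "
            "(total elimination rate is zero)"
        )
    return p.k_u / k_total


def bcf_24h(tissue_conc_24h: float, c_water_avg: float) -> float:
    """Apparent BCF after 24 h: tissue concentration over average medium
    concentration during uptake."""
    if c_water_avg <= 0:
        raise ValueError("average water concentration must be > 0")
    if tissue_conc_24h < 0:
        raise ValueError("tissue concentration must be >= 0")
    return tissue_conc_24h / c_water_avg


def half_life(k_total: float) -> float:
    """Elimination half-life, ln(2)/k (day)."""
    if k_total <= 0:
        raise NotComputable("no steady state reachable: total elimination rate <= 0")
    return math.log(2.0) / k_total


def time_to_ss95(k_total: float) -> float:
    """Time to 95 % of steady state, ln(20)/k (day).

    Solves 1 - exp(-k t) = 0.95 for a first-order system.
    """
    if k_total <= 0:
        raise NotComputable("no steady state reachable: total elimination rate <= 0")
    return math.log(20.0) / k_total
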