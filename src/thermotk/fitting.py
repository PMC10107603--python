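"""Weighted simultaneous estimation of toxicokinetic rate constants.

All model parameters are fitted simultaneously to the measured tissue
concentrations by minimizing a weighted sum of squares,

    SSQ_w = sum_i w_i (C_obs,i - C_model(t_i))^2,    w_i = n_animals_i,

which corresponds to independent normal errors with variance proportional to
1/n_animals (replicates pooling more animals are less noisy).  Optimization
is a deterministic multi-start: a Latin-hypercube over log-rates feeds a
bounded trust-region least-squares refinement, so results are reproducible.

Model comparison uses the least-squares AIC,

    AIC = n ln(SSQ_w / n) + 2 (K + 1),

counting the error variance as a parameter; candidates within two AIC units
of the best are resolved in favour of the higher mean R^2 over the parent
and primary-BTP states (the secondary-BTP pool is measured with the highest
uncertainty and does not take part in the tie-break).

Confidence intervals are profile likelihoods: each parameter in turn is
stepped along a grid while all other parameters are re-optimized, and the
95 % bound sits where the profiled deviance  n ln(SSQ_prof / SSQ_best)
crosses the chi-square(1) 0.95 quantile (3.84).  Flat profiles yield
unbounded intervals with a flag rather than an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .tk_models import (
    BiotransParams,
    ExposureDesign,
    ParentParams,
    cascade_conc,
    parent_conc,
)

__all__ = [
    "TKObservation",
    "TKDataset",
    "FitResult",
    "fit_parent",
    "fit_biotrans",
    "profile_ci",
    "select_model",
    "goodness_of_fit",
    "InsufficientDataError",
]

CHI2_1_95 = 3.841458820694124  # chi-square(1) 0.95 quantile
LOG_RATE_BOUNDS = (-3.0, 3.0)  # log10 bounds of the multi-start hypercube
N_STARTS = 8

TISSUE_STATES = ("parent", "btp1", "btp2")
STATES = TISSUE_STATES + ("medium",)


class InsufficientDataError(ValueError):
    """The dataset does not cover both phases well enough for a fit."""


@dataclass(frozen=True)
class TKObservation:
    """A single measured concentration.

    ``state`` is one of ``parent``, ``btp1``, ``btp2`` (tissue,
    µmol/kg_ww) or ``medium`` (water, µmol/L).  ``n_animals`` is the number
    of pooled animals in a tissue sample and sets the fitting weight.
    """

    time: float
    state: str
    concentration: float
    replicate_id: str = "r1"
    n_animals: int = 1
    below_loq: bool = False
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.below_loq and self.concentration < 0:
            raise ValueError("concentration must be >= 0 unless censored")
        if self.state in TISSUE_STATES and self.n_animals < 1:
            raise ValueError("tissue observations need n_animals >= 1")


@dataclass
class TKDataset:
    """One compound x species x temperature bioconcentration experiment."""

    species: str
    compound: str
    temperature_K: float
    design: ExposureDesign
    observations: list[TKObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [o for o in self.observations if o.time > self.design.t_end + 1e-9]
        if bad:
            raise ValueError(
                f"{len(bad)} observation(s) beyond the experiment end "
                f"t={self.design.t_end}"
            )

    @property
    def temperature_C(self) -> float:
        return self.temperature_K - 273.15

    def tissue(self, state: str, loq_policy: str = "drop"):
        """(times, concentrations, weights) for one tissue state.

        ``loq_policy``: ``drop`` removes censored rows, ``half`` substitutes
        LOQ/2.
        """
        t, c, w = [], [], []
        for o in self.observations:
            if o.state != state:
                continue
            if o.below_loq:
                if loq_policy == "drop":
                    continue
                if loq_policy == "half":
                    if o.loq is None:
                        continue
                    t.append(o.time)
                    c.append(o.loq / 2.0)
                    w.append(o.n_animals)
                    continue
                raise ValueError(f"unknown loq_policy {loq_policy!r}")
            t.append(o.time)
            c.append(o.concentration)
            w.append(o.n_animals)
        return np.array(t), np.array(c), np.array(w, dtype=float)

    def n_dropped_loq(self) -> int:
        return sum(1 for o in self.observations if o.below_loq)

    def mean_medium_uptake(self) -> float:
        """Arithmetic mean of measured medium values in the uptake phase."""
        vals = [
            o.concentration
            for o in self.observations
            if o.state == "medium"
            and o.time <= self.design.t_depuration_start
            and not o.below_loq
        ]
        return float(np.mean(vals)) if vals else self.design.c_water_uptake

    def has_states(self) -> set[str]:
        """States with any observation, censored rows included."""
        return {o.state for o in self.observations}

    def check_phase_coverage(self, state: str = "parent") -> None:
        t, _, _ = self.tissue(state)
        td = self.design.t_depuration_start
        n_up = len(np.unique(t[t <= td]))
        n_el = len(np.unique(t[t > td]))
        if n_up < 2 or n_el < 2:
            raise InsufficientDataError(
                f"state {state!r}: need >= 2 distinct uptake-phase and >= 2 "
                f"elimination-phase time points, have {n_up} and {n_el}"
            )


@dataclass
class FitResult:
    """Outcome of a weighted least-squares toxicokinetic fit."""

    model: str  # "parent" | "biotrans"
    estimates: ParentParams | BiotransParams
    weighted_ssq: float
    n_obs: int
    n_params: int
    aic: float
    r2: dict[str, float]
    converged: bool
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    profile_curves: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    selection_trace: list[str] = field(default_factory=list)

    @property
    def free_params(self) -> tuple[str, ...]:
        if self.model == "parent":
            return ("k_u", "k_e")
        if self.n_params == 6:
            return ("k_u", "k_e_p", "k_m_1st", "k_e_1st", "k_m_2nd", "k_e_2nd")
        return ("k_u", "k_e_p", "k_m_1st", "k_e_1st")


def _aic(ssq: float, n: int, k: int) -> float:
    # guard against exactly-zero residuals on noise-free data
    return n * math.log(max(ssq, 1e-300) / n) + 2 * (k + 1)


def _design_for_fit(ds: TKDataset) -> ExposureDesign:
    """Design with uptake C_w replaced by the measured-medium average."""
    cw = ds.mean_medium_uptake()
    return replace(ds.design, c_water_uptake=cw)


def _collect(ds: TKDataset, states: tuple[str, ...], loq_policy: str):
    ts, cs, ws, idx = [], [], [], []
    for j, s in enumerate(states):
        t, c, w = ds.tissue(s, loq_policy)
        ts.append(t)
        cs.append(c)
        ws.append(w)
        idx.append(np.full(len(t), j))
    return (np.concatenate(ts), np.concatenate(cs), np.concatenate(ws),
            np.concatenate(idx))


def _multistart(residual, n_par, x0_list, seed=0):
    sampler = qmc.LatinHypercube(d=n_par, seed=seed)
    lo, hi = LOG_RATE_BOUNDS
    starts = list(x0_list) + list(qmc.scale(sampler.random(N_STARTS), lo, hi))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, method="trf",
                                bounds=(lo - 3, hi + 3), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    return best


def fit_parent(ds: TKDataset, loq_policy: str = "drop") -> FitResult:
    """Fit the parent one-compartment model (k_u, k_e) to a dataset.

    Rates are optimized in log10 space (positivity by construction) from a
    deterministic multi-start; the fit is weighted by the number of animals
    per replicate.
    """
    ds.check_phase_coverage("parent")
    d = _design_for_fit(ds)
    t, c, w, _ = _collect(ds, ("parent",), loq_policy)
    sw = np.sqrt(w)

    if np.all(c == 0):
        p = ParentParams(0.0, 0.0)
        return FitResult("parent", p, 0.0, len(c), 2,
                         _aic(0.0, len(c), 2), {"parent": 1.0}, True)

    def residual(x):
        p = ParentParams(10.0 ** x[0], 10.0 ** x[1])
        return sw * (parent_conc(t, p, d) - c)

    # heuristic start: BCF-scale guess from late-uptake plateau
    c24 = np.mean(c[t <= d.t_depuration_start][-2:]) if np.any(t <= d.t_depuration_start) else 1.0
    bcf0 = max(c24 / max(d.c_water_uptake, 1e-12), 1e-3)
    x0 = [math.log10(bcf0 * 1.0), 0.0]  # k_e ~ 1/day
    sol = _multistart(residual, 2, [x0])
    converged = sol is not None and sol.success
    if sol is None:
        raise RuntimeError("all optimization starts failed")
    p = ParentParams(10.0 ** sol.x[0], 10.0 ** sol.x[1])
    ssq = float(2 * sol.cost)
    fr = FitResult("parent", p, ssq, len(c), 2, _aic(ssq, len(c), 2), {},
                   converged)
    fr.r2 = goodness_of_fit(fr, ds, loq_policy)
    return fr


def fit_biotrans(ds: TKDataset, loq_policy: str = "drop") -> FitResult:
    """Fit the biotransformation cascade simultaneously to parent + BTP data.

    If no secondary-BTP observations are present, ``k_m_2nd`` and ``k_e_2nd``
    are fixed at zero and excluded from the parameter count.
    """
    ds.check_phase_coverage("parent")
    observed = {o.state for o in ds.observations}  # censored rows count
    has_btp2 = "btp2" in observed
    states = ("parent", "btp1", "btp2") if has_btp2 else ("parent", "btp1")
    if "btp1" not in observed:
        raise InsufficientDataError("biotransformation fit needs btp1 observations")
    d = _design_for_fit(ds)
    t, c, w, idx = _collect(ds, states, loq_policy)
    sw = np.sqrt(w)
    n_par = 6 if has_btp2 else 4

    def make_params(x):
        if has_btp2:
            return BiotransParams(*(10.0 ** x))
        return BiotransParams(10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2],
                              10.0 ** x[3], 0.0, 0.0)

    def residual(x):
        p = make_params(x)
        model = cascade_conc(t, p, d)
        return sw * (model[np.arange(len(t)), idx] - c)

    x0 = [0.5, 0.0, -0.5, -0.5] + ([-0.5, -0.5] if has_btp2 else [])
    sol = _multistart(residual, n_par, [x0])
    if sol is None:
        raise RuntimeError("all optimization starts failed")
    p = make_params(sol.x)
    ssq = float(2 * sol.cost)
    fr = FitResult("biotrans", p, ssq, len(c), n_par,
                   _aic(ssq, len(c), n_par), {}, bool(sol.success))
    fr.r2 = goodness_of_fit(fr, ds, loq_policy)
    return fr


def _model_curve(fit: FitResult, ds: TKDataset, state: str, t: np.ndarray,
                 loq_policy: str = "drop") -> np.ndarray:
    d = _design_for_fit(ds)
    if fit.model == "parent":
        if state != "parent":
            raise ValueError("parent model has only the parent state")
        return parent_conc(t, fit.estimates, d)
    j = TISSUE_STATES.index(state)
    return cascade_conc(t, fit.estimates, d)[:, j]


def goodness_of_fit(fit: FitResult, ds: TKDataset,
                    loq_policy: str = "drop") -> dict[str, float]:
    """Per-state weighted R^2 = 1 - SSQ_res/SSQ_tot.

    States with fewer than two observations map to ``nan`` (undefined).
    """
    states = ("parent",) if fit.model == "parent" else (
        tuple(s for s in TISSUE_STATES if s in ds.has_states() or s == "parent"))
    out: dict[str, float] = {}
    for s in states:
        t, c, w = ds.tissue(s, loq_policy)
        if len(c) < 2:
            out[s] = float("nan")
            continue
        pred = _model_curve(fit, ds, s, t, loq_policy)
        ss_res = float(np.sum(w * (c - pred) ** 2))
        cbar = float(np.sum(w * c) / np.sum(w))
        ss_tot = float(np.sum(w * (c - cbar) ** 2))
        out[s] = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("nan"))
    return out


def _refit_fixed(ds: TKDataset, fit: FitResult, param: str, value: float,
                 loq_policy: str, x0=None):
    """Weighted SSQ re-optimizing all parameters except ``param`` = value.

    Returns ``(ssq, x)`` so a profile walk can warm-start each refit from
    the previous grid point's inner optimum (continuation), which keeps the
    profiled objective from being overestimated far from the best fit.
    """
    d = _design_for_fit(ds)
    free = [q for q in fit.free_params if q != param]
    if fit.model == "parent":
        states = ("parent",)
    else:
        states = tuple(s for s in ("parent", "btp1", "btp2") if s in ds.has_states())
    t, c, w, idx = _collect(ds, states, loq_policy)
    sw = np.sqrt(w)

    def build(x):
        vals = {param: value}
        vals.update({q: 10.0 ** xi for q, xi in zip(free, x)})
        if fit.model == "parent":
            return ParentParams(vals["k_u"], vals["k_e"])
        return BiotransParams(
            vals["k_u"], vals["k_e_p"], vals["k_m_1st"],
            vals.get("k_e_1st", 0.0), vals.get("k_m_2nd", 0.0),
            vals.get("k_e_2nd", 0.0))

    def residual(x):
        p = build(x)
        if fit.model == "parent":
            model = parent_conc(t, p, d)
        else:
            model = cascade_conc(t, p, d)[np.arange(len(t)), idx]
        return sw * (model - c)

    if x0 is None:
        x0 = [math.log10(max(getattr(fit.estimates, q), 1e-6)) for q in free]
    sol = least_squares(residual, x0, method="trf",
                        bounds=(LOG_RATE_BOUNDS[0] - 3, LOG_RATE_BOUNDS[1] + 3),
                        xtol=1e-12, ftol=1e-12)
    return float(2 * sol.cost), sol.x


def profile_ci(fit: FitResult, ds: TKDataset, param: str,
               loq_policy: str = "drop", max_factor: float = 1e4,
               n_refine: int = 30) -> tuple[float, float]:
    """95 % profile-likelihood interval for one rate constant.

    Walks the parameter outward on a multiplicative grid, re-optimizing the
    remaining parameters at each value; the bound is where the profiled
    deviance n ln(SSQ/SSQ_best) crosses 3.84, refined by bisection.  A
    profile still below the threshold at ``max_factor`` times the estimate
    (or at a near-zero floor) is reported as unbounded: 0 or +inf, with the
    flag recorded in ``fit.ci_flags``.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    est = getattr(fit.estimates, param)
    n = fit.n_obs
    ssq0 = max(fit.weighted_ssq, 1e-300)

    warm = {"x": None}

    def deviance(value: float) -> float:
        ssq, x = _refit_fixed(ds, fit, param, value, loq_policy,
                              x0=warm["x"])
        warm["x"] = x
        return n * math.log(max(ssq, 1e-300) / ssq0)

    if est <= 0:
        est = 1e-6

    curve: list[tuple[float, float]] = []

    def bound(direction: int) -> tuple[float, str]:
        # direction -1: walk down; +1: walk up
        warm["x"] = None  # fresh continuation per direction
        factor_limit = max_factor
        v_in, v_out = est, est
        d_out = 0.0
        step = 1.6
        for _ in range(40):
            v_out = v_out / step if direction < 0 else v_out * step
            if direction < 0 and v_out < est / factor_limit:
                return (0.0, "unbounded-low")
            if direction > 0 and v_out > est * factor_limit:
                return (math.inf, "unbounded-high")
            d_out = deviance(v_out)
            curve.append((v_out, d_out))
            if d_out >= CHI2_1_95:
                break
            v_in = v_out
        else:
            return ((0.0, "unbounded-low") if direction < 0
                    else (math.inf, "unbounded-high"))
        lo, hi = (v_out, v_in) if direction < 0 else (v_in, v_out)
        # bisect in log space: deviance is monotone along the walk
        for _ in range(n_refine):
            mid = math.sqrt(lo * hi)
            dm = deviance(mid)
            crossed = dm >= CHI2_1_95
            if direction < 0:
                # walking down: lo side is past the crossing, hi side inside
                if crossed:
                    lo = mid
                else:
                    hi = mid
            else:
                if crossed:
                    hi = mid
                else:
                    lo = mid
        return (math.sqrt(lo * hi), "ok")

    lo_val, lo_flag = bound(-1)
    hi_val, hi_flag = bound(+1)
    fit.ci95[param] = (lo_val, hi_val)
    fit.ci_flags[param] = f"{lo_flag}/{hi_flag}"
    fit.profile_curves[param] = sorted(curve)
    return (lo_val, hi_val)


def select_model(parent_fit: FitResult | None,
                 biotrans_fits: list[FitResult] | None = None) -> FitResult:
    """Pick the final model: lowest AIC, with a tie-break within 2 units.

    Among candidates whose AIC lies within 2 of the best, the fit with the
    highest mean R^2 over the parent and primary-BTP states wins; the
    secondary BTP does not enter the tie-break.  The decision is recorded in
    ``selection_trace`` on the returned fit.
    """
    candidates = [f for f in ([parent_fit] + list(biotrans_fits or [])) if f is not None]
    if not candidates:
        raise ValueError("no candidate fits supplied")
    trace = []
    best_aic = min(f.aic for f in candidates)
    close = [f for f in candidates if f.aic - best_aic < 2.0]
    trace.append(
        f"{len(candidates)} candidate(s); best AIC {best_aic:.3f}; "
        f"{len(close)} within 2 AIC units")

    def tiebreak_r2(f: FitResult) -> float:
        vals = [f.r2.get(s) for s in ("parent", "btp1")]
        vals = [v for v in vals if v is not None and not math.isnan(v)]
        return float(np.mean(vals)) if vals else -math.inf

    winner = max(close, key=tiebreak_r2)
    if len(close) > 1:
        trace.append(
            f"tie-break on mean R2(parent, btp1): chose {winner.model} "
            f"with {tiebreak_r2(winner):.4f}")
    else:
        trace.append(f"chose {winner.model} by AIC")
    winner.selection_trace = trace
    return winner
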