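"""Arrhenius analysis of temperature-dependent rates.

Any positive rate (toxicokinetic rate constant, standard metabolic rate, ...)
that rises exponentially with temperature can be summarized by the Arrhenius
relationship

    k(T) = A * exp(-T_A / T),

where ``T`` is absolute temperature (K), ``T_A`` the Arrhenius temperature
(K, activation energy over the gas constant) and ``A`` the frequency factor.
``T_A`` is estimated as minus the slope of the ordinary least-squares
regression of ln k on 1/T.

The kinetic bioconcentration factor is the ratio k_u/k_e; when both rates
share the same Arrhenius temperature the ratio is independent of temperature.
:func:`bcf_trend` tests that: an OLS regression of BCF_kin on temperature with
a two-sided t-test of zero slope, declaring temperature dependence at
p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RateTable",
    "ArrheniusFit",
    "BCFTrendResult",
    "arrhenius_fit",
    "rate_at_temperature",
    "bcf_trend",
    "fold_change",
    "celsius_to_kelvin",
    "REFERENCE_TA",
]

#: Physiological Arrhenius temperatures (K) for report overlays: Add-my-Pet
#: database entries for the two amphipods plus the respirometry-derived value
#: for H. azteca.
REFERENCE_TA = {
    "G. pulex (AmP)": 10560.0,
    "H. azteca (AmP)": 10830.0,
    "H. azteca (respirometry)": 8030.0,
}

#: rates at or below this (1/day) are considered "close to zero" and excluded
#: from Arrhenius fitting (log undefined in any meaningful sense)
NEAR_ZERO_RATE = 1e-6


def celsius_to_kelvin(t_C):
    return np.asarray(t_C, dtype=float) + 273.15


@dataclass
class RateTable:
    """Rates of one kind measured at several temperatures.

    ``se`` entries are optional per-rate standard errors; ``weighted=True``
    in :func:`arrhenius_fit` uses them for 1/se^2 weighting (off by default).
    """

    temperature_K: np.ndarray
    rate: np.ndarray
    se: np.ndarray | None = None
    label: str = "k"
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    def exclude_near_zero(self, floor: float = NEAR_ZERO_RATE) -> "RateTable":
        """Drop rates at or below ``floor``, logging each exclusion.

        Mirrors the treatment of elimination rates that collapse to zero when
        biotransformation dominates total elimination: such estimates carry
        no usable temperature signal.
        """
        keep = self.rate > floor
        excl = list(self.exclusions)
        for T, k in zip(self.temperature_K[~keep], self.rate[~keep]):
            excl.append(
                f"{self.label} at {T - 273.15:.1f} C excluded: rate {k:.3g} "
                f"close to zero (<= {floor:g})")
        return RateTable(self.temperature_K[keep], self.rate[keep],
                         None if self.se is None else self.se[keep],
                         self.label, excl)


@dataclass
class ArrheniusFit:
    """Result of the ln k vs 1/T regression."""

    T_A: float
    ln_A: float
    se_T_A: float | None
    r2: float
    n: int
    residuals: np.ndarray
    label: str = "k"

    def predict(self, T_K):
        """Rate at absolute temperature(s) ``T_K`` from the fitted line."""
        return rate_at_temperature(self, T_K)


@dataclass
class BCFTrendResult:
    """Zero-slope test of BCF_kin against temperature."""

    slope: float  # L/kg_ww per K
    intercept: float
    p_value: float
    n: int

    @property
    def verdict(self) -> str:
        return ("temperature-dependent" if self.p_value < 0.05
                else "not temperature-dependent")


def arrhenius_fit(rt: RateTable, weighted: bool = False) -> ArrheniusFit:
    """OLS of ln(rate) on inverse temperature; T_A = -slope, ln A = intercept.

    The slope SE is reported only for n >= 3 (two points determine the line
    exactly).  ``weighted=True`` applies 1/se^2 weights via a scaled
    regression when the table carries standard errors.
    """
    T = rt.temperature_K
    k = rt.rate
    if len(np.unique(T)) < 2:
        raise ValueError("Arrhenius fit needs >= 2 distinct temperatures")
    if np.any(k <= 0):
        i = int(np.argmax(k <= 0))
        raise ValueError(
            f"non-positive rate {k[i]!r} at T = {T[i] - 273.15:.1f} C "
            f"(label {rt.label!r}): ln undefined")
    x = 1.0 / T
    y = np.log(k)
    if weighted and rt.se is not None:
        # delta method: var(ln k) ~ (se/k)^2
        w = (k / rt.se) ** 2
        W = np.sum(w)
        xbar = np.sum(w * x) / W
        ybar = np.sum(w * y) / W
        sxx = np.sum(w * (x - xbar) ** 2)
        slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        dof = len(x) - 2
        se_slope = (math.sqrt(np.sum(w * resid ** 2) / dof / sxx)
                    if dof > 0 else None)
        ss_tot = np.sum(w * (y - ybar) ** 2)
        r2 = 1.0 - np.sum(w * resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        resid = y - (intercept + slope * x)
        se_slope = res.stderr if len(x) >= 3 else None
        r2 = res.rvalue ** 2
    return ArrheniusFit(
        T_A=-float(slope),
        ln_A=float(intercept),
        se_T_A=None if se_slope is None else float(se_slope),
        r2=float(r2),
        n=len(x),
        residuals=resid,
        label=rt.label,
    )


def _ta_lna(af) -> tuple[float, float]:
    if isinstance(af, ArrheniusFit):
        return af.T_A, af.ln_A
    T_A, ln_A = af
    return float(T_A), float(ln_A)


def rate_at_temperature(af, T_K):
    """k(T) = A exp(-T_A / T) for an ArrheniusFit or a (T_A, ln_A) pair."""
    T = np.asarray(T_K, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be > 0")
    T_A, ln_A = _ta_lna(af)
    out = np.exp(ln_A - T_A / T)
    return float(out) if np.ndim(T_K) == 0 else out


def bcf_trend(bcfs) -> BCFTrendResult:
    """Linear regression of BCF_kin on temperature with a zero-slope t-test.

    ``bcfs`` is a sequence of (temperature_K, BCF) pairs; at least three
    distinct temperatures are required for the test to be defined.
    """
    arr = np.asarray(list(bcfs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (temperature_K, BCF) pairs")
    T, b = arr[:, 0], arr[:, 1]
    if len(np.unique(T)) < 3:
        raise ValueError("BCF trend test needs >= 3 distinct temperatures")
    res = stats.linregress(T, b)
    # identical BCFs: slope exactly 0, p-value degenerate -> report p = 1
    p = 1.0 if np.allclose(b, b[0]) else float(res.pvalue)
    return BCFTrendResult(float(res.slope), float(res.intercept), p, len(T))


def fold_change(af_or_pair, T_lo: float, T_hi: float) -> float:
    """Ratio of the predicted rate at ``T_hi`` versus ``T_lo`` (kelvin).

    For an Arrhenius fit (or a (T_A, ln_A) pair) this equals
    exp(T_A (1/T_lo - 1/T_hi)), independent of the frequency factor.  For a
    :class:`BCFTrendResult` the fitted line is evaluated at both endpoint
    temperatures and the ratio returned.
    """
    if T_lo <= 0 or T_hi <= 0:
        raise ValueError("absolute temperatures must be > 0")
    if isinstance(af_or_pair, BCFTrendResult):
        lo = af_or_pair.intercept + af_or_pair.slope * T_lo
        hi = af_or_pair.intercept + af_or_pair.slope * T_hi
        if lo <= 0:
            raise ValueError("fitted BCF non-positive at the lower temperature")
        return hi / lo
    T_A, _ = _ta_lna(af_or_pair)
    return math.exp(T_A * (1.0 / T_lo - 1.0 / T_hi))
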