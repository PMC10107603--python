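"""Synthetic bioconcentration experiments with known ground truth.

Emulates the design of a multi-temperature amphipod bioconcentration study:
four exposure temperatures (measured values 6.1, 11.0, 15.4 and 21.2 C), a
1-day uptake phase at a constant nominal exposure followed by up to three
days of elimination, duplicate tissue and medium samples at regular
intervals, pooled animals per tissue sample (4 for *Gammarus pulex*, 15 for
*Hyalella azteca*), multiplicative measurement noise, and censoring below a
limit of quantification (LOQ).  True rate constants follow an Arrhenius law
across temperatures, so end-to-end recovery of the Arrhenius temperature can
be tested against a known truth.

Noise is lognormal with mean exactly 1 (a mean-correction of -sigma^2/2 on
the log scale), so generated observations are unbiased for the closed-form
model values.  Every generator is a pure function of its configuration and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arrhenius import RateTable, celsius_to_kelvin, rate_at_temperature
from .fitting import TKDataset, TKObservation
from .tk_models import BiotransParams, ExposureDesign, ParentParams, cascade_conc, parent_conc

__all__ = [
    "TruthConfig",
    "generate_experiment",
    "generate_respiration",
    "generate_btp_cascade",
    "default_sampling_times",
    "BIOTRANS_PRESETS",
]

#: measured water temperatures of the emulated bioconcentration study (C)
DEFAULT_TEMPERATURES_C = (6.1, 11.0, 15.4, 21.2)

#: pooled animals per tissue sample, by species
ANIMALS_PER_SAMPLE = {"G. pulex": 4, "H. azteca": 15}


def default_sampling_times(t_uptake: float = 1.0, t_end: float = 4.0,
                           n_uptake: int = 5, n_elim: int = 6) -> np.ndarray:
    """Regular sampling grid: ``n_uptake`` times in (0, t_uptake] and
    ``n_elim`` in (t_uptake, t_end]."""
    up = np.linspace(t_uptake / n_uptake, t_uptake, n_uptake)
    el = np.linspace(t_uptake, t_end, n_elim + 1)[1:]
    return np.concatenate([up, el])


@dataclass(frozen=True)
class TruthConfig:
    """Ground truth and design of a synthetic bioconcentration study.

    Either ``arrhenius`` maps rate names (``k_u``, ``k_e``) to (T_A, ln_A)
    pairs — rates at each temperature follow k(T) = A exp(-T_A/T) — or
    ``rates_per_temperature`` fixes the true parameters per temperature
    directly.
    """

    arrhenius: dict | None = None
    rates_per_temperature: dict | None = None  # temperature_C -> params
    species: str = "H. azteca"
    compound: str = "demo"
    temperatures_C: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    c_water: float = 50.0  # exposure concentration (nominal 50 ug/L)
    water_unit: str = "ug/L"
    t_uptake: float = 1.0
    t_end: float = 4.0
    sampling_times: np.ndarray | None = None
    n_replicates: int = 2
    n_animals: int | None = None  # default from species
    cv_tissue: float = 0.2
    cv_medium: float = 0.05
    loq: float = 0.0
    medium_drift: float = 0.0  # fractional decline of C_w over uptake (<= 0.2 typical)
    mortality_rate: dict | None = None  # temperature_C -> fraction, drops late replicates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_tissue < 0 or self.cv_medium < 0:
            raise ValueError("CVs must be >= 0")
        if len(set(self.temperatures_C)) != len(self.temperatures_C):
            raise ValueError("temperatures must be distinct")
        if (self.arrhenius is None) == (self.rates_per_temperature is None):
            raise ValueError(
                "provide exactly one of arrhenius / rates_per_temperature")

    def times(self) -> np.ndarray:
        t = (np.asarray(self.sampling_times, dtype=float)
             if self.sampling_times is not None
             else default_sampling_times(self.t_uptake, self.t_end))
        if np.any(t <= 0) or np.any(t > self.t_end + 1e-9):
            raise ValueError("sampling times must lie in (0, t_end]")
        return t

    def animals(self) -> int:
        if self.n_animals is not None:
            return self.n_animals
        return ANIMALS_PER_SAMPLE.get(self.species, 4)

    def params_at(self, T_C: float):
        """True model parameters at one temperature."""
        if self.rates_per_temperature is not None:
            return self.rates_per_temperature[T_C]
        T_K = T_C + 273.15
        rates = {name: rate_at_temperature(pair, T_K)
                 for name, pair in self.arrhenius.items()}
        if set(rates) == {"k_u", "k_e"}:
            return ParentParams(rates["k_u"], rates["k_e"])
        return BiotransParams(
            rates["k_u"], rates.get("k_e_p", 0.0), rates.get("k_m_1st", 0.0),
            rates.get("k_e_1st", 0.0), rates.get("k_m_2nd", 0.0),
            rates.get("k_e_2nd", 0.0))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _medium_series(tc: TruthConfig, rng: np.random.Generator):
    """Medium observations during uptake, optionally drifting downward."""
    t_med = np.linspace(0.0, tc.t_uptake, 3)
    # linear decline by medium_drift over the uptake phase
    truth = tc.c_water * (1.0 - tc.medium_drift * t_med / tc.t_uptake)
    obs = []
    for rep in range(tc.n_replicates):
        noise = _lognormal_factor(rng, tc.cv_medium, len(t_med))
        for t, v in zip(t_med, truth * noise):
            obs.append(TKObservation(float(t), "medium", float(v),
                                     replicate_id=f"m{rep + 1}", n_animals=1))
    return obs


def _tissue_obs(tc: TruthConfig, rng: np.random.Generator, times, state,
                truth_vals, surviving) -> list[TKObservation]:
    obs = []
    n_an = tc.animals()
    for rep in range(tc.n_replicates):
        noise = _lognormal_factor(rng, tc.cv_tissue, len(times))
        for j, (t, v) in enumerate(zip(times, truth_vals * noise)):
            if not surviving[rep][j]:
                continue
            below = v < tc.loq
            obs.append(TKObservation(
                float(t), state, float(v), replicate_id=f"r{rep + 1}",
                n_animals=n_an, below_loq=bool(below),
                loq=tc.loq if below else None))
    return obs


def _survival_mask(tc: TruthConfig, rng: np.random.Generator, T_C: float,
                   times: np.ndarray):
    """Progressive loss of late replicates emulating mortality (default off)."""
    frac = (tc.mortality_rate or {}).get(T_C, 0.0)
    masks = []
    for _ in range(tc.n_replicates):
        if frac <= 0:
            masks.append(np.ones(len(times), dtype=bool))
        else:
            # each sampling occasion independently lost with probability
            # increasing linearly to `frac` at the end of the experiment
            p = frac * times / times[-1]
            masks.append(rng.random(len(times)) >= p)
    return masks


def generate_experiment(tc: TruthConfig):
    """Generate one parent-model dataset per temperature, plus the truth.

    Returns ``(datasets, truth)``: a list of :class:`TKDataset` (one per
    configured temperature, in order) and a dict mapping temperature (C) to
    the true parameter object.  Deterministic given ``tc.seed``.
    """
    rng = np.random.default_rng(tc.seed)
    times = tc.times()
    design = ExposureDesign(tc.c_water, tc.t_uptake, tc.t_end,
                            unit=tc.water_unit)
    datasets, truth = [], {}
    for T_C in tc.temperatures_C:
        p = tc.params_at(T_C)
        if not isinstance(p, ParentParams):
            raise TypeError("generate_experiment expects ParentParams truth; "
                            "use generate_btp_cascade for cascade truth")
        truth[T_C] = p
        truth_vals = parent_conc(times, p, design)
        surviving = _survival_mask(tc, rng, T_C, times)
        obs = _tissue_obs(tc, rng, times, "parent", truth_vals, surviving)
        obs += _medium_series(tc, rng)
        datasets.append(TKDataset(tc.species, tc.compound,
                                  celsius_to_kelvin(T_C).item(), design, obs))
    return datasets, truth


def generate_btp_cascade(tc: TruthConfig):
    """Three-state datasets (parent, btp1, btp2) from the cascade model."""
    rng = np.random.default_rng(tc.seed)
    times = tc.times()
    design = ExposureDesign(tc.c_water, tc.t_uptake, tc.t_end,
                            unit=tc.water_unit)
    datasets, truth = [], {}
    for T_C in tc.temperatures_C:
        p = tc.params_at(T_C)
        if not isinstance(p, BiotransParams):
            raise TypeError("generate_btp_cascade expects BiotransParams truth")
        truth[T_C] = p
        all_states = cascade_conc(times, p, design)
        surviving = _survival_mask(tc, rng, T_C, times)
        obs: list[TKObservation] = []
        for j, state in enumerate(("parent", "btp1", "btp2")):
            obs += _tissue_obs(tc, rng, times, state, all_states[:, j],
                               surviving)
        obs += _medium_series(tc, rng)
        datasets.append(TKDataset(tc.species, tc.compound,
                                  celsius_to_kelvin(T_C).item(), design, obs))
    return datasets, truth


#: Cascade presets for the two observed biotransformation regimes: a minor
#: share (biotransformation < 7 % of total parent elimination) and a dominant
#: share (> 90 %, leaving the excretion rate near zero).
BIOTRANS_PRESETS = {
    "minor": BiotransParams(k_u=20.0, k_e_p=1.9, k_m_1st=0.1,
                            k_e_1st=0.5, k_m_2nd=0.1, k_e_2nd=0.8),
    "dominant": BiotransParams(k_u=20.0, k_e_p=0.02, k_m_1st=1.8,
                               k_e_1st=0.5, k_m_2nd=0.2, k_e_2nd=0.8),
    "none": BiotransParams(k_u=20.0, k_e_p=2.0, k_m_1st=0.0,
                           k_e_1st=0.0, k_m_2nd=0.0, k_e_2nd=0.0),
}

#: respirometry temperatures of the emulated oxygen-consumption study (C)
RESPIRATION_TEMPERATURES_C = (7.3, 11.6, 16.4, 21.2)


def generate_respiration(arrhenius_smr: tuple[float, float] | None = None,
                         temperatures_C=RESPIRATION_TEMPERATURES_C,
                         n_chambers: int = 8, cv: float = 0.2,
                         seed: int = 0) -> RateTable:
    """Per-chamber standard metabolic rates at each temperature.

    The default truth anchors the SMR to 330 ug O2 / g / h at 7.3 C with an
    Arrhenius temperature of 8030 K, emulating respirometry on *H. azteca*
    (rates rise roughly fourfold to ~21 C).  Returns a :class:`RateTable`
    (one row per chamber x temperature) consumable by
    :func:`thermotk.arrhenius.arrhenius_fit`.
    """
    if arrhenius_smr is None:
        T_ref = 7.3 + 273.15
        T_A = 8030.0
        ln_A = math.log(330.0) + T_A / T_ref
        arrhenius_smr = (T_A, ln_A)
    rng = np.random.default_rng(seed)
    temps, rates = [], []
    for T_C in temperatures_C:
        T_K = T_C + 273.15
        truth = rate_at_temperature(arrhenius_smr, T_K)
        noise = _lognormal_factor(rng, cv, n_chambers)
        temps.extend([T_K] * n_chambers)
        rates.extend(truth * noise)
    return RateTable(np.array(temps), np.array(rates), label="SMR")
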