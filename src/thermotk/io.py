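"""CSV/JSON interchange for datasets, rate tables, profiles and reports.

One tabular dialect: UTF-8 CSV with a mandatory header row and '.' decimals.
Temperatures are stored in degrees Celsius in files (the customary field
presentation) and converted to kelvin on read.  Unknown columns are
preserved on a round trip; missing required columns and invalid rows are
rejected with the offending row number.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .arrhenius import RateTable, celsius_to_kelvin
from .fitting import FitResult, TKDataset, TKObservation
from .scenario import Profile
from .tk_models import ExposureDesign

__all__ = [
    "write_observations",
    "read_observations",
    "write_rate_table",
    "read_rate_table",
    "write_profile",
    "read_profile",
    "fit_report_frame",
    "write_fit_report",
    "write_manifest",
    "ValidationError",
]

OBS_COLUMNS = [
    "species", "compound", "temperature_C", "time_day", "state", "matrix",
    "concentration", "unit", "replicate_id", "n_animals", "below_loq", "loq",
]
OBS_REQUIRED = ["species", "compound", "temperature_C", "time_day", "state",
                "concentration", "replicate_id", "n_animals", "below_loq"]

RATE_COLUMNS = ["label", "species", "compound", "temperature_C", "rate",
                "unit", "se"]


class ValidationError(ValueError):
    """A file failed row-level validation; the message names the row."""


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def write_observations(datasets: list[TKDataset], path) -> None:
    rows = []
    for ds in datasets:
        for o in ds.observations:
            rows.append(
                {
                    "species": ds.species,
                    "compound": ds.compound,
                    "temperature_C": ds.temperature_C,
                    "time_day": o.time,
                    "state": o.state,
                    "matrix": "water" if o.state == "medium" else "tissue",
                    "concentration": o.concentration,
                    "unit": (ds.design.unit if o.state == "medium"
                             else ds.design.unit.replace("/L", "/kg_ww")),
                    "replicate_id": o.replicate_id,
                    "n_animals": o.n_animals,
                    "below_loq": o.below_loq,
                    "loq": "" if o.loq is None else o.loq,
                    "c_water_uptake": ds.design.c_water_uptake,
                    "t_depuration_start": ds.design.t_depuration_start,
                    "t_end": ds.design.t_end,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations(path) -> list[TKDataset]:
    """Parse an observation table into one TKDataset per
    species x compound x temperature group."""
    df = pd.read_csv(path)
    _require(df, OBS_REQUIRED, path)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            t = float(row["time_day"])
            c = float(row["concentration"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {line}: malformed numeric "
                                  f"({exc})") from None
        if t < 0:
            raise ValidationError(f"{path}: row {line}: negative time {t}")
        below = _parse_bool(row["below_loq"], path, line)
        if c < 0 and not below:
            raise ValidationError(
                f"{path}: row {line}: negative concentration {c}")

    datasets = []
    for (sp, cpd, T_C), grp in df.groupby(
            ["species", "compound", "temperature_C"], sort=True):
        t_dep = float(grp["t_depuration_start"].iloc[0]) \
            if "t_depuration_start" in grp else 1.0
        t_end = float(grp["t_end"].iloc[0]) if "t_end" in grp \
            else float(grp["time_day"].max())
        if "c_water_uptake" in grp:
            cw = float(grp["c_water_uptake"].iloc[0])
        else:
            med = grp[(grp["state"] == "medium") & (grp["time_day"] <= t_dep)]
            cw = float(med["concentration"].mean()) if len(med) else 0.0
        unit = "umol/L"
        if "unit" in grp:
            med_units = grp.loc[grp["state"] == "medium", "unit"]
            if len(med_units):
                unit = str(med_units.iloc[0])
        design = ExposureDesign(cw, t_dep, max(t_end, t_dep), unit=unit)
        obs = []
        for _, row in grp.iterrows():
            below = _parse_bool(row["below_loq"], path, 0)
            loq = row.get("loq")
            loq = None if loq is None or (isinstance(loq, float) and math.isnan(loq)) \
                or loq == "" else float(loq)
            obs.append(TKObservation(
                time=float(row["time_day"]), state=str(row["state"]),
                concentration=float(row["concentration"]),
                replicate_id=str(row["replicate_id"]),
                n_animals=int(row["n_animals"]), below_loq=below, loq=loq))
        datasets.append(TKDataset(str(sp), str(cpd),
                                  float(celsius_to_kelvin(T_C)), design, obs))
    return datasets


def _parse_bool(v, path, line) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise ValidationError(f"{path}: row {line}: bad boolean {v!r}")


def write_rate_table(rt: RateTable, path, species: str = "",
                     compound: str = "", unit: str = "1/day") -> None:
    df = pd.DataFrame(
        {
            "label": rt.label,
            "species": species,
            "compound": compound,
            "temperature_C": rt.temperature_K - 273.15,
            "rate": rt.rate,
            "unit": unit,
            "se": rt.se if rt.se is not None else "",
        }
    )
    df.to_csv(path, index=False)


def read_rate_table(path) -> RateTable:
    df = pd.read_csv(path)
    _require(df, ["temperature_C", "rate"], path)
    se = None
    if "se" in df.columns and df["se"].notna().any():
        se = df["se"].astype(float).to_numpy()
    label = str(df["label"].iloc[0]) if "label" in df.columns else "k"
    return RateTable(celsius_to_kelvin(df["temperature_C"].astype(float).to_numpy()),
                     df["rate"].astype(float).to_numpy(), se, label)


def write_profile(p: Profile, path) -> None:
    pd.DataFrame({"time_day": p.times, "value": p.values,
                  "kind": p.kind}).to_csv(path, index=False)


def read_profile(path, interpolation: str = "linear",
                 extrapolate: bool = False) -> Profile:
    df = pd.read_csv(path)
    _require(df, ["time_day", "value", "kind"], path)
    t = df["time_day"].astype(float).to_numpy()
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0)) + 3
        raise ValidationError(f"{path}: row {i}: times not strictly increasing")
    return Profile(t, df["value"].astype(float).to_numpy(),
                   kind=str(df["kind"].iloc[0]), interpolation=interpolation,
                   extrapolate=extrapolate)


def fit_report_frame(fits: list[tuple[TKDataset, FitResult]]) -> pd.DataFrame:
    """One row per dataset x parameter with estimate, CI and fit metrics."""
    rows = []
    for ds, fr in fits:
        from .tk_models import NotComputable, bcf_kin

        try:
            bcf = bcf_kin(fr.estimates)
        except NotComputable:
            bcf = float("nan")
        for name in fr.free_params:
            lo, hi = fr.ci95.get(name, (float("nan"), float("nan")))
            rows.append(
                {
                    "species": ds.species,
                    "compound": ds.compound,
                    "temperature_C": ds.temperature_C,
                    "model": fr.model,
                    "parameter": name,
                    "estimate": getattr(fr.estimates, name),
                    "ci95_lo": lo,
                    "ci95_hi": hi,
                    "bcf_kin": bcf,
                    "weighted_ssq": fr.weighted_ssq,
                    "aic": fr.aic,
                    "r2_parent": fr.r2.get("parent", float("nan")),
                    "r2_btp1": fr.r2.get("btp1", float("nan")),
                    "converged": fr.converged,
                    "selection": "; ".join(fr.selection_trace),
                }
            )
    return pd.DataFrame(rows)


def write_fit_report(fits, path) -> None:
    fit_report_frame(fits).to_csv(path, index=False)


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Record the run configuration (and its hash) for reproducibility."""
    payload = {k: v for k, v in sorted(config.items())}
    if seed is not None:
        payload["seed"] = seed
    blob = json.dumps(payload, sort_keys=True, default=str)
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package": "thermotk",
        "version": _version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("thermotk")
    except Exception:
        return "unknown"
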