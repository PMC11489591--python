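"""CSV readers/writers and calibration-model serialization.

All interchange is UTF-8 CSV with a header row and '.' decimals.  Column
dialects (units in the name where ambiguity is possible):

samples    sample_id, mgca_mmolmol, d18Oc_permil, source, crust_state,
           cleaning, size_fraction, temp_C, co3_umolkg, sal, d18Osw_permil
profile    station_id, lat, lon, date, depth_m, temp_C, sal, alk_umolkg,
           dic_umolkg, d18Osw_permil, co3_umolkg
record     core_id, age_ka, mgca_mmolmol, d18Oc_permil, cleaning, crust_state
sea level  age_ka, rsl_m

Empty cells mean "absent".  Internally the short names (mgca, d18Oc,
temperature, co3, ...) are used; renaming happens only here.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel, ExpLaw, OxyCarbLine, PowerLaw
from .corrections import SeaLevelCurve
from .hydro import HydroProfile

__all__ = ["read_samples", "read_profile", "read_record", "read_sealevel_curve",
           "write_table", "save_model", "load_model", "RowError", "SchemaError"]


class SchemaError(ValueError):
    """Mandatory columns are missing from an input file."""


class RowError(ValueError):
    """One or more data rows failed validation."""

    def __init__(self, messages: list[str]):
        self.messages = messages
        super().__init__("; ".join(messages))


_SAMPLE_RENAME = {"mgca_mmolmol": "mgca", "d18Oc_permil": "d18Oc",
                  "temp_C": "temperature", "co3_umolkg": "co3",
                  "sal": "salinity", "d18Osw_permil": "d18Osw"}
_PROFILE_RENAME = {"depth_m": "depth", "temp_C": "temperature", "sal": "salinity",
                   "alk_umolkg": "alk", "dic_umolkg": "dic",
                   "d18Osw_permil": "d18Osw", "co3_umolkg": "co3"}
_RECORD_RENAME = {"mgca_mmolmol": "mgca", "d18Oc_permil": "d18Oc"}


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): "
                          + ", ".join(missing))


def read_samples(path, strict: bool = False) -> pd.DataFrame:
    """Read a geochemical sample table.

    Each row needs at least one of mgca_mmolmol / d18Oc_permil, and Mg/Ca
    must be positive where present.  Invalid rows are dropped with a
    line-numbered report (raised when ``strict``, otherwise attached to the
    returned frame as ``df.attrs['row_errors']``).
    """
    df = pd.read_csv(path, float_precision='round_trip')
    if "mgca_mmolmol" not in df.columns and "d18Oc_permil" not in df.columns:
        raise SchemaError(f"{path}: need at least one of mgca_mmolmol, "
                          "d18Oc_permil")
    df = df.rename(columns=_SAMPLE_RENAME)
    errors: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        mg = row.get("mgca", math.nan)
        d18 = row.get("d18Oc", math.nan)
        if not (np.isfinite(mg) or np.isfinite(d18)):
            errors.append(f"line {line}: neither Mg/Ca nor d18Oc present")
            keep[i] = False
        elif np.isfinite(mg) and mg <= 0:
            errors.append(f"line {line}: non-positive Mg/Ca {mg}")
            keep[i] = False
    if errors and strict:
        raise RowError(errors)
    out = df[keep].reset_index(drop=True)
    out.attrs["row_errors"] = errors
    return out


def read_profile(path, station_id: str | None = None) -> HydroProfile:
    """Read a hydrographic profile table (one station per call)."""
    df = pd.read_csv(path, float_precision='round_trip')
    _require(df, ["depth_m", "temp_C", "sal"], path)
    df = df.rename(columns=_PROFILE_RENAME)
    if station_id is not None and "station_id" in df.columns:
        df = df[df["station_id"] == station_id]
        if len(df) == 0:
            raise ValueError(f"{path}: no rows for station {station_id}")
    sid = str(df["station_id"].iloc[0]) if "station_id" in df.columns else str(path)
    meta = {}
    for col, key in (("lat", "latitude"), ("lon", "longitude"), ("date", "date")):
        if col in df.columns:
            meta[key] = df[col].iloc[0]
    levels = df[[c for c in ("depth", "temperature", "salinity", "alk", "dic",
                             "d18Osw", "co3") if c in df.columns]]
    levels = levels.sort_values("depth").reset_index(drop=True)
    return HydroProfile(station_id=sid, levels=levels,
                        latitude=float(meta.get("latitude", np.nan)),
                        longitude=float(meta.get("longitude", np.nan)),
                        date=str(meta.get("date", "")))


def read_record(path) -> pd.DataFrame:
    """Read an age-indexed paired Mg/Ca–δ¹⁸O_c downcore record."""
    df = pd.read_csv(path, float_precision='round_trip')
    _require(df, ["age_ka", "mgca_mmolmol", "d18Oc_permil"], path)
    df = df.rename(columns=_RECORD_RENAME)
    ages = df["age_ka"].to_numpy(float)
    if np.any(np.diff(ages) < 0):
        raise ValueError(f"{path}: ages must be non-decreasing")
    return df


def read_sealevel_curve(path) -> SeaLevelCurve:
    df = pd.read_csv(path, float_precision='round_trip')
    _require(df, ["age_ka", "rsl_m"], path)
    return SeaLevelCurve(ages=df["age_ka"].to_numpy(float),
                         rsl=df["rsl_m"].to_numpy(float))


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table back to the public CSV dialect."""
    inverse = {v: k for k, v in {**_SAMPLE_RENAME, **_PROFILE_RENAME}.items()}
    # %.17g guarantees binary round-tripping of doubles through the text form
    df.rename(columns=inverse).to_csv(path, index=False, float_format="%.17g")


# --- model serialization (flat YAML-compatible key/value file) -------------

def save_model(model: CalibrationModel, path) -> None:
    doc: dict = {"prediction_a": model.prediction_law.a,
                 "prediction_b": model.prediction_law.b}
    if model.exp_law is not None:
        e = model.exp_law
        doc.update(a=e.a, b=e.b, a_se=e.a_se, b_se=e.b_se, n_exp=e.n,
                   r2_exp=None if math.isnan(e.r2) else e.r2)
    if model.power_law is not None:
        p = model.power_law
        doc.update(p=p.p, q=p.q, p_se=p.p_se, q_se=p.q_se, n_power=p.n,
                   r2_power=None if math.isnan(p.r2) else p.r2)
    if model.oxy_line is not None:
        o = model.oxy_line
        doc.update(oxy_slope=o.slope, oxy_slope_se=o.slope_se, oxy_n=o.n)
        if math.isfinite(o.intercept_ontogenetic):
            doc["oxy_intercept_ontogenetic"] = o.intercept_ontogenetic
        if math.isfinite(o.intercept_crusted):
            doc["oxy_intercept_crusted"] = o.intercept_crusted
    with open(path, "w") as fh:
        yaml.safe_dump({k: (float(v) if isinstance(v, (int, float)) and
                            not isinstance(v, bool) else v)
                        for k, v in doc.items()}, fh, sort_keys=True)


def load_model(path) -> CalibrationModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pred = ExpLaw(a=doc.get("prediction_a", 0.4), b=doc.get("prediction_b", 0.09))
    exp = None
    if "a" in doc:
        exp = ExpLaw(a=doc["a"], b=doc["b"], a_se=doc.get("a_se", 0.0),
                     b_se=doc.get("b_se", 0.0), n=doc.get("n_exp", 0),
                     r2=doc.get("r2_exp") or float("nan"))
    power = None
    if "p" in doc:
        power = PowerLaw(p=doc["p"], q=doc["q"], p_se=doc.get("p_se", 0.0),
                         q_se=doc.get("q_se", 0.0), n=doc.get("n_power", 0),
                         r2=doc.get("r2_power") or float("nan"))
    oxy = None
    if "oxy_slope" in doc:
        oxy = OxyCarbLine(
            slope=doc["oxy_slope"],
            intercept_ontogenetic=doc.get("oxy_intercept_ontogenetic",
                                          float("nan")),
            intercept_crusted=doc.get("oxy_intercept_crusted", float("nan")),
            slope_se=doc.get("oxy_slope_se", 0.0), n=doc.get("oxy_n", 0))
    return CalibrationModel(prediction_law=pred, power_law=power,
                            exp_law=exp, oxy_line=oxy)
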