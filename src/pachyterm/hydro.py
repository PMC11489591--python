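"""Water-column hydrography: profiles, interpolation and δ¹⁸O_sw–salinity fits.

A :class:`HydroProfile` is a depth-indexed record of temperature, salinity and
(optionally) carbonate-system inputs (ALK/DIC) or a pre-computed carbonate-ion
concentration, plus seawater δ¹⁸O where measured.  Where δ¹⁸O_sw was not
sampled it can be reconstructed from salinity through a site-specific linear
mixing line (:func:`fit_d18Osw_salinity`), reflecting the freshwater–seawater
mixing control on both quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbsys import solve_carbonate

__all__ = ["HydroProfile", "SalinityMixingLine", "fit_d18Osw_salinity",
           "profile_interpolate"]

#: columns a profile may carry beyond depth
LEVEL_FIELDS = ("temperature", "salinity", "alk", "dic", "d18Osw", "co3")


class ExtrapolationError(ValueError):
    """Requested depth lies outside the profile's depth grid."""


class DegenerateFitError(ValueError):
    """Regression input carries no spread in the predictor."""


@dataclass(frozen=True)
class SalinityMixingLine:
    """Linear δ¹⁸O_sw = slope·S + intercept relationship (‰ VSMOW)."""

    slope: float
    intercept: float
    n_points: int
    rmse: float

    def d18Osw(self, salinity: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(salinity, dtype=float) + self.intercept


@dataclass
class HydroProfile:
    """Depth-ordered water-column state at one station.

    ``levels`` is a DataFrame with a ``depth`` column (m, strictly increasing)
    and any of temperature (°C), salinity, alk/dic (µmol·kg⁻¹), d18Osw
    (‰ VSMOW), co3 (µmol·kg⁻¹).  Missing values are NaN.
    """

    station_id: str
    levels: pd.DataFrame
    latitude: float = np.nan
    longitude: float = np.nan
    date: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "depth" not in self.levels.columns:
            raise ValueError("profile levels need a 'depth' column")
        depths = self.levels["depth"].to_numpy(dtype=float)
        if len(depths) and not np.all(np.diff(depths) > 0):
            raise ValueError(f"depths of station {self.station_id} "
                             "must be strictly increasing")
        sal = self.levels.get("salinity")
        if sal is not None:
            s = sal.dropna()
            if len(s) and not ((s > 0) & (s < 45)).all():
                raise ValueError("salinity outside (0, 45)")
        temp = self.levels.get("temperature")
        if temp is not None:
            t = temp.dropna()
            if len(t) and not ((t > -3) & (t < 40)).all():
                raise ValueError("temperature outside (-3, 40) degC")

    @property
    def depths(self) -> np.ndarray:
        return self.levels["depth"].to_numpy(dtype=float)

    def ensure_co3(self) -> "HydroProfile":
        """Fill the co3 column from ALK/DIC where it is missing.

        Levels with neither co3 nor the ALK/DIC pair stay NaN.  Pressure for
        the constants is approximated by depth in metres (1 dbar ≈ 1 m).
        """
        lv = self.levels.copy()
        if "co3" not in lv.columns:
            lv["co3"] = np.nan
        for i, row in lv.iterrows():
            if np.isfinite(lv.at[i, "co3"]):
                continue
            alk, dic = row.get("alk", np.nan), row.get("dic", np.nan)
            if np.isfinite(alk) and np.isfinite(dic):
                state = solve_carbonate(alk, dic, row["salinity"],
                                        row["temperature"],
                                        pressure=row["depth"])
                lv.at[i, "co3"] = state.co3
        return HydroProfile(self.station_id, lv, self.latitude, self.longitude,
                            self.date, dict(self.meta))


def fit_d18Osw_salinity(pairs) -> SalinityMixingLine:
    """Ordinary least-squares δ¹⁸O_sw–salinity line.

    ``pairs`` is a sequence of (salinity, δ¹⁸O_sw ‰ VSMOW) tuples or an
    (n, 2) array.  Requires at least two distinct salinities.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (salinity, d18Osw) pairs")
    s, d = arr[:, 0], arr[:, 1]
    if np.ptp(s) == 0:
        raise DegenerateFitError("all salinities identical; mixing line undefined")
    slope, intercept = np.polyfit(s, d, 1)
    resid = d - (slope * s + intercept)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return SalinityMixingLine(slope=float(slope), intercept=float(intercept),
                              n_points=len(s), rmse=rmse)


def profile_interpolate(profile: HydroProfile, depth: float) -> dict[str, float]:
    """Linearly interpolate every present level field at ``depth`` (m).

    Exact at grid nodes.  Raises :class:`ExtrapolationError` outside the
    grid — fossil-data workflows must see the failure, not a clamped value.
    """
    depths = profile.depths
    if len(depths) == 0:
        raise ValueError("empty profile")
    if depth < depths[0] or depth > depths[-1]:
        raise ExtrapolationError(
            f"depth {depth} m outside profile grid "
            f"[{depths[0]}, {depths[-1]}] of station {profile.station_id}")
    out: dict[str, float] = {"depth": float(depth)}
    for col in profile.levels.columns:
        if col == "depth":
            continue
        vals = profile.levels[col].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        if mask.sum() == 0:
            out[col] = float("nan")
            continue
        out[col] = float(np.interp(depth, depths[mask], vals[mask]))
    return out
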