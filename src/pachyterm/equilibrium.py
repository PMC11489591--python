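"""Equilibrium-calcite δ¹⁸O profiles and apparent calcification depth.

The δ¹⁸O of inorganic calcite grown in isotopic equilibrium with seawater is
a function of temperature and seawater δ¹⁸O.  Computing the equilibrium
δ¹⁸O_c at every depth of a hydrographic profile turns a measured
foraminiferal δ¹⁸O_c into an apparent calcification depth: the depth at which
the equilibrium curve crosses the measured value.  The hydrographic state
interpolated at that depth (temperature, salinity, [CO3^2-]) is then assigned
to the shell.

The default paleotemperature equation is the classic quadratic

    T = 16.9 - 4.38*(d18Oc - A) + 0.10*(d18Oc - A)^2,   A = d18Osw - 0.27

(T in °C, δ¹⁸O_c on VPDB, δ¹⁸O_sw on VSMOW; the 0.27 ‰ term converts the
water value to the carbonate scale).  Alternative coefficient sets can be
registered by name, since the literature carries several refits of the same
O'Neil-lineage fractionation data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hydro import HydroProfile, SalinityMixingLine, profile_interpolate

__all__ = ["EquilibriumProfile", "CalcificationEstimate", "equilibrium_d18Oc",
           "equilibrium_profile", "infer_calcification_depth",
    "PALEOTEMP_EQUATIONS"]

VSMOW_TO_VPDB_ADJ = 0.27  # permil, subtracted from d18Osw

#: quadratic coefficients (c0, c1, c2) of T = c0 - c1*D + c2*D^2
PALEOTEMP_EQUATIONS: dict[str, tuple[float, float, float]] = {
    # Shackleton-style refit of the O'Neil inorganic-calcite data
    "oneil_quadratic": (16.9, 4.38, 0.10),
    # Epstein-lineage biogenic-carbonate fit, for sensitivity studies
    "epstein": (16.5, 4.3, 0.14),
}
DEFAULT_EQUATION = "oneil_quadratic"

MAX_SEARCH_DEPTH = 400.0   # m, depth window over which profiles are built
SUSPECT_DEPTH = 300.0      # m, deeper matches are ecologically implausible


@dataclass(frozen=True)
class EquilibriumProfile:
    """Equilibrium calcite δ¹⁸O (VPDB) on a depth grid."""

    depths: np.ndarray
    d18Oc_eq: np.ndarray
    source_profile_id: str = ""

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.d18Oc_eq, dtype=float)
        if d.shape != v.shape:
            raise ValueError("depth and d18Oc_eq grids differ in length")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite equilibrium d18Oc values")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "d18Oc_eq", v)


@dataclass(frozen=True)
class CalcificationEstimate:
    """Apparent calcification depth and the hydrographic state there."""

    matched: bool
    depth: float = math.nan
    temperature: float = math.nan
    salinity: float = math.nan
    co3: float = math.nan
    d18Osw: float = math.nan
    ambiguity_count: int = 0
    suspect: bool = False
    extras: dict = field(default_factory=dict)


def equilibrium_d18Oc(temperature: float, d18Osw: float,
                      equation: str = DEFAULT_EQUATION,
                      vital_effect: float = 0.0) -> float:
    """Equilibrium calcite δ¹⁸O (‰ VPDB) at ``temperature`` (°C).

    Inverts the quadratic paleotemperature form, taking the smaller
    (physically meaningful) root.  ``vital_effect`` is an optional constant
    offset (‰, added) for datasets where a species disequilibrium was
    characterised; the default is no correction.
    """
    if not -3 < temperature < 30:
        raise ValueError(f"temperature {temperature} outside (-3, 30) degC")
    c0, c1, c2 = PALEOTEMP_EQUATIONS[equation]
    disc = c1 * c1 - 4.0 * c2 * (c0 - temperature)
    if disc < 0:
        raise ValueError(
            f"temperature {temperature} above the apex of equation '{equation}'")
    delta = (c1 - math.sqrt(disc)) / (2.0 * c2)
    return delta + (d18Osw - VSMOW_TO_VPDB_ADJ) + vital_effect


def paleotemperature(d18Oc: float, d18Osw: float,
                     equation: str = DEFAULT_EQUATION) -> float:
    """Forward quadratic: temperature (°C) from calcite and water δ¹⁸O."""
    c0, c1, c2 = PALEOTEMP_EQUATIONS[equation]
    delta = d18Oc - (d18Osw - VSMOW_TO_VPDB_ADJ)
    return c0 - c1 * delta + c2 * delta * delta


def equilibrium_profile(profile: HydroProfile,
                        mixing_line: SalinityMixingLine | None = None,
                        equation: str = DEFAULT_EQUATION,
                        vital_effect: float = 0.0) -> EquilibriumProfile:
    """Equilibrium δ¹⁸O_c at every level of a hydrographic profile.

    δ¹⁸O_sw is taken from the profile where present, otherwise from the
    salinity mixing line; levels with neither are a configuration error.
    """
    lv = profile.levels
    t = lv["temperature"].to_numpy(dtype=float)
    if "d18Osw" in lv.columns:
        dsw = lv["d18Osw"].to_numpy(dtype=float).copy()
    else:
        dsw = np.full(len(lv), np.nan)
    missing = ~np.isfinite(dsw)
    if missing.any():
        if mixing_line is None:
            raise ValueError(
                f"station {profile.station_id}: levels lack d18Osw and no "
                "salinity mixing line was supplied")
        dsw[missing] = mixing_line.d18Osw(
            lv["salinity"].to_numpy(dtype=float)[missing])
    eq = np.array([equilibrium_d18Oc(ti, di, equation, vital_effect)
                   for ti, di in zip(t, dsw)])
    return EquilibriumProfile(profile.depths.copy(), eq, profile.station_id)


def infer_calcification_depth(measured_d18Oc: float, eq: EquilibriumProfile,
                              profile: HydroProfile) -> CalcificationEstimate:
    """Depth(s) where the equilibrium curve crosses a measured δ¹⁸O_c.

    The piecewise-linear equilibrium curve may cross the measured value more
    than once on non-monotone profiles; the SHALLOWEST crossing is returned
    (consistent with the near-surface habitat of the species) and
    ``ambiguity_count`` reports how many crossings exist.  No crossing gives
    ``matched=False`` — fossil values routinely fall outside modern profiles
    and must not raise.
    """
    if not np.array_equal(eq.depths, profile.depths):
        raise ValueError("equilibrium and hydrographic profiles must share "
                         "the same depth grid")
    z, v = eq.depths, eq.d18Oc_eq
    crossings: list[float] = []
    for i in range(len(z) - 1):
        lo, hi = v[i], v[i + 1]
        if lo == measured_d18Oc:
            crossings.append(z[i])
            continue
        if (lo - measured_d18Oc) * (hi - measured_d18Oc) < 0:
            frac = (measured_d18Oc - lo) / (hi - lo)
            crossings.append(z[i] + frac * (z[i + 1] - z[i]))
    if len(z) and v[-1] == measured_d18Oc:
        crossings.append(z[-1])
    # node hits found twice by adjacent segments
    crossings = sorted(set(round(c, 9) for c in crossings))
    if not crossings:
        return CalcificationEstimate(matched=False)
    depth = crossings[0]
    env = profile_interpolate(profile, depth)
    return CalcificationEstimate(
        matched=True, depth=depth,
        temperature=env.get("temperature", math.nan),
        salinity=env.get("salinity", math.nan),
        co3=env.get("co3", math.nan),
        d18Osw=env.get("d18Osw", math.nan),
        ambiguity_count=len(crossings),
        suspect=depth > SUSPECT_DEPTH,
        extras={k: val for k, val in env.items()
                if k not in {"depth", "temperature", "salinity", "co3", "d18Osw"}})
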