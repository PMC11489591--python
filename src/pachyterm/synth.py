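"""Seeded forward model: synthetic calibration sets, profiles and records.

This is the package's proxy-system model.  It generates observations with a
known hidden truth so that every stage of the correction scheme can be
tested as a round trip:

* calibration sets — (temperature, [CO3^2-]) designs drawn uniformly over
  the calibrated ranges (−2–16 °C, 50–220 µmol/kg, the design spread of the
  field dataset), forward-modelled through the central exponential/power
  laws with the stated 2σ measurement noise;
* water-column profiles with equilibrium δ¹⁸O_c and a planted calcification
  depth;
* downcore records including the ice-volume δ¹⁸O_sw term, for end-to-end
  pipeline tests.

Error model: noise enters on the *proxies* — Mg/Ca (absolute 2σ on the
corrected scale, where its uncertainty is quoted) and δ¹⁸O_c — while the
environmental design values are exact.  The stated temperature and
carbonate-ion 2σ describe how well hydrographic conditions can be assigned
to a shell; they are propagated by the Monte Carlo ensemble
(:func:`~pachyterm.uncertainty.mc_calibration_ensemble`), not used to
corrupt the generator's truth.

The δ¹⁸O_c–[CO3^2-] intercepts (4.0 ‰ ontogenetic, 6.0 ‰ crusted) are
SYNTHETIC defaults chosen to give realistic polar δ¹⁸O_c values with the
published slope and 2 ‰ crust offset; they are free parameters of the
method, not published constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (CrustState, ExpLaw, OxyCarbLine, PowerLaw)
from .corrections import CorrectionConfig, DEFAULT_CORRECTIONS
from .equilibrium import EquilibriumProfile, equilibrium_d18Oc
from .hydro import HydroProfile
from .uncertainty import UncertaintySpec

__all__ = ["ForwardConfig", "simulate_calibration_set", "simulate_profile",
           "simulate_downcore", "representative_co3"]

#: central corrected calibration and sensitivity used as generator truth
TRUE_EXP_LAW = ExpLaw(a=0.372, b=0.0936)
TRUE_POWER_LAW = PowerLaw(p=3227.95, q=-1.53)
#: synthetic intercepts (see module docstring); slope and 2.0 offset published
TRUE_OXY_LINE = OxyCarbLine(slope=-0.0279, intercept_ontogenetic=4.0,
                            intercept_crusted=6.0)


def representative_co3(temperature):
    """Typical modern surface [CO3^2-] (µmol/kg) at a given SST.

    Linear between 100 µmol/kg at 0 °C (polar surface water) and
    200 µmol/kg at 15 °C (temperate surface water) — the covariation of
    carbonate ion with temperature across the calibration transect.
    """
    return 100.0 + (100.0 / 15.0) * np.asarray(temperature, dtype=float)


@dataclass(frozen=True)
class ForwardConfig:
    """Generator settings; defaults are the study conditions."""

    n_samples: int = 235
    temp_range: tuple[float, float] = (-2.0, 16.0)
    co3_range: tuple[float, float] = (50.0, 220.0)
    true_exp_law: ExpLaw = TRUE_EXP_LAW
    true_power_law: PowerLaw = TRUE_POWER_LAW
    true_oxy_line: OxyCarbLine = TRUE_OXY_LINE
    noise: UncertaintySpec = field(default_factory=UncertaintySpec)
    corrections: CorrectionConfig = DEFAULT_CORRECTIONS
    tow_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        for name in ("temp_range", "co3_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} is degenerate: ({lo}, {hi})")

    def zero_noise(self) -> "ForwardConfig":
        return replace(self, noise=self.noise.zero_noise())


def simulate_calibration_set(cfg: ForwardConfig) -> pd.DataFrame:
    """Synthetic tow/core-top calibration table with hidden truth columns.

    Observable columns: sample_id, source, crust_state, cleaning,
    mgca (mmol/mol, as reported — tow values on the uncrusted scale),
    d18Oc (‰ VPDB, tow values on the ontogenetic scale), temperature (°C)
    and co3 (µmol/kg).  ``true_mgca_corr`` is the noise-free corrected
    Mg/Ca each shell would carry.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    noise = cfg.noise

    t_true = rng.uniform(*cfg.temp_range, n)
    c_true = rng.uniform(*cfg.co3_range, n)

    is_tow = rng.random(n) < cfg.tow_fraction
    crust = np.where(is_tow, CrustState.ONTOGENETIC.value,
                     CrustState.CRUSTED.value)

    mgca_corr_true = cfg.true_exp_law(t_true)
    sens = cfg.true_power_law(c_true)
    mgca_corr_obs = mgca_corr_true + noise.perturb(rng, noise.mgca_corr_2s, n)
    bad = mgca_corr_obs <= 0
    while np.any(bad):
        mgca_corr_obs[bad] = mgca_corr_true[bad] \
            + noise.perturb(rng, noise.mgca_corr_2s, int(bad.sum()))
        bad = mgca_corr_obs <= 0
    mgca_crust_scale = mgca_corr_obs * sens
    # tow shells lack the low-Mg crust: reported values sit higher
    mgca_obs = np.where(is_tow,
                        mgca_crust_scale / (1.0 - cfg.corrections.crust_mgca_fraction),
                        mgca_crust_scale)

    line = cfg.true_oxy_line
    intercepts = np.where(is_tow, line.intercept_ontogenetic,
                          line.intercept_crusted)
    d18O_obs = intercepts + line.slope * c_true \
        + noise.perturb(rng, noise.d18O_2s, n)

    return pd.DataFrame({
        "sample_id": [f"syn{i:04d}" for i in range(n)],
        "source": np.where(is_tow, "tow", "coretop"),
        "crust_state": crust,
        "cleaning": "oxidative",
        "mgca": mgca_obs,
        "d18Oc": d18O_obs,
        "temperature": t_true,
        "co3": c_true,
        "true_mgca_corr": mgca_corr_true,
    })


def simulate_profile(cfg: ForwardConfig, planted_depth: float = 50.0,
                     depth_step: float = 10.0, max_depth: float = 400.0,
                     monotone: bool = True
                     ) -> tuple[HydroProfile, EquilibriumProfile, dict]:
    """Synthetic 0–400 m water column with a planted calcification depth.

    Temperature decays from a warm surface toward cold deep water (with a
    mid-depth warm intrusion when ``monotone`` is False, which makes the
    equilibrium curve non-monotone); salinity rises gently with depth.
    Returns (profile, equilibrium profile, truth) where truth holds the
    planted depth and the δ¹⁸O_c a shell calcifying there would carry.
    """
    z = np.arange(0.0, max_depth + depth_step / 2, depth_step)
    t_surface, t_deep = 8.0, 1.0
    temp = t_deep + (t_surface - t_deep) * np.exp(-z / 120.0)
    if not monotone:
        temp = temp + 3.0 * np.exp(-((z - 200.0) / 40.0) ** 2)
    sal = 34.0 + 1.0 * (1.0 - np.exp(-z / 150.0))
    d18Osw = 0.5 * sal - 17.0          # mixing-line water column
    alk = 2300.0 + 0.05 * z
    dic = 2100.0 + 0.10 * z

    profile = HydroProfile(
        station_id="synthetic-station",
        levels=pd.DataFrame({"depth": z, "temperature": temp, "salinity": sal,
                             "alk": alk, "dic": dic, "d18Osw": d18Osw}),
    ).ensure_co3()
    eq_vals = np.array([equilibrium_d18Oc(t, d)
                        for t, d in zip(temp, profile.levels["d18Osw"])])
    eq = EquilibriumProfile(z, eq_vals, profile.station_id)

    idx = int(np.argmin(np.abs(z - planted_depth)))
    truth = {"depth": float(z[idx]), "d18Oc": float(eq_vals[idx]),
             "temperature": float(temp[idx]), "co3": float(profile.levels["co3"][idx])}
    return profile, eq, truth


def simulate_downcore(cfg: ForwardConfig, sst_history) -> pd.DataFrame:
    """Forward-model a paired Mg/Ca–δ¹⁸O_c downcore record.

    ``sst_history`` is a sequence of (age_ka, true_sst_C, rsl_m) tuples.
    True [CO3^2-] covaries with SST through :func:`representative_co3`;
    δ¹⁸O_c carries the ice-volume term (−rsl/10 · sl_coeff, enrichment at
    glacials) on top of the carbonate-ion control.  Fossil shells are
    crusted; cleaning is oxidative.  Truth columns prefixed ``true_``.
    """
    hist = np.asarray(list(sst_history), dtype=float)
    if hist.size == 0:
        raise ValueError("sst_history must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    noise = cfg.noise
    ages, sst, rsl = hist[:, 0], hist[:, 1], hist[:, 2]
    n = len(ages)

    co3 = representative_co3(sst)
    mgca_corr = cfg.true_exp_law(sst) + noise.perturb(rng, noise.mgca_corr_2s, n)
    bad = mgca_corr <= 0
    while np.any(bad):
        mgca_corr[bad] = cfg.true_exp_law(sst[bad]) \
            + noise.perturb(rng, noise.mgca_corr_2s, int(bad.sum()))
        bad = mgca_corr <= 0
    mgca = mgca_corr * cfg.true_power_law(co3)
    d18Oc = (cfg.true_oxy_line.intercept_crusted + cfg.true_oxy_line.slope * co3
             - rsl / 10.0 * cfg.corrections.sl_coeff
             + noise.perturb(rng, noise.d18O_2s, n))

    return pd.DataFrame({
        "core_id": "synthetic-core",
        "age_ka": ages,
        "mgca": mgca,
        "d18Oc": d18Oc,
        "cleaning": "oxidative",
        "crust_state": CrustState.CRUSTED.value,
        "true_sst": sst,
        "true_co3": co3,
        "rsl_m": rsl,
    })
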