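"""Fixed pre-processing adjustments applied before any fitting.

Three systematic offsets must be removed before tow, core-top and downcore
datasets can be pooled:

* crust vs. ontogenetic calcite — live (uncrusted) tow specimens carry
  ~15 % higher Mg/Ca and ~2 ‰ lighter δ¹⁸O than crusted fossil shells;
* reductive cleaning lowers Mg/Ca by ~10–15 % relative to oxidative-only
  protocols;
* ice volume — lower glacial sea level enriches whole-ocean δ¹⁸O_sw
  (0.11 ‰ per 10 m of sea-level fall), which must be stripped from δ¹⁸O_c
  before it is read as a carbonate-ion proxy.

Each correction is applied exactly once per sample; pipeline-level guards
refuse re-application instead of silently compounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import Cleaning, CrustState

__all__ = ["SeaLevelCurve", "CorrectionConfig", "crust_adjust_mgca",
           "crust_adjust_d18O", "cleaning_adjust_mgca", "sealevel_correct_d18O"]


class DoubleCorrectionError(RuntimeError):
    """A correction was about to be applied twice to the same quantity."""


@dataclass(frozen=True)
class SeaLevelCurve:
    """Relative sea level vs. age (negative rsl = lower-than-present)."""

    ages: np.ndarray    # ka, strictly increasing
    rsl: np.ndarray     # m

    def __post_init__(self):
        a = np.asarray(self.ages, dtype=float)
        r = np.asarray(self.rsl, dtype=float)
        if a.shape != r.shape or a.ndim != 1:
            raise ValueError("ages and rsl must be matching 1-D arrays")
        if not np.all(np.diff(a) > 0):
            raise ValueError("ages must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("rsl must be finite")
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "rsl", r)

    def rsl_at(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]):
            raise ValueError(
                f"age outside sea-level curve range "
                f"[{self.ages[0]}, {self.ages[-1]}] ka")
        return np.interp(age, self.ages, self.rsl)


@dataclass(frozen=True)
class CorrectionConfig:
    """The fixed adjustment constants.

    crust_mgca_fraction     fractional Mg/Ca reduction for tow (uncrusted)
                            samples (default 0.15)
    crust_d18O_offset       ‰ added to tow δ¹⁸O_c (default +2.0)
    cleaning_mgca_fraction  fractional Mg/Ca increase for reductively
                            cleaned samples (default 0.15; 0.10–0.15 in use)
    sl_coeff                ‰ δ¹⁸O_sw per 10 m of sea-level change (0.11)
    vital_effect_d18O       ‰ species disequilibrium offset (default 0)
    """

    crust_mgca_fraction: float = 0.15
    crust_d18O_offset: float = 2.0
    cleaning_mgca_fraction: float = 0.15
    sl_coeff: float = 0.11
    vital_effect_d18O: float = 0.0

    def __post_init__(self):
        for name in ("crust_mgca_fraction", "cleaning_mgca_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.3:
                raise ValueError(f"{name}={v} outside [0, 0.3]")
        if not self.sl_coeff > 0:
            raise ValueError("sl_coeff must be positive")


DEFAULT_CORRECTIONS = CorrectionConfig()


def _require_uncrusted(crust_state) -> None:
    cs = CrustState(crust_state)
    if cs is CrustState.CRUSTED:
        raise DoubleCorrectionError(
            "crust adjustment applies to tow/ontogenetic material only; "
            "this sample is already crusted")


def crust_adjust_mgca(mgca_tow, cfg: CorrectionConfig = DEFAULT_CORRECTIONS,
                      crust_state=CrustState.ONTOGENETIC):
    """Scale tow Mg/Ca down to the crusted-shell scale: ×(1 − fraction)."""
    _require_uncrusted(crust_state)
    mgca_tow = np.asarray(mgca_tow, dtype=float)
    if np.any(mgca_tow < 0):
        raise ValueError("Mg/Ca must be non-negative")
    return mgca_tow * (1.0 - cfg.crust_mgca_fraction)


def crust_adjust_d18O(d18Oc_tow, cfg: CorrectionConfig = DEFAULT_CORRECTIONS,
                      crust_state=CrustState.ONTOGENETIC):
    """Shift tow δ¹⁸O_c up to the crusted-shell scale: + offset."""
    _require_uncrusted(crust_state)
    return np.asarray(d18Oc_tow, dtype=float) + cfg.crust_d18O_offset


def cleaning_adjust_mgca(mgca, cleaning_method,
                         cfg: CorrectionConfig = DEFAULT_CORRECTIONS):
    """Compensate the reductive-cleaning Mg loss: ×(1 + fraction).

    Oxidatively cleaned samples pass unchanged; an unknown method passes
    unchanged with a warning.
    """
    mgca = np.asarray(mgca, dtype=float)
    method = Cleaning(cleaning_method)
    if method is Cleaning.REDUCTIVE:
        return mgca * (1.0 + cfg.cleaning_mgca_fraction)
    if method is Cleaning.UNKNOWN:
        warnings.warn("cleaning method unknown; Mg/Ca left unadjusted",
                      stacklevel=2)
    return mgca


def sealevel_correct_d18O(d18Oc, age, curve: SeaLevelCurve,
                          cfg: CorrectionConfig = DEFAULT_CORRECTIONS):
    """Remove the ice-volume δ¹⁸O_sw signal from δ¹⁸O_c.

    Adds rsl(age)/10 · sl_coeff: with rsl negative at glacials this
    subtracts the glacial enrichment (−120 m → −1.32 ‰).
    """
    rsl = curve.rsl_at(age)
    return np.asarray(d18Oc, dtype=float) + rsl / 10.0 * cfg.sl_coeff
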