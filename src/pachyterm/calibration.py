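"""Core proxy mathematics of the carbonate-ion-corrected Mg/Ca thermometer.

Mg/Ca of *N. pachyderma* responds exponentially to calcification temperature
but carries a strong non-thermal overprint from the carbonate-ion
concentration of ambient seawater.  The correction scheme implemented here:

1. predicts a temperature-only Mg/Ca from a fixed exponential law
   (default Mg/Ca_pred = 0.4·exp(0.09·T), the *N. incompta* law shared with
   its sister species),
2. normalises measured values, Mg/Ca_norm = Mg/Ca_meas / Mg/Ca_pred,
3. fits the [CO3^2-] sensitivity as a power law S = p·[CO3]^q,
4. corrects, Mg/Ca_corr = Mg/Ca_meas / S([CO3]), and
5. refits the corrected values as Mg/Ca_corr = a·exp(b·T), which inverts to
   the thermometer T = ln(Mg/Ca_corr / a) / b.

For fossil samples [CO3^2-] is not observable; δ¹⁸O_c doubles as the
carbonate-ion proxy through a shared-slope line per crust state
(δ¹⁸O_c = intercept + slope·[CO3], slope < 0, crust calcite ~2 ‰ heavier).

Fits are nonlinear least squares on the natural scale, initialised from
log-space OLS; quoted coefficient uncertainties are 2σ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = ["CrustState", "Cleaning", "ExpLaw", "PowerLaw", "OxyCarbLine",
           "CalibrationModel", "Co3FromOxygen", "DEFAULT_PREDICTION_LAW",
           "predict_mgca", "normalize_mgca", "fit_co3_sensitivity",
           "co3_sensitivity", "correct_mgca", "fit_temp_calibration",
           "invert_temperature", "fit_d18O_co3", "co3_from_d18O",
           "fit_full_chain"]


class CrustState(str, Enum):
    ONTOGENETIC = "ontogenetic"
    CRUSTED = "crusted"
    UNKNOWN = "unknown"


class Cleaning(str, Enum):
    OXIDATIVE = "oxidative"
    REDUCTIVE = "reductive"
    UNKNOWN = "unknown"


class DegenerateFitError(ValueError):
    """Fit input lacks the spread needed to identify the coefficients."""


@dataclass(frozen=True)
class ExpLaw:
    """Exponential Mg/Ca–temperature law, Mg/Ca = a·exp(b·T).

    ``a`` in mmol/mol, ``b`` in 1/°C; ``a_se``/``b_se`` are 2σ.
    """

    a: float
    b: float
    a_se: float = 0.0
    b_se: float = 0.0
    n: int = 0
    r2: float = float("nan")
    cov: tuple = ()   # 2x2 covariance of (a, b), row tuples

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"ExpLaw requires a > 0 and b > 0 (a={self.a}, b={self.b})")

    def __call__(self, temperature):
        return self.a * np.exp(self.b * np.asarray(temperature, dtype=float))

    def ci95(self, param: str) -> tuple[float, float]:
        val = getattr(self, param)
        half = 1.959964 * getattr(self, param + "_se") / 2.0
        return (val - half, val + half)


@dataclass(frozen=True)
class PowerLaw:
    """Mg/Ca–[CO3^2-] sensitivity, S = p·[CO3]^q with q < 0."""

    p: float
    q: float
    p_se: float = 0.0
    q_se: float = 0.0
    n: int = 0
    r2: float = float("nan")
    cov: tuple = ()

    def __post_init__(self):
        if not self.p > 0:
            raise ValueError(f"PowerLaw requires p > 0 (p={self.p})")
        if not self.q < 0:
            raise ValueError(f"PowerLaw requires q < 0 (q={self.q}): the "
                             "sensitivity must fall with rising carbonate ion")

    def __call__(self, co3):
        return self.p * np.asarray(co3, dtype=float) ** self.q

    def ci95(self, param: str) -> tuple[float, float]:
        val = getattr(self, param)
        half = 1.959964 * getattr(self, param + "_se") / 2.0
        return (val - half, val + half)


@dataclass(frozen=True)
class OxyCarbLine:
    """Shared-slope δ¹⁸O_c–[CO3^2-] lines, one intercept per crust state."""

    slope: float
    intercept_ontogenetic: float = float("nan")
    intercept_crusted: float = float("nan")
    slope_se: float = 0.0     # 2 sigma
    n: int = 0

    def __post_init__(self):
        if not self.slope < 0:
            raise ValueError(f"oxy-carb slope must be negative (got {self.slope})")
        ic, io = self.intercept_crusted, self.intercept_ontogenetic
        if math.isfinite(ic) and math.isfinite(io) and not ic > io:
            raise ValueError("crust calcite must be isotopically heavier "
                             f"(intercept_crusted={ic} <= intercept_ontogenetic={io})")

    def intercept(self, crust_state: CrustState | str) -> float:
        cs = CrustState(crust_state)
        if cs is CrustState.CRUSTED:
            val = self.intercept_crusted
        elif cs is CrustState.ONTOGENETIC:
            val = self.intercept_ontogenetic
        else:
            raise ValueError("crust state must be known to pick an intercept")
        if not math.isfinite(val):
            raise ValueError(f"no intercept fitted for crust state '{cs.value}'")
        return val

    def d18Oc(self, co3, crust_state) -> np.ndarray:
        return self.intercept(crust_state) + self.slope * np.asarray(co3, dtype=float)


#: temperature-only law of the uncrusted sister species N. incompta,
#: assumed shared (Mg/Ca_pred = 0.4 exp(0.09 T))
DEFAULT_PREDICTION_LAW = ExpLaw(a=0.4, b=0.09)

#: [CO3^2-] window (µmol/kg) over which the d18O proxy line is calibrated
CO3_CALIBRATION_RANGE = (0.0, 350.0)

#: above this the power-law sensitivity is extrapolated beyond the data
CO3_SENSITIVITY_MAX = 250.0


@dataclass(frozen=True)
class Co3FromOxygen:
    """A δ¹⁸O-derived carbonate-ion estimate with its calibration-range flag."""

    co3: float
    out_of_calibration: bool

    def __float__(self) -> float:
        return self.co3


@dataclass
class CalibrationModel:
    """The complete fitted coefficient set of the correction scheme."""

    prediction_law: ExpLaw = DEFAULT_PREDICTION_LAW
    power_law: PowerLaw | None = None
    exp_law: ExpLaw | None = None
    oxy_line: OxyCarbLine | None = None
    meta: dict = field(default_factory=dict)


def predict_mgca(temperature, law: ExpLaw | None = None):
    """Temperature-only predicted Mg/Ca (mmol/mol), a·exp(b·T)."""
    law = DEFAULT_PREDICTION_LAW if law is None else law
    return law(temperature)


def normalize_mgca(mgca_meas, temperature, law: ExpLaw | None = None):
    """Mg/Ca_norm = Mg/Ca_meas / Mg/Ca_pred(T): the non-thermal overprint."""
    mgca_meas = np.asarray(mgca_meas, dtype=float)
    if np.any(mgca_meas <= 0):
        raise ValueError("measured Mg/Ca must be positive")
    return mgca_meas / predict_mgca(temperature, law)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_co3_sensitivity(mgca_norm, co3) -> PowerLaw:
    """Fit the power-law sensitivity S = p·[CO3]^q to normalised Mg/Ca.

    Nonlinear least squares on the natural scale, started from the log–log
    OLS solution.  The scatter of normalised Mg/Ca is multiplicative — it
    scales with the sensitivity itself, which spans nearly a decade over
    the calibrated [CO3^2-] range — so the fit is iteratively reweighted
    with σ_i proportional to the current model prediction (unweighted
    natural-scale NLS lets the large-sensitivity end dominate and biases q
    steep).  r² is reported on the natural scale, coefficient uncertainties
    as 2σ.
    """
    y = np.asarray(mgca_norm, dtype=float)
    x = np.asarray(co3, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need >= 3 (mgca_norm, co3) pairs")
    if np.any(x <= 0):
        raise ValueError("co3 must be positive")
    if np.any(y <= 0):
        raise ValueError("normalised Mg/Ca must be positive")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all co3 values identical")
    lq, lp = np.polyfit(np.log(x), np.log(y), 1)
    popt = (math.exp(lp), lq)
    for _ in range(3):
        sigma = popt[0] * x ** popt[1]
        popt, pcov = curve_fit(lambda c, p, q: p * c ** q, x, y,
                               p0=popt, sigma=sigma, maxfev=20000)
    se2 = 2.0 * np.sqrt(np.diag(pcov))
    return PowerLaw(p=float(popt[0]), q=float(popt[1]),
                    p_se=float(se2[0]), q_se=float(se2[1]),
                    n=y.size, r2=_r2(y, popt[0] * x ** popt[1]),
                    cov=tuple(map(tuple, pcov)))


def co3_sensitivity(co3, law: PowerLaw):
    """Evaluate the sensitivity S = p·[CO3]^q (dimensionless)."""
    co3 = np.asarray(co3, dtype=float)
    if np.any(co3 <= 0):
        raise ValueError("co3 must be positive")
    return law(co3)


def correct_mgca(mgca_meas, co3, law: PowerLaw):
    """Carbonate-ion-corrected Mg/Ca: Mg/Ca_meas / S([CO3])."""
    mgca_meas = np.asarray(mgca_meas, dtype=float)
    if np.any(mgca_meas <= 0):
        raise ValueError("measured Mg/Ca must be positive")
    return mgca_meas / co3_sensitivity(co3, law)


def fit_temp_calibration(mgca_corr, temperature) -> ExpLaw:
    """Fit the corrected calibration Mg/Ca_corr = a·exp(b·T).

    The (a, b) covariance is retained on the returned law for Monte Carlo
    propagation.
    """
    y = np.asarray(mgca_corr, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if y.shape != t.shape or y.size < 3:
        raise ValueError("need >= 3 (mgca_corr, temperature) pairs")
    if np.any(y <= 0):
        raise ValueError("corrected Mg/Ca must be positive")
    if np.ptp(t) <= 2.0:
        raise DegenerateFitError(
            f"temperature span {np.ptp(t):.2f} degC too small (> 2 required)")
    lb, la = np.polyfit(t, np.log(y), 1)
    popt, pcov = curve_fit(lambda x, a, b: a * np.exp(b * x), t, y,
                           p0=(math.exp(la), lb), maxfev=20000)
    se2 = 2.0 * np.sqrt(np.diag(pcov))
    return ExpLaw(a=float(popt[0]), b=float(popt[1]),
                  a_se=float(se2[0]), b_se=float(se2[1]),
                  n=y.size, r2=_r2(y, popt[0] * np.exp(popt[1] * t)),
                  cov=tuple(map(tuple, pcov)))


def invert_temperature(mgca_corr, law: ExpLaw):
    """The thermometer: T = ln(Mg/Ca_corr / a) / b (°C)."""
    mgca_corr = np.asarray(mgca_corr, dtype=float)
    if np.any(mgca_corr <= 0):
        raise ValueError("corrected Mg/Ca must be positive")
    return np.log(mgca_corr / law.a) / law.b


def fit_d18O_co3(d18Oc, co3, crust_state) -> OxyCarbLine:
    """Shared-slope, two-intercept δ¹⁸O_c–[CO3^2-] fit (ANCOVA form).

    Crust and ontogenetic calcite share one slope but sit ~2 ‰ apart; the
    design matrix carries the common [CO3] column and one indicator per
    crust group present.  Single-group input yields one intercept, the
    other NaN.
    """
    d = np.asarray(d18Oc, dtype=float)
    x = np.asarray(co3, dtype=float)
    groups = np.asarray([CrustState(c).value for c in np.atleast_1d(crust_state)])
    if not (d.shape == x.shape == groups.shape):
        raise ValueError("d18Oc, co3 and crust_state must align")
    if np.ptp(x) == 0:
        raise DegenerateFitError("no spread in co3")
    present = [g for g in (CrustState.ONTOGENETIC.value, CrustState.CRUSTED.value)
               if np.any(groups == g)]
    if not present:
        raise ValueError("crust_state must be 'ontogenetic' or 'crusted'")
    cols = [x] + [(groups == g).astype(float) for g in present]
    design = np.column_stack(cols)
    fit = sm.OLS(d, design).fit()
    slope = float(fit.params[0])
    slope_se2 = 2.0 * float(fit.bse[0]) if d.size > len(present) + 1 else 0.0
    inter = {g: float(fit.params[1 + i]) for i, g in enumerate(present)}
    return OxyCarbLine(
        slope=slope,
        intercept_ontogenetic=inter.get(CrustState.ONTOGENETIC.value, float("nan")),
        intercept_crusted=inter.get(CrustState.CRUSTED.value, float("nan")),
        slope_se=slope_se2, n=d.size)


def co3_from_d18O(d18Oc, line: OxyCarbLine, crust_state) -> Co3FromOxygen:
    """Invert the oxygen–carbonate line: [CO3] = (δ¹⁸O_c − intercept)/slope.

    Estimates outside the calibrated window are flagged, not rejected —
    glacial samples legitimately probe the low end.
    """
    if line.slope == 0:
        raise ValueError("zero slope cannot be inverted")
    co3 = (float(d18Oc) - line.intercept(crust_state)) / line.slope
    lo, hi = CO3_CALIBRATION_RANGE
    return Co3FromOxygen(co3=co3, out_of_calibration=not (lo < co3 < hi))


def fit_full_chain(mgca_meas, temperature, co3,
                   prediction_law: ExpLaw | None = None
                   ) -> tuple[PowerLaw, ExpLaw]:
    """Run normalise → sensitivity fit → correct → calibration fit.

    Note the identifiability structure: the data constrain b, q and the
    product a·p; the a/p split is anchored by ``prediction_law`` (the
    temperature-only law assumed correct, default the *N. incompta* law).
    """
    norm = normalize_mgca(mgca_meas, temperature, prediction_law)
    power = fit_co3_sensitivity(norm, co3)
    corr = correct_mgca(mgca_meas, co3, power)
    exp = fit_temp_calibration(corr, temperature)
    return power, exp
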