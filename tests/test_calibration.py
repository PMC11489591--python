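"""The correction-scheme mathematics: laws, fits, inversions, round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pachyterm as pt
from pachyterm.calibration import (DEFAULT_PREDICTION_LAW, DegenerateFitError,
                                   ExpLaw, OxyCarbLine, PowerLaw)

TRUE_A, TRUE_B = 0.372, 0.0936
TRUE_P, TRUE_Q = 3227.95, -1.53
TRUE_SLOPE = -0.0279


class TestPredictNormalize:
    @pytest.mark.parametrize("t,expect", [
        (0.0, 0.4),
        (10.0, 0.4 * math.exp(0.9)),      # = 0.98377...
        (-2.0, 0.4 * math.exp(-0.18)),    # = 0.33410...
    ])
    def test_default_law_values(self, t, expect):
        assert pt.predict_mgca(t) == pytest.approx(expect, rel=1e-12)

    def test_normalization(self):
        assert pt.normalize_mgca(0.8, 0.0) == pytest.approx(2.0)
        assert pt.normalize_mgca(0.4, 0.0) == pytest.approx(1.0)
        assert pt.normalize_mgca(0.4 * math.exp(0.9), 10.0) == pytest.approx(1.0)

    def test_nonpositive_mgca_rejected(self):
        with pytest.raises(ValueError):
            pt.normalize_mgca(0.0, 5.0)


class TestSensitivity:
    @pytest.mark.parametrize("co3,expect", [
        (200.0, TRUE_P * 200.0 ** TRUE_Q),   # ~0.97: near-unity threshold
        (100.0, TRUE_P * 100.0 ** TRUE_Q),   # ~2.81
        (50.0, TRUE_P * 50.0 ** TRUE_Q),     # ~8.1
    ])
    def test_power_law_values(self, co3, expect):
        law = PowerLaw(p=TRUE_P, q=TRUE_Q)
        assert pt.co3_sensitivity(co3, law) == pytest.approx(expect, rel=1e-12)

    def test_published_magnitudes(self):
        law = PowerLaw(p=TRUE_P, q=TRUE_Q)
        assert pt.co3_sensitivity(200.0, law) == pytest.approx(0.97, abs=0.01)
        assert pt.co3_sensitivity(100.0, law) == pytest.approx(2.81, abs=0.01)
        assert pt.co3_sensitivity(50.0, law) == pytest.approx(8.1, abs=0.1)

    def test_correct_mgca(self):
        law = PowerLaw(p=2.0 * 120.0 ** 1.53, q=TRUE_Q)  # S(120) = 2 exactly
        assert pt.correct_mgca(0.8, 120.0, law) == pytest.approx(0.4)

    def test_forward_inverse_consistency_at_5C(self):
        law = PowerLaw(p=TRUE_P, q=TRUE_Q)
        mgca = TRUE_A * math.exp(TRUE_B * 5.0) * pt.co3_sensitivity(120.0, law)
        assert pt.correct_mgca(mgca, 120.0, law) == pytest.approx(0.594, abs=5e-4)

    def test_identity_at_unit_sensitivity(self):
        co3_unit = (1.0 / TRUE_P) ** (1.0 / TRUE_Q)
        law = PowerLaw(p=TRUE_P, q=TRUE_Q)
        assert pt.correct_mgca(1.234, co3_unit, law) == pytest.approx(1.234)

    @given(st.floats(min_value=50, max_value=220),
           st.floats(min_value=50, max_value=220))
    @settings(max_examples=50, deadline=None)
    def test_sensitivity_monotone_decreasing(self, c1, c2):
        law = PowerLaw(p=TRUE_P, q=TRUE_Q)
        if abs(c1 - c2) > 1e-9:
            lo, hi = sorted([c1, c2])
            assert pt.co3_sensitivity(lo, law) > pt.co3_sensitivity(hi, law)


class TestFits:
    def test_power_fit_noiseless_recovery(self):
        co3 = np.linspace(50, 220, 40)
        for p, q in [(TRUE_P, TRUE_Q), (100.0, -1.0)]:
            law = pt.fit_co3_sensitivity(p * co3 ** q, co3)
            assert law.p == pytest.approx(p, rel=1e-8)
            assert law.q == pytest.approx(q, abs=1e-9)
            assert law.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exp_fit_noiseless_recovery(self):
        t = np.linspace(-2, 16, 40)
        for a, b in [(TRUE_A, TRUE_B), (0.4, 0.09)]:
            law = pt.fit_temp_calibration(a * np.exp(b * t), t)
            assert law.a == pytest.approx(a, rel=1e-10)
            assert law.b == pytest.approx(b, abs=1e-10)

    def test_power_fit_degenerate_co3(self):
        with pytest.raises(DegenerateFitError):
            pt.fit_co3_sensitivity([1.0, 2.0, 3.0], [100.0, 100.0, 100.0])

    def test_exp_fit_degenerate_temperature_span(self):
        t = np.array([5.0, 5.5, 6.0])
        with pytest.raises(DegenerateFitError):
            pt.fit_temp_calibration(TRUE_A * np.exp(TRUE_B * t), t)

    def test_invert_temperature(self):
        law = ExpLaw(a=TRUE_A, b=TRUE_B)
        assert pt.invert_temperature(TRUE_A, law) == pytest.approx(0.0, abs=1e-12)
        assert pt.invert_temperature(0.594, law) == pytest.approx(5.0, abs=1e-3)

    @given(st.floats(min_value=-5, max_value=25))
    @settings(max_examples=50, deadline=None)
    def test_predict_invert_roundtrip(self, t):
        law = ExpLaw(a=TRUE_A, b=TRUE_B)
        assert pt.invert_temperature(law(t), law) == pytest.approx(t, abs=1e-10)


class TestOxyCarbLine:
    def test_noiseless_two_group_recovery(self):
        rng = np.random.default_rng(0)
        co3 = rng.uniform(50, 220, 60)
        groups = np.where(np.arange(60) % 2 == 0, "ontogenetic", "crusted")
        inter = np.where(groups == "ontogenetic", 4.0, 6.0)
        line = pt.fit_d18O_co3(inter + TRUE_SLOPE * co3, co3, groups)
        assert line.slope == pytest.approx(TRUE_SLOPE, abs=1e-12)
        assert line.intercept_ontogenetic == pytest.approx(4.0, abs=1e-10)
        assert line.intercept_crusted == pytest.approx(6.0, abs=1e-10)

    def test_single_group_leaves_other_intercept_absent(self):
        co3 = np.linspace(60, 200, 10)
        line = pt.fit_d18O_co3(4.0 + TRUE_SLOPE * co3, co3, ["ontogenetic"] * 10)
        assert line.slope == pytest.approx(TRUE_SLOPE, abs=1e-12)
        assert math.isnan(line.intercept_crusted)

    def test_noisy_slope_within_ci(self, calset, oxy_fit):
        lo = oxy_fit.slope - 0.98 * oxy_fit.slope_se
        hi = oxy_fit.slope + 0.98 * oxy_fit.slope_se
        assert lo <= TRUE_SLOPE <= hi
        offset = oxy_fit.intercept_crusted - oxy_fit.intercept_ontogenetic
        assert offset == pytest.approx(2.0, abs=0.15)

    def test_co3_from_d18O_inversion(self):
        line = OxyCarbLine(slope=TRUE_SLOPE, intercept_crusted=4.0)
        est = pt.co3_from_d18O(1.0, line, "crusted")
        assert est.co3 == pytest.approx((1.0 - 4.0) / TRUE_SLOPE)  # 107.53
        assert not est.out_of_calibration
        at_intercept = pt.co3_from_d18O(4.0, line, "crusted")
        assert at_intercept.co3 == pytest.approx(0.0, abs=1e-12)
        assert at_intercept.out_of_calibration

    def test_slope_reciprocal_increment(self):
        # one unit of CO3 is worth exactly |slope| permil
        line = OxyCarbLine(slope=TRUE_SLOPE, intercept_crusted=4.0)
        c1 = pt.co3_from_d18O(2.0, line, "crusted").co3
        c2 = pt.co3_from_d18O(2.0 - 0.0279, line, "crusted").co3
        assert c2 - c1 == pytest.approx(1.0, abs=1e-9)

    def test_invariant_crust_heavier_enforced(self):
        with pytest.raises(ValueError):
            OxyCarbLine(slope=TRUE_SLOPE, intercept_ontogenetic=6.0,
                        intercept_crusted=4.0)


class TestFullChain:
    def test_noiseless_full_chain_machine_precision(self, forward_cfg):
        """The central oracle: noiseless forward model -> exact recovery."""
        cfg = forward_cfg.zero_noise()
        df = pt.simulate_calibration_set(cfg)
        mg = np.where(df.source == "tow", pt.crust_adjust_mgca(df.mgca), df.mgca)
        power, exp = pt.fit_full_chain(mg, df.temperature.to_numpy(),
                                       df.co3.to_numpy(), cfg.true_exp_law)
        assert power.p == pytest.approx(TRUE_P, rel=1e-7)
        assert power.q == pytest.approx(TRUE_Q, abs=1e-8)
        assert exp.a == pytest.approx(TRUE_A, rel=1e-9)
        assert exp.b == pytest.approx(TRUE_B, abs=1e-9)

    def test_noisy_chain_recovers_within_ci(self, chain_fit):
        power, exp = chain_fit
        assert exp.ci95("a")[0] <= TRUE_A <= exp.ci95("a")[1]
        assert exp.ci95("b")[0] <= TRUE_B <= exp.ci95("b")[1]
        assert power.ci95("q")[0] <= TRUE_Q <= power.ci95("q")[1]

    def test_correction_inverts_forward_model_exactly(self):
        power = PowerLaw(p=TRUE_P, q=TRUE_Q)
        for t in (-2.0, 5.0, 16.0):
            for co3 in (50.0, 120.0, 220.0):
                mgca = pt.predict_mgca(t) * pt.co3_sensitivity(co3, power)
                assert pt.correct_mgca(mgca, co3, power) == pytest.approx(
                    pt.predict_mgca(t), rel=1e-12)

    def test_ci_coverage_of_chain_fits(self):
        """Over repeated noisy datasets the 95% CIs behave as advertised.

        b, q and the oxy slope cover their generating values at the nominal
        rate; the pre-exponential's final-stage CI is conservative (the
        sensitivity fit absorbs part of the shared Mg/Ca noise), so only a
        lower bound is asserted for a.
        """
        hits = {"a": 0, "b": 0, "q": 0, "oxy": 0}
        nrep = 300
        for k in range(nrep):
            cfg = pt.ForwardConfig(seed=10_000 + k)
            df = pt.simulate_calibration_set(cfg)
            mg = np.where(df.source == "tow",
                          pt.crust_adjust_mgca(df.mgca), df.mgca)
            power, exp = pt.fit_full_chain(mg, df.temperature.to_numpy(),
                                           df.co3.to_numpy(), cfg.true_exp_law)
            hits["a"] += exp.ci95("a")[0] <= TRUE_A <= exp.ci95("a")[1]
            hits["b"] += exp.ci95("b")[0] <= TRUE_B <= exp.ci95("b")[1]
            hits["q"] += power.ci95("q")[0] <= TRUE_Q <= power.ci95("q")[1]
            oxy = pt.fit_d18O_co3(df.d18Oc.to_numpy(), df.co3.to_numpy(),
                                  df.crust_state.to_numpy())
            hits["oxy"] += (oxy.slope - 0.98 * oxy.slope_se <= TRUE_SLOPE
                            <= oxy.slope + 0.98 * oxy.slope_se)
        for key in ("b", "q", "oxy"):
            assert 0.92 <= hits[key] / nrep <= 0.98, (key, hits[key] / nrep)
        assert hits["a"] / nrep >= 0.92
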