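"""Monte Carlo propagation: determinism, degenerate limits, intervals."""

import dataclasses

import numpy as np
import pytest

import pachyterm as pt
from pachyterm.synth import TRUE_EXP_LAW, TRUE_OXY_LINE, TRUE_POWER_LAW
from pachyterm.uncertainty import (UncertaintySpec, interval_summary,
                                   point_temperature,
                                   temperature_with_uncertainty)


class TestIntervalSummary:
    def test_constant_draws_zero_width(self):
        s = interval_summary(np.full(500, 3.14))
        assert s["median"] == pytest.approx(3.14)
        assert s["ci68"][0] == s["ci68"][1] == pytest.approx(3.14)
        assert s["ci95"][0] == s["ci95"][1] == pytest.approx(3.14)

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(12345).normal(0, 1, 100_000)
        s = interval_summary(draws)
        assert s["ci95"][0] == pytest.approx(-1.96, abs=0.02)
        assert s["ci95"][1] == pytest.approx(1.96, abs=0.02)
        assert s["ci68"][0] == pytest.approx(-0.994, abs=0.02)

    def test_nesting(self):
        draws = np.random.default_rng(5).exponential(2.0, 5000)
        s = interval_summary(draws)
        assert s["ci95"][0] <= s["ci68"][0] <= s["median"] \
            <= s["ci68"][1] <= s["ci95"][1]

    def test_prediction_interval_wider(self):
        draws = np.random.default_rng(6).normal(0, 1, 5000)
        s = interval_summary(draws, residual_sd=1.0)
        assert s["prediction95"][0] < s["ci95"][0]
        assert s["prediction95"][1] > s["ci95"][1]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            interval_summary(np.arange(50))


class TestSpecValidation:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            UncertaintySpec(d18O_2s=-0.1)

    def test_min_draws(self):
        with pytest.raises(ValueError):
            UncertaintySpec(n_draws=50)

    def test_uniform_perturbation_bounded(self):
        spec = UncertaintySpec(distribution="uniform")
        draws = spec.perturb(np.random.default_rng(0), 2.0, 10_000)
        assert np.all(np.abs(draws) <= 2.0)


class TestCalibrationEnsemble:
    def test_zero_noise_reproduces_point_fit(self, calset, pooled_mgca,
                                             forward_cfg, chain_fit):
        spec = UncertaintySpec(n_draws=100).zero_noise()
        ens = pt.mc_calibration_ensemble(
            pooled_mgca, calset.temperature.to_numpy(), calset.co3.to_numpy(),
            spec, prediction_law=forward_cfg.true_exp_law, seed=2)
        power, exp = chain_fit
        assert np.allclose(ens.draws["a"], exp.a)
        assert np.allclose(ens.draws["b"], exp.b)
        assert np.allclose(ens.draws["p"], power.p)
        assert np.allclose(ens.draws["q"], power.q)

    def test_same_seed_bitwise_identical(self, calset, pooled_mgca, forward_cfg):
        spec = dataclasses.replace(UncertaintySpec(), n_draws=120)
        args = (pooled_mgca, calset.temperature.to_numpy(),
                calset.co3.to_numpy(), spec)
        e1 = pt.mc_calibration_ensemble(*args, prediction_law=forward_cfg.true_exp_law,
                                        seed=42)
        e2 = pt.mc_calibration_ensemble(*args, prediction_law=forward_cfg.true_exp_law,
                                        seed=42)
        for k in e1.draws:
            assert np.array_equal(e1.draws[k], e2.draws[k])

    def test_median_exponent_near_generator(self, default_ensemble):
        med = default_ensemble.median["b"]
        assert med == pytest.approx(0.0936, abs=default_ensemble.halfwidth95("b"))

    def test_interval_nesting_invariant(self, default_ensemble):
        for k in default_ensemble.draws:
            lo68, hi68 = default_ensemble.ci68[k]
            lo95, hi95 = default_ensemble.ci95[k]
            assert lo95 <= lo68 <= default_ensemble.median[k] <= hi68 <= hi95

    def test_width_monotone_in_input_sigma(self, calset, pooled_mgca, forward_cfg):
        base = dataclasses.replace(UncertaintySpec(), n_draws=150)
        doubled = dataclasses.replace(base, temp_2s=5.6, co3_2s=40.0,
                                      mgca_corr_2s=0.4)
        args = (pooled_mgca, calset.temperature.to_numpy(), calset.co3.to_numpy())
        e1 = pt.mc_calibration_ensemble(*args, base,
                                        prediction_law=forward_cfg.true_exp_law,
                                        seed=3)
        e2 = pt.mc_calibration_ensemble(*args, doubled,
                                        prediction_law=forward_cfg.true_exp_law,
                                        seed=3)
        assert e2.halfwidth95("b") > e1.halfwidth95("b")
        assert e2.halfwidth95("a") > e1.halfwidth95("a")


class TestTemperaturePropagation:
    def _sample(self, t_true, co3):
        mgca = float(TRUE_EXP_LAW(t_true) * TRUE_POWER_LAW(co3))
        d18 = TRUE_OXY_LINE.intercept_crusted + TRUE_OXY_LINE.slope * co3
        return mgca, d18

    def test_zero_noise_collapses_to_point(self, calset, pooled_mgca,
                                           forward_cfg, chain_fit):
        spec = UncertaintySpec(n_draws=100).zero_noise()
        ens = pt.mc_calibration_ensemble(
            pooled_mgca, calset.temperature.to_numpy(), calset.co3.to_numpy(),
            spec, prediction_law=forward_cfg.true_exp_law, seed=2)
        mgca, d18 = self._sample(5.0, 130.0)
        res = temperature_with_uncertainty(mgca, d18, ens, spec,
                                           TRUE_OXY_LINE, "crusted", seed=3)
        power, exp = chain_fit
        point = point_temperature(mgca, d18, power, exp, TRUE_OXY_LINE)
        assert res.halfwidth95("temperature") == pytest.approx(0.0, abs=1e-12)
        assert res.median["temperature"] == pytest.approx(point, abs=1e-10)

    def test_truth_recovered_within_interval(self, default_ensemble):
        spec = dataclasses.replace(UncertaintySpec(), mgca_corr_2s=0.0)
        for t_true in (0.0, 8.0, 15.0):
            mgca, d18 = self._sample(t_true, float(pt.representative_co3(t_true)))
            res = temperature_with_uncertainty(mgca, d18, default_ensemble,
                                               spec, TRUE_OXY_LINE, "crusted",
                                               seed=4)
            lo, hi = res.ci95["temperature"]
            assert lo <= t_true <= hi

    def test_interval_coverage_on_synthetic_truth(self, matched_ensemble,
                                                  calset, oxy_fit):
        """95% interval contains the true temperature ~95% of the time."""
        spec = dataclasses.replace(UncertaintySpec(), temp_2s=0.0, co3_2s=0.0)
        rng = np.random.default_rng(4242)
        nrep, hit = 500, 0
        for _ in range(nrep):
            t_true = rng.uniform(-2, 16)
            co3 = rng.uniform(60, 220)
            corr = TRUE_EXP_LAW(t_true) + rng.normal(0, 0.1)
            while corr <= 0:
                corr = TRUE_EXP_LAW(t_true) + rng.normal(0, 0.1)
            mgca = float(corr * TRUE_POWER_LAW(co3))
            d18 = (TRUE_OXY_LINE.intercept_crusted + TRUE_OXY_LINE.slope * co3
                   + rng.normal(0, 0.1))
            res = temperature_with_uncertainty(mgca, d18, matched_ensemble,
                                               spec, oxy_fit, "crusted",
                                               seed=rng)
            lo, hi = res.ci95["temperature"]
            hit += lo <= t_true <= hi
        assert 0.92 <= hit / nrep <= 0.98, hit / nrep
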