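"""Shared fixtures: the synthetic study conditions, fitted once per session."""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import pachyterm as pt

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def forward_cfg():
    """Default study conditions (235 samples, stated noise), seed 0."""
    return pt.ForwardConfig(seed=0)


@pytest.fixture(scope="session")
def calset(forward_cfg):
    return pt.simulate_calibration_set(forward_cfg)


@pytest.fixture(scope="session")
def pooled_mgca(calset):
    """Measured Mg/Ca pooled on the crusted-shell scale (tows come down 15%)."""
    return np.where(calset.source == "tow",
                    pt.crust_adjust_mgca(calset.mgca), calset.mgca)


@pytest.fixture(scope="session")
def chain_fit(calset, pooled_mgca, forward_cfg):
    """(PowerLaw, ExpLaw) from the full chain anchored at the generator law."""
    return pt.fit_full_chain(pooled_mgca, calset.temperature.to_numpy(),
                             calset.co3.to_numpy(), forward_cfg.true_exp_law)


@pytest.fixture(scope="session")
def oxy_fit(calset):
    return pt.fit_d18O_co3(calset.d18Oc.to_numpy(), calset.co3.to_numpy(),
                           calset.crust_state.to_numpy())


@pytest.fixture(scope="session")
def default_ensemble(calset, pooled_mgca, forward_cfg):
    """1000-draw coefficient ensemble under the full stated uncertainties."""
    return pt.mc_calibration_ensemble(
        pooled_mgca, calset.temperature.to_numpy(), calset.co3.to_numpy(),
        pt.UncertaintySpec(), prediction_law=forward_cfg.true_exp_law, seed=1)


@pytest.fixture(scope="session")
def matched_ensemble(calset, pooled_mgca, forward_cfg):
    """Ensemble whose perturbations match the generator's noise model."""
    spec = dataclasses.replace(pt.UncertaintySpec(), temp_2s=0.0, co3_2s=0.0)
    return pt.mc_calibration_ensemble(
        pooled_mgca, calset.temperature.to_numpy(), calset.co3.to_numpy(),
        spec, prediction_law=forward_cfg.true_exp_law, seed=99)
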