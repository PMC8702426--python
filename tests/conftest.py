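"""Shared fixtures: expensive simulations are session-scoped."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests.oracles importable

from nsclc_cea.survival_models import SurvivalFit
from nsclc_cea.synthetic_data import TrialScenario, camel_like_fixture, simulate_trial_ipd


@pytest.fixture(scope="session")
def camel_fixture():
    return camel_like_fixture()


@pytest.fixture(scope="session")
def camel_data_10k(camel_fixture):
    """Large-sample simulation of the calibrated trial scenario."""
    from dataclasses import replace

    sc = replace(camel_fixture.scenario, n_per_arm=10000)
    return simulate_trial_ipd(sc, seed=1234)


@pytest.fixture(scope="session")
def true_fits(camel_fixture):
    """Parametric fits fixed at the generative truth (no estimation noise)."""
    sc = camel_fixture.scenario

    def wb(scale, shape):
        return SurvivalFit("weibull", (scale, shape), loglik=0.0, n=1, n_events=1)

    return {
        "camrelizumab": {"pfs": wb(sc.pfs_scale_exp, sc.pfs_shape_exp), "os": wb(sc.os_scale_exp, sc.os_shape_exp)},
        "chemotherapy": {"pfs": wb(sc.pfs_scale_ctrl, sc.pfs_shape_ctrl), "os": wb(sc.os_scale_ctrl, sc.os_shape_ctrl)},
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
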