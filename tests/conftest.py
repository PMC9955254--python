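"""Shared fixtures: printed reference models and small synthetic records."""

import numpy as np
import pytest

from warfadapt import model_core as mc
from warfadapt.cohort import CohortConfig


@pytest.fixture
def patient7_model():
    """Fourth-order warfarin-INR model reported for one study patient;
    its denominator has a root exactly at z = -1."""
    return mc.TransferFunctionModel(
        num=[0.09, 0.13, 0.12, 0.08, 0.001],
        den=[1.0, 0.50, -0.09, -0.45, -0.86],
    )


@pytest.fixture
def patient7_adaptive_first():
    """First adaptive-segment model of the same patient (third order)."""
    return mc.TransferFunctionModel(
        num=[0.12, -0.13, 0.04, -2.677e-5],
        den=[1.0, -1.48, 0.5, -0.008],
    )


@pytest.fixture
def default_priors():
    return mc.PrioriSet(K=10.0, r=0.95, epsilon=0.1, gamma=0.5, K_u=1.0)


@pytest.fixture
def tight_priors():
    """Near-noiseless priors with a negligible initial-condition budget."""
    return mc.PrioriSet(K=10.0, r=0.95, epsilon=1e-8, gamma=1e-6, K_u=1.0)


@pytest.fixture
def cohort_cfg():
    return CohortConfig()


def make_series(u, y_dev, baseline=1.0, pid="t"):
    """DoseResponseSeries from dose and INR-deviation arrays."""
    u = np.asarray(u, dtype=float)
    return mc.DoseResponseSeries(pid, np.arange(len(u)), u,
                                 np.asarray(y_dev, float) + baseline,
                                 inr_baseline=baseline)


@pytest.fixture
def series_factory():
    return make_series
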