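"""Shared fixtures: the linear-Gaussian conjugate toy and trained flows.

The toy simulator is ``theta ~ N(0, I3)``, ``x | theta ~ N(theta, 0.01 I3)``,
whose posterior is available in closed form:
``theta | x ~ N(x / (1 + sigma^2), sigma^2 / (1 + sigma^2) I)`` with
``sigma = 0.1``.  Training a flow on these pairs checks the whole
estimation stack against an analytic target.
"""

import numpy as np
import pytest

from ergmflow import ConditionalMAF, FlowConfig, PriorSpec, TrainingPairs, fit_ml
from ergmflow.surrogates import train_nle

LG_SIGMA = 0.1
LG_B = 20_000


def lg_posterior_mean(x_obs: np.ndarray) -> np.ndarray:
    return np.asarray(x_obs) / (1.0 + LG_SIGMA**2)


@pytest.fixture(scope="session")
def lg_pairs() -> TrainingPairs:
    rng = np.random.default_rng(2024)
    thetas = rng.standard_normal((LG_B, 3))
    xs = thetas + LG_SIGMA * rng.standard_normal((LG_B, 3))
    return TrainingPairs(
        thetas, xs, np.ones(LG_B, dtype=int), np.arange(LG_B, dtype=np.int64)
    )


@pytest.fixture(scope="session")
def lg_flow_cfg() -> FlowConfig:
    return FlowConfig(hidden_units=50, n_transforms=5, max_epochs=60, seed=11)


@pytest.fixture(scope="session")
def lg_npe_flow(lg_pairs, lg_flow_cfg) -> ConditionalMAF:
    """Posterior flow q(theta | x) trained on the conjugate toy."""
    flow = ConditionalMAF(lg_flow_cfg, 3, 3)
    return fit_ml(flow, lg_pairs.thetas, lg_pairs.stats, lg_flow_cfg)


@pytest.fixture(scope="session")
def lg_nle_flow(lg_pairs, lg_flow_cfg) -> ConditionalMAF:
    """Likelihood flow q(x | theta) trained on the same pairs."""
    return train_nle(lg_pairs, lg_flow_cfg)


@pytest.fixture(scope="session")
def unit_prior() -> PriorSpec:
    return PriorSpec(np.zeros(3), np.eye(3))
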