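import numpy as np
import pytest

from feedbackmr import SimulationConfig, StructuralParams, simulate_dataset, solve_residual_covariance


def params_for_cell(beta12, beta21, gamma11, gamma22, target_r):
    """StructuralParams with Psi solved for unit variances and target correlation."""
    psi11, psi22, psi12 = solve_residual_covariance(beta12, beta21, gamma11, gamma22, target_r)
    return StructuralParams(
        beta12=beta12, beta21=beta21, gamma11=gamma11, gamma22=gamma22,
        psi11=psi11, psi22=psi22, psi12=psi12,
    )


@pytest.fixture(scope="session")
def feedback_params():
    """A representative feedback cell: beta21=0.5, beta12=0.1, gammas 0.3, r=0.3."""
    return params_for_cell(beta12=0.1, beta21=0.5, gamma11=0.3, gamma22=0.3, target_r=0.3)


@pytest.fixture(scope="session")
def feedback_dataset(feedback_params):
    """One seeded n=10000 draw from the representative cell."""
    return simulate_dataset(SimulationConfig(params=feedback_params, n=10_000, seed=20240531))


@pytest.fixture
def rng():
    return np.random.default_rng(777)
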