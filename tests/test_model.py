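"""Population-level algebra: implied covariances, asymptotic Wald ratios,
disturbance-covariance solving, feasibility checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from feedbackmr import (
    FeedbackModelError,
    InfeasibleCellError,
    StructuralParams,
    UnstableLoopError,
    WeakInstrumentError,
    implied_covariance,
    population_residualized_wald,
    population_wald,
    solve_residual_covariance,
    solve_residual_variances,
)
from conftest import params_for_cell


# ---------------------------------------------------------------------------
# hypothesis strategies for valid model parameters
# ---------------------------------------------------------------------------

def valid_params(phi12_rho=st.just(0.0)):
    """Random valid StructuralParams; phi12 drawn as a correlation and scaled."""
    betas = st.floats(-0.7, 0.7)
    gammas = st.floats(0.05, 0.8)
    variances = st.floats(0.2, 1.5)
    rho = st.floats(-0.9, 0.9)

    @st.composite
    def build(draw):
        b12, b21 = draw(betas), draw(betas)
        if abs(b12 * b21) >= 0.95:
            b21 = 0.0
        psi11, psi22 = draw(variances), draw(variances)
        psi12 = draw(rho) * np.sqrt(psi11 * psi22)
        phi11, phi22 = draw(variances), draw(variances)
        phi12 = draw(phi12_rho) * np.sqrt(phi11 * phi22)
        return StructuralParams(
            beta12=b12, beta21=b21, gamma11=draw(gammas), gamma22=draw(gammas),
            phi11=phi11, phi22=phi22, phi12=phi12,
            psi11=psi11, psi22=psi22, psi12=psi12,
        )

    return build()


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------

def test_implied_variance_no_feedback():
    # with no feedback, var(y1) = gamma11^2 phi11 + psi11
    p = StructuralParams(gamma11=0.3, phi11=1.0, psi11=0.91, psi22=1.0)
    sigma = implied_covariance(p)
    assert sigma["y1", "y1"] == pytest.approx(1.0, abs=1e-14)


def test_implied_covariance_decoupled_model():
    # all betas and gammas zero: phenotype block is Psi, cross block is 0
    p = StructuralParams(psi11=0.7, psi22=1.2, psi12=0.4)
    sigma = implied_covariance(p)
    np.testing.assert_allclose(sigma.matrix[2:, 2:], p.Psi, atol=1e-15)
    np.testing.assert_allclose(sigma.matrix[:2, 2:], 0.0, atol=1e-15)


def test_implied_covariance_matches_simulation_oracle():
    """Closed form agrees entrywise with the empirical covariance of 1e6
    reduced-form draws coded independently of the package."""
    p = params_for_cell(beta12=0.1, beta21=0.5, gamma11=0.3, gamma22=0.3, target_r=0.3)
    n = 1_000_000
    rng = np.random.default_rng(8112)
    x = rng.standard_normal((n, 2))
    L = np.linalg.cholesky(np.array([[p.psi11, p.psi12], [p.psi12, p.psi22]]))
    zeta = rng.standard_normal((n, 2)) @ L.T
    inv_ib = np.linalg.inv(np.array([[1.0, -p.beta12], [-p.beta21, 1.0]]))
    y = (x @ np.diag([p.gamma11, p.gamma22]).T + zeta) @ inv_ib.T
    emp = np.cov(np.hstack([x, y]), rowvar=False)

    sigma = implied_covariance(p).matrix
    # MC SE of a covariance entry of a Gaussian sample
    mc_se = np.sqrt(
        (np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n
    )
    assert np.all(np.abs(emp - sigma) < 3.0 * mc_se)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(valid_params())
def test_implied_covariance_symmetric_positive_definite(p):
    sigma = implied_covariance(p).matrix
    np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
    eigvals = np.linalg.eigvalsh(sigma)
    assert eigvals.min() > -1e-10


@pytest.mark.parametrize(
    "kwargs, exc",
    [
        (dict(beta12=2.0, beta21=0.5), UnstableLoopError),
        (dict(beta12=-1.0, beta21=1.0), UnstableLoopError),
        (dict(phi11=-1.0), FeedbackModelError),
        (dict(phi12=2.0), FeedbackModelError),
        (dict(psi12=1.5), FeedbackModelError),
    ],
)
def test_invalid_params_rejected(kwargs, exc):
    with pytest.raises(exc):
        StructuralParams(**kwargs)


# ---------------------------------------------------------------------------
# population Wald ratio
# ---------------------------------------------------------------------------

@settings(max_examples=100, deadline=None, derandomize=True)
@given(valid_params())
def test_population_wald_recovers_structural_betas(p):
    """With independent instruments the asymptotic Wald ratio is exactly the
    structural causal parameter, in both directions."""
    assert population_wald(p, "y1->y2") == pytest.approx(p.beta21, abs=1e-12)
    assert population_wald(p, "y2->y1") == pytest.approx(p.beta12, abs=1e-12)


def test_population_wald_null_effect():
    p = StructuralParams(beta21=0.0, beta12=0.1, gamma11=0.3, gamma22=0.3)
    assert population_wald(p, "y1->y2") == pytest.approx(0.0, abs=1e-15)


def test_population_wald_correlated_instruments_inconsistent():
    """With phi12 != 0 the ratio no longer equals beta21; the exact limit is
    (gamma11*beta21 + phi12*gamma22) / (gamma11 + phi12*gamma22*beta12),
    derived from Sigma_xy = Phi Gamma' (I-B)^{-1}' by hand."""
    p = StructuralParams(beta21=0.5, beta12=0.1, gamma11=0.3, gamma22=0.3, phi12=0.3)
    expected = (0.3 * 0.5 + 0.3 * 0.3) / (0.3 + 0.3 * 0.3 * 0.1)
    w = population_wald(p, "y1->y2")
    assert w == pytest.approx(expected, abs=1e-12)
    assert abs(w - 0.5) > 0.05  # visibly different from the structural value


@settings(max_examples=50, deadline=None, derandomize=True)
@given(valid_params(phi12_rho=st.floats(0.05, 0.6)))
def test_population_wald_correlated_instruments_generic_gap(p):
    """For generic parameters with correlated instruments and a live feedback
    loop, the plim differs from the structural beta."""
    if abs(p.beta21) < 0.05 and abs(p.beta12) < 0.05:
        return
    gap1 = population_wald(p, "y1->y2") - p.beta21
    gap2 = population_wald(p, "y2->y1") - p.beta12
    assert max(abs(gap1), abs(gap2)) > 1e-8


def test_population_wald_irrelevant_instrument():
    p = StructuralParams(beta21=0.2, beta12=0.1, gamma11=0.0, gamma22=0.3)
    with pytest.raises(WeakInstrumentError, match="irrelevant instrument"):
        population_wald(p, "y1->y2")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(valid_params())
def test_population_residualized_wald_consistent(p):
    """Residualizing the outcome on its own instrument leaves the plim at the
    structural beta when instruments are independent."""
    assert population_residualized_wald(p, "y1->y2") == pytest.approx(p.beta21, abs=1e-12)
    assert population_residualized_wald(p, "y2->y1") == pytest.approx(p.beta12, abs=1e-12)


# ---------------------------------------------------------------------------
# solving disturbance covariances for the simulation design
# ---------------------------------------------------------------------------

def test_solve_residual_covariance_no_feedback():
    # B = 0, independent instruments: var(y) = gamma^2 + psi, corr = psi12
    psi11, psi22, psi12 = solve_residual_covariance(0.0, 0.0, 0.1, 0.1, 0.3)
    assert psi11 == pytest.approx(0.99, abs=1e-14)
    assert psi22 == pytest.approx(0.99, abs=1e-14)
    assert psi12 == pytest.approx(0.3, abs=1e-14)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(-0.6, 0.6), st.floats(-0.6, 0.6),
    st.floats(0.05, 0.5), st.floats(0.05, 0.5),
    st.floats(-0.6, 0.6),
)
def test_solve_residual_covariance_round_trip(b12, b21, g11, g22, r):
    """Feeding the solved Psi back through the implied covariance reproduces
    unit variances and the target correlation to 1e-10."""
    try:
        psi11, psi22, psi12 = solve_residual_covariance(b12, b21, g11, g22, r)
    except InfeasibleCellError:
        return
    p = StructuralParams(beta12=b12, beta21=b21, gamma11=g11, gamma22=g22,
                         psi11=psi11, psi22=psi22, psi12=psi12)
    sigma = implied_covariance(p)
    assert sigma["y1", "y1"] == pytest.approx(1.0, abs=1e-10)
    assert sigma["y2", "y2"] == pytest.approx(1.0, abs=1e-10)
    assert sigma["y1", "y2"] == pytest.approx(r, abs=1e-10)


def test_solve_residual_covariance_infeasible():
    # instrument alone explains more than the whole unit variance
    with pytest.raises(InfeasibleCellError, match="infeasible cell"):
        solve_residual_covariance(0.0, 0.0, 1.2, 0.1, 0.3)


def test_solve_residual_covariance_unstable():
    with pytest.raises(UnstableLoopError):
        solve_residual_covariance(2.0, 0.6, 0.3, 0.3, 0.3)


def test_solve_residual_variances_fixed_psi12():
    """Residual-targeting mode: psi12 fixed, variances solved to one."""
    b12, b21, g11, g22, psi12 = 0.1, 0.1, 0.3, 0.3, 0.25
    psi11, psi22 = solve_residual_variances(b12, b21, g11, g22, psi12)
    p = StructuralParams(beta12=b12, beta21=b21, gamma11=g11, gamma22=g22,
                         psi11=psi11, psi22=psi22, psi12=psi12)
    sigma = implied_covariance(p)
    assert sigma["y1", "y1"] == pytest.approx(1.0, abs=1e-10)
    assert sigma["y2", "y2"] == pytest.approx(1.0, abs=1e-10)
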