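"""Estimators of the reciprocal causal effects beta21 and beta12.

Four routes are implemented, each run separately per causal direction
(``"y1->y2"`` uses x1 to instrument y1; ``"y2->y1"`` uses x2 to instrument
y2):

wald_ratio
    Ratio of the two simple regression slopes (outcome on instrument over
    exposure on instrument).  The standard error is a delta-method expansion;
    the default "second order" form is

        var(b*) = var(b_zy)/b_zx^2 + b_zy^2 var(b_zx)/b_zx^4
                  - 2 b_zy cov(b_zx, b_zy)/b_zx^3,

    where cov(b_zx, b_zy) is estimated from the residual cross-covariance of
    the two regressions sharing the instrument (one-sample overlap).  The
    "first" order keeps only the leading term.  Significance is referred to
    the standard normal.

tsls
    Single-instrument two-stage least squares.  Its point estimate equals the
    Wald ratio algebraically; the SE is the textbook IV variance.

residualized_wald
    The outcome is first residualized on its own instrument, then the Wald
    ratio is applied.  This removes instrument-explained outcome variance and
    recovers most of the precision advantage the maximum-likelihood SEM has
    when the outcome's instrument is strong.

sem_ml_fit
    Full-information maximum likelihood for the feedback structural equation
    model, minimizing F = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - p over
    the free parameters.  With Phi fully free the model is just-identified
    (10 parameters, 10 unique covariance elements) and reproduces the sample
    covariance at the optimum.  SEs come from the numerically differentiated
    Hessian of F scaled by (n-1); per-direction significance from the
    likelihood-ratio test against the model with that beta constrained to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import Direction, FeedbackModelError, WeakInstrumentError

__all__ = [
    "EstimateResult",
    "SEMFit",
    "wald_ratio",
    "tsls",
    "residualized_wald",
    "sem_ml_fit",
    "sem_estimate_result",
]

_Z95 = 1.96  # nominal 95% interval multiplier


@dataclass(frozen=True)
class EstimateResult:
    """One causal-effect estimate with inference."""

    method: str
    direction: str
    estimate: float
    se: float
    statistic: float
    pvalue: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be nonnegative")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("estimate must lie inside its confidence interval")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "direction": self.direction,
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _columns(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        arr = data[["x1", "x2", "y1", "y2"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("data must be n x 4 in order (x1, x2, y1, y2)")
    if np.isnan(arr).any():
        raise ValueError("data contains missing values")
    return arr


def _direction_indices(direction: str) -> tuple[int, int, int, int]:
    """(instrument, exposure, outcome, outcome's own instrument) column indices."""
    if direction == "y1->y2":
        return 0, 2, 3, 1
    if direction == "y2->y1":
        return 1, 3, 2, 0
    raise ValueError(f"unknown direction {direction!r}")


def _simple_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Slope of y on x (with intercept), residuals, and centered sum Sxx."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise WeakInstrumentError("weak or irrelevant instrument: degenerate regressor")
    b = float(xc @ yc) / sxx
    return b, yc - b * xc, sxx


def _normal_result(method: str, direction: str, estimate: float, se: float) -> EstimateResult:
    z = estimate / se if se > 0 else math.inf * np.sign(estimate)
    p = 2.0 * stats.norm.sf(abs(z))
    return EstimateResult(
        method=method,
        direction=direction,
        estimate=estimate,
        se=se,
        statistic=z,
        pvalue=float(p),
        ci_low=estimate - _Z95 * se,
        ci_high=estimate + _Z95 * se,
    )


def wald_ratio(data, direction: Direction, order: str = "second") -> EstimateResult:
    """Wald-ratio estimate of the causal effect in one direction.

    Parameters
    ----------
    data : DataFrame or (n, 4) array
        Columns (x1, x2, y1, y2).
    direction : {"y1->y2", "y2->y1"}
    order : {"second", "first"}
        Delta-method expansion order for the SE (see module docstring).
    """
    arr = _columns(data)
    i_inst, i_exp, i_out, _ = _direction_indices(direction)
    n = arr.shape[0]
    x = arr[:, i_inst]

    b_zx, e_x, sxx = _simple_slope(x, arr[:, i_exp])
    b_zy, e_y, _ = _simple_slope(x, arr[:, i_out])

    sd_ratio = math.sqrt(max(np.var(arr[:, i_exp]), 1e-300) / max(np.var(x), 1e-300))
    if abs(b_zx) < 1e-10 * max(sd_ratio, 1e-300):
        raise WeakInstrumentError("weak or irrelevant instrument: denominator slope ~ 0")

    dof = n - 2
    v_zx = float(e_x @ e_x) / dof / sxx
    v_zy = float(e_y @ e_y) / dof / sxx
    c_xy = float(e_x @ e_y) / dof / sxx

    estimate = b_zy / b_zx
    var1 = v_zy / b_zx**2
    if order == "second":
        var = var1 + b_zy**2 * v_zx / b_zx**4 - 2.0 * b_zy * c_xy / b_zx**3
    elif order == "first":
        var = var1
    else:
        raise ValueError("order must be 'first' or 'second'")
    se = math.sqrt(max(var, 0.0))
    return _normal_result("wald", direction, estimate, se)


def tsls(data, direction: Direction) -> EstimateResult:
    """Two-stage least squares with the direction's single instrument.

    The point estimate is algebraically identical to :func:`wald_ratio`;
    the SE is the usual IV asymptotic variance with residual variance taken
    from the structural (second-stage-with-true-regressor) residuals.
    """
    arr = _columns(data)
    i_inst, i_exp, i_out, _ = _direction_indices(direction)
    n = arr.shape[0]
    z = arr[:, i_inst] - arr[:, i_inst].mean()
    w = arr[:, i_exp] - arr[:, i_exp].mean()
    y = arr[:, i_out] - arr[:, i_out].mean()

    szz = float(z @ z)
    szw = float(z @ w)
    if szz <= 0:
        raise WeakInstrumentError("weak or irrelevant instrument: degenerate instrument")
    sd_ratio = math.sqrt(max(float(w @ w), 1e-300) / szz)
    if abs(szw) < 1e-10 * szz * max(sd_ratio, 1e-300):
        raise WeakInstrumentError("weak or irrelevant instrument: rank-deficient first stage")

    estimate = float(z @ y) / szw
    resid = y - estimate * w
    sigma2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(sigma2 * szz) / abs(szw)
    return _normal_result("tsls", direction, estimate, se)


def residualized_wald(data, direction: Direction, order: str = "second") -> EstimateResult:
    """Wald ratio after residualizing the outcome on its own instrument.

    For direction y1->y2 the outcome y2 is replaced by the residual of the
    regression of y2 on x2 before the ratio is formed; the estimate remains
    consistent for the structural beta (with independent instruments) while
    removing the instrument-explained share of the outcome variance from the
    numerator's sampling noise.
    """
    arr = _columns(data)
    i_inst, i_exp, i_out, i_own = _direction_indices(direction)
    _, resid_out, _ = _simple_slope(arr[:, i_own], arr[:, i_out])
    arr2 = arr.copy()
    arr2[:, i_out] = resid_out
    res = wald_ratio(arr2, direction, order=order)
    return EstimateResult(**{**res.to_dict(), "method": "residualized_wald"})


# ---------------------------------------------------------------------------
# Maximum-likelihood SEM
# ---------------------------------------------------------------------------

_PARAM_NAMES = (
    "beta12",
    "beta21",
    "gamma11",
    "gamma22",
    "phi11",
    "phi22",
    "phi12",
    "psi11",
    "psi22",
    "psi12",
)

_STABILITY_BOUND = 0.99  # |beta12*beta21| kept below this during optimization


@dataclass
class SEMFit:
    """Result of the maximum-likelihood feedback-SEM fit."""

    estimates: dict
    se: dict
    loglik: float
    fmin: float
    converged: bool
    n: int
    n_restarts: int = 0
    lrt: dict = field(default_factory=dict)  # direction -> (statistic, pvalue)

    @property
    def implied_sigma(self) -> np.ndarray:
        return _sem_sigma(np.array([self.estimates[k] for k in _PARAM_NAMES]))


def _sem_sigma(theta: np.ndarray) -> np.ndarray:
    """Implied 4x4 covariance from the full 10-parameter vector."""
    b12, b21, g11, g22, p11, p22, p12, q11, q22, q12 = theta
    d = 1.0 - b12 * b21
    A = np.array([[1.0, b12], [b21, 1.0]]) / d
    Phi = np.array([[p11, p12], [p12, p22]])
    G = np.array([[g11, 0.0], [0.0, g22]])
    Psi = np.array([[q11, q12], [q12, q22]])
    s_xy = Phi @ G.T @ A.T
    s_yy = A @ (G @ Phi @ G.T + Psi) @ A.T
    return np.block([[Phi, s_xy], [s_xy.T, s_yy]])


def _make_objective(S: np.ndarray, logdet_S: float, free_idx: np.ndarray, base: np.ndarray):
    """ML discrepancy F(theta_free) with smooth penalties outside the valid region."""

    def fml(free: np.ndarray) -> float:
        theta = base.copy()
        theta[free_idx] = free
        prod = theta[0] * theta[1]
        if abs(prod) > _STABILITY_BOUND:
            return 1e6 * (1.0 + (abs(prod) - _STABILITY_BOUND))
        sigma = _sem_sigma(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e6
        try:
            trace = np.trace(np.linalg.solve(sigma, S))
        except np.linalg.LinAlgError:
            return 1e6
        return logdet + trace - logdet_S - 4.0

    return fml


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _start_values(S: np.ndarray) -> np.ndarray:
    """Spec'd starting point: Wald ratios for betas, OLS slopes for gammas,
    sample variances for Phi, Psi backed out of the sample phenotype block."""
    b21 = S[0, 3] / S[0, 2] if abs(S[0, 2]) > 1e-12 else 0.0
    b12 = S[1, 2] / S[1, 3] if abs(S[1, 3]) > 1e-12 else 0.0
    if abs(b12 * b21) > _STABILITY_BOUND:
        scale = math.sqrt(_STABILITY_BOUND / abs(b12 * b21)) * 0.95
        b12 *= scale
        b21 *= scale
    g11 = S[0, 2] / S[0, 0]
    g22 = S[1, 3] / S[1, 1]
    ib = np.array([[1.0, -b12], [-b21, 1.0]])
    G = np.array([[g11, 0.0], [0.0, g22]])
    Phi = S[:2, :2]
    Psi = ib @ S[2:, 2:] @ ib.T - G @ Phi @ G.T
    return np.array(
        [b12, b21, g11, g22, Phi[0, 0], Phi[1, 1], Phi[0, 1], Psi[0, 0], Psi[1, 1], Psi[0, 1]]
    )


def _minimize(fml, x0: np.ndarray, max_restarts: int = 5):
    rng = np.random.default_rng(951413)
    best = None
    restarts = 0
    x_start = x0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(fml, x_start, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
        ok = res.success or (np.max(np.abs(res.jac)) < 1e-5 and res.fun < 1e5)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            return res, True, attempt
        restarts = attempt + 1
        x_start = x0 * (1.0 + 0.1 * rng.standard_normal(x0.size)) + 0.01 * rng.standard_normal(
            x0.size
        )
    res, ok = best
    return res, ok, restarts


def sem_ml_fit(
    data=None,
    *,
    cov: Optional[np.ndarray] = None,
    n: Optional[int] = None,
    fix_phi12: bool = False,
    compute_se: bool = True,
    lrt: bool = True,
) -> SEMFit:
    """Fit the feedback SEM by maximum likelihood.

    Accepts either individual-level ``data`` (DataFrame / n x 4 array) or a
    precomputed 4x4 covariance via ``cov=`` and ``n=`` (covariance-input
    mode).  ``fix_phi12=True`` constrains the instrument covariance to zero
    (9 free parameters, 1 df overidentified); by default Phi is free and the
    model is just-identified.

    Raises
    ------
    FeedbackModelError
        If the sample covariance is not positive definite or n <= 10.
    """
    if cov is None:
        arr = _columns(data)
        n = arr.shape[0]
        if n <= 10:
            raise FeedbackModelError("sem_ml_fit needs n > 10")
        S = np.cov(arr, rowvar=False, ddof=1)
    else:
        S = np.asarray(cov, dtype=float)
        if n is None:
            raise FeedbackModelError("covariance-input mode requires n")
    if S.shape != (4, 4):
        raise FeedbackModelError("sample covariance must be 4x4")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet_S):
        raise FeedbackModelError("sample covariance of the 4 variables is not positive definite")

    base = np.zeros(10)
    free = [i for i, name in enumerate(_PARAM_NAMES) if not (fix_phi12 and name == "phi12")]
    free_idx = np.array(free)

    x0_full = _start_values(S)
    if fix_phi12:
        x0_full[_PARAM_NAMES.index("phi12")] = 0.0
    fml = _make_objective(S, logdet_S, free_idx, base)
    res, converged, restarts = _minimize(fml, x0_full[free_idx])

    theta = base.copy()
    theta[free_idx] = res.x
    estimates = dict(zip(_PARAM_NAMES, theta))
    fmin = float(res.fun)
    loglik = -0.5 * (n - 1) * (fmin + logdet_S + 4.0)

    ses = {name: math.nan for name in _PARAM_NAMES}
    if fix_phi12:
        ses["phi12"] = 0.0
    if compute_se and converged:
        H = _numeric_hessian(fml, res.x)
        try:
            acov = 2.0 / (n - 1) * np.linalg.inv(H)
            diag = np.diag(acov)
            for k, i in enumerate(free_idx):
                ses[_PARAM_NAMES[i]] = math.sqrt(diag[k]) if diag[k] > 0 else math.nan
        except np.linalg.LinAlgError:
            pass

    fit = SEMFit(
        estimates=estimates,
        se=ses,
        loglik=loglik,
        fmin=fmin,
        converged=bool(converged),
        n=int(n),
        n_restarts=restarts,
    )

    if lrt and converged:
        for direction, beta_name in (("y1->y2", "beta21"), ("y2->y1", "beta12")):
            bi = _PARAM_NAMES.index(beta_name)
            free_r = np.array([i for i in free_idx if i != bi])
            fml_r = _make_objective(S, logdet_S, free_r, base)
            x0_r = theta[free_r]
            res_r, ok_r, _ = _minimize(fml_r, x0_r)
            if ok_r:
                stat = max((n - 1) * (float(res_r.fun) - fmin), 0.0)
                pval = float(stats.chi2.sf(stat, df=1))
            else:
                stat, pval = math.nan, math.nan
            fit.lrt[direction] = (stat, pval)

    return fit


def sem_estimate_result(fit: SEMFit, direction: Direction) -> EstimateResult:
    """Package one direction of a SEM fit as an :class:`EstimateResult`.

    The point estimate and CI use the ML estimate and its Hessian-based SE;
    the test statistic and p-value come from the likelihood-ratio test
    (chi-square, 1 df) when available, else the Wald z-test.
    """
    beta_name = "beta21" if direction == "y1->y2" else "beta12"
    est = fit.estimates[beta_name]
    se = fit.se[beta_name]
    if direction in fit.lrt and np.isfinite(fit.lrt[direction][0]):
        stat, pval = fit.lrt[direction]
    else:
        stat = est / se if se and se > 0 else math.nan
        pval = float(2.0 * stats.norm.sf(abs(stat))) if np.isfinite(stat) else math.nan
    se_ci = se if np.isfinite(se) else 0.0
    return EstimateResult(
        method="sem_ml",
        direction=direction,
        estimate=est,
        se=se if np.isfinite(se) else 0.0,
        statistic=stat,
        pvalue=pval,
        ci_low=est - _Z95 * se_ci,
        ci_high=est + _Z95 * se_ci,
    )
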