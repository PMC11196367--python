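"""Exact population-level algebra for the two-phenotype feedback model.

The model is a nonrecursive structural equation model in LISREL form,

    y = B y + Gamma x + zeta,

with two endogenous phenotypes ``y = (y1, y2)`` that cause each other
(``beta21``: y1 -> y2, ``beta12``: y2 -> y1) and two exogenous genetic
instruments ``x = (x1, x2)``, each affecting only its own phenotype
(``gamma11``: x1 -> y1, ``gamma22``: x2 -> y2).  The disturbances
``zeta = (zeta1, zeta2)`` are latent, multivariate normal with covariance
``Psi``; ``psi12`` quantifies latent confounding between the phenotypes.
The instruments have covariance ``Phi`` (``phi12 = 0`` means independent
instruments, the standard Mendelian-randomization setting).

Solving the system gives the reduced form ``y = (I - B)^{-1}(Gamma x + zeta)``
and the implied second moments

    Sigma_yy = (I-B)^{-1} (Gamma Phi Gamma' + Psi) (I-B)^{-1}',
    Sigma_xy = Phi Gamma' (I-B)^{-1}',
    Sigma_xx = Phi.

All matrices exposed here use the fixed variable order ``(x1, x2, y1, y2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "VARIABLES",
    "Direction",
    "FeedbackModelError",
    "UnstableLoopError",
    "InfeasibleCellError",
    "WeakInstrumentError",
    "StructuralParams",
    "ImpliedCovariance",
    "implied_covariance",
    "population_wald",
    "population_residualized_wald",
    "solve_residual_covariance",
    "solve_residual_variances",
]

#: Fixed variable order used by every 4x4 matrix in the package.
VARIABLES = ("x1", "x2", "y1", "y2")

Direction = Literal["y1->y2", "y2->y1"]


class FeedbackModelError(ValueError):
    """Base class for invalid model configurations."""


class UnstableLoopError(FeedbackModelError):
    """Raised when |beta12 * beta21| >= 1 and the feedback loop diverges."""


class InfeasibleCellError(FeedbackModelError):
    """Raised when no positive-semidefinite Psi meets the variance targets."""


class WeakInstrumentError(FeedbackModelError):
    """Raised when an instrument has (near-)zero covariance with its exposure."""


@dataclass(frozen=True)
class StructuralParams:
    """All population parameters of the feedback model.

    Parameters
    ----------
    beta12 : float
        Causal effect of y2 on y1.
    beta21 : float
        Causal effect of y1 on y2.
    gamma11, gamma22 : float
        Instrument effects x1 -> y1 and x2 -> y2.
    phi11, phi22, phi12 : float
        Variances and covariance of the instruments.  ``phi12 = 0`` in the
        independent-instrument (main) setting.
    psi11, psi22, psi12 : float
        Variances and covariance of the latent disturbances.

    Raises
    ------
    UnstableLoopError
        If ``|beta12 * beta21| >= 1`` (I - B singular or the loop unstable).
    FeedbackModelError
        If Phi is not positive definite or Psi not positive semidefinite.
    """

    beta12: float = 0.0
    beta21: float = 0.0
    gamma11: float = 0.0
    gamma22: float = 0.0
    phi11: float = 1.0
    phi22: float = 1.0
    phi12: float = 0.0
    psi11: float = 1.0
    psi22: float = 1.0
    psi12: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.beta12 * self.beta21) >= 1.0:
            raise UnstableLoopError(
                "unstable feedback loop: |beta12*beta21| = "
                f"{abs(self.beta12 * self.beta21):g} >= 1"
            )
        if self.phi11 <= 0 or self.phi22 <= 0 or self.phi12**2 >= self.phi11 * self.phi22:
            raise FeedbackModelError("Phi must be positive definite")
        # Psi may sit on the PSD boundary (perfectly correlated disturbances).
        if (
            self.psi11 < 0
            or self.psi22 < 0
            or self.psi12**2 > self.psi11 * self.psi22 + 1e-12
        ):
            raise FeedbackModelError("Psi must be positive semidefinite")

    # -- LISREL matrix views ------------------------------------------------
    @property
    def B(self) -> np.ndarray:
        """2x2 coefficient matrix of the reciprocal causal effects."""
        return np.array([[0.0, self.beta12], [self.beta21, 0.0]])

    @property
    def Gamma(self) -> np.ndarray:
        """2x2 diagonal matrix of instrument effects."""
        return np.diag([self.gamma11, self.gamma22])

    @property
    def Phi(self) -> np.ndarray:
        """2x2 instrument covariance matrix."""
        return np.array([[self.phi11, self.phi12], [self.phi12, self.phi22]])

    @property
    def Psi(self) -> np.ndarray:
        """2x2 disturbance covariance matrix."""
        return np.array([[self.psi11, self.psi12], [self.psi12, self.psi22]])

    def reduced_form(self) -> np.ndarray:
        """Return ``(I - B)^{-1}``, the reduced-form multiplier matrix."""
        d = 1.0 - self.beta12 * self.beta21
        return np.array([[1.0, self.beta12], [self.beta21, 1.0]]) / d


@dataclass(frozen=True)
class ImpliedCovariance:
    """Model-implied 4x4 covariance of (x1, x2, y1, y2)."""

    matrix: np.ndarray
    labels: tuple = field(default=VARIABLES)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("implied covariance must be 4x4")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("implied covariance must be symmetric")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, key) -> float:
        i, j = key
        idx = {v: k for k, v in enumerate(self.labels)}
        return float(self.matrix[idx.get(i, i), idx.get(j, j)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))


def implied_covariance(params: StructuralParams) -> ImpliedCovariance:
    """Exact model-implied covariance of ``(x1, x2, y1, y2)``.

    Assembles ``Sigma_xx = Phi``, ``Sigma_xy = Phi Gamma' (I-B)^{-1}'`` and
    ``Sigma_yy = (I-B)^{-1}(Gamma Phi Gamma' + Psi)(I-B)^{-1}'`` in closed
    form — no sampling involved.
    """
    A = params.reduced_form()
    G, Phi, Psi = params.Gamma, params.Phi, params.Psi
    s_xx = Phi
    s_xy = Phi @ G.T @ A.T
    s_yy = A @ (G @ Phi @ G.T + Psi) @ A.T
    full = np.block([[s_xx, s_xy], [s_xy.T, s_yy]])
    return ImpliedCovariance(0.5 * (full + full.T))


def population_wald(params: StructuralParams, direction: Direction) -> float:
    """Asymptotic (probability-limit) Wald ratio for one causal direction.

    For direction ``"y1->y2"`` this is ``COV(x1, y2) / COV(x1, y1)`` computed
    from the exact implied covariance; with independent instruments
    (``phi12 = 0``) it equals the structural ``beta21`` identically.  With
    correlated instruments (``phi12 != 0``) it generally does not — the
    estimator loses consistency.

    Raises
    ------
    WeakInstrumentError
        If the instrument-exposure covariance is zero ("irrelevant
        instrument").
    """
    sigma = implied_covariance(params)
    if direction == "y1->y2":
        num, den = sigma["x1", "y2"], sigma["x1", "y1"]
    elif direction == "y2->y1":
        num, den = sigma["x2", "y1"], sigma["x2", "y2"]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if abs(den) < 1e-300:
        raise WeakInstrumentError("irrelevant instrument: COV(instrument, exposure) = 0")
    return num / den


def population_residualized_wald(params: StructuralParams, direction: Direction) -> float:
    """Probability limit of the residualized Wald ratio.

    The outcome is replaced by the residual of its regression on its own
    instrument before forming the Wald ratio; this is the population
    (implied-covariance) version of :func:`feedbackmr.estimators.residualized_wald`.
    """
    sigma = implied_covariance(params)
    if direction == "y1->y2":
        inst, exp_, out, out_inst = "x1", "y1", "y2", "x2"
    elif direction == "y2->y1":
        inst, exp_, out, out_inst = "x2", "y2", "y1", "x1"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    slope = sigma[out_inst, out] / sigma[out_inst, out_inst]
    num = sigma[inst, out] - slope * sigma[inst, out_inst]
    den = sigma[inst, exp_]
    if abs(den) < 1e-300:
        raise WeakInstrumentError("irrelevant instrument: COV(instrument, exposure) = 0")
    return num / den


def solve_residual_covariance(
    beta12: float,
    beta21: float,
    gamma11: float,
    gamma22: float,
    target_r: float,
) -> tuple[float, float, float]:
    """Disturbance covariances giving unit phenotype variances and corr ``target_r``.

    Under the main-design constraints ``phi11 = phi22 = 1``, ``phi12 = 0``,
    find the unique ``(psi11, psi22, psi12)`` such that the implied
    ``var(y1) = var(y2) = 1`` and ``corr(y1, y2) = target_r``.  Because
    ``Sigma_yy`` is affine in ``Psi`` the solution is closed form:

        Psi = (I - B) T (I - B)' - Gamma Gamma',   T = [[1, r], [r, 1]].

    Raises
    ------
    UnstableLoopError
        If ``|beta12 * beta21| >= 1``.
    InfeasibleCellError
        If the required Psi is not positive semidefinite or needs a negative
        diagonal entry; the Monte Carlo grid skips and logs such cells.
    """
    if abs(beta12 * beta21) >= 1.0:
        raise UnstableLoopError("unstable feedback loop: |beta12*beta21| >= 1")
    if not -1.0 < target_r < 1.0:
        raise InfeasibleCellError(f"target correlation {target_r} outside (-1, 1)")
    ib = np.array([[1.0, -beta12], [-beta21, 1.0]])
    T = np.array([[1.0, target_r], [target_r, 1.0]])
    psi = ib @ T @ ib.T - np.diag([gamma11**2, gamma22**2])
    psi11, psi22, psi12 = psi[0, 0], psi[1, 1], psi[0, 1]
    if psi11 < 0 or psi22 < 0 or psi12**2 > psi11 * psi22 + 1e-12:
        raise InfeasibleCellError(
            "infeasible cell: required Psi not positive semidefinite "
            f"(psi11={psi11:.4g}, psi22={psi22:.4g}, psi12={psi12:.4g})"
        )
    return float(psi11), float(psi22), float(psi12)


def solve_residual_variances(
    beta12: float,
    beta21: float,
    gamma11: float,
    gamma22: float,
    psi12: float,
) -> tuple[float, float]:
    """Disturbance variances for unit phenotype variances at a fixed ``psi12``.

    Alternative targeting mode: the residual covariance ``psi12`` is set
    directly and ``(psi11, psi22)`` are solved so the implied
    ``var(y1) = var(y2) = 1`` (``phi11 = phi22 = 1``, ``phi12 = 0``).  The
    implied total correlation then follows from the model rather than being
    a target.
    """
    if abs(beta12 * beta21) >= 1.0:
        raise UnstableLoopError("unstable feedback loop: |beta12*beta21| >= 1")
    d2 = (1.0 - beta12 * beta21) ** 2
    # var(y_i) = [A (Gamma Gamma' + Psi) A']_{ii} is affine in (psi11, psi22).
    c11 = gamma11**2
    c22 = gamma22**2
    # known contributions with psi11 = psi22 = 0
    k1 = (c11 + 2.0 * beta12 * psi12 + beta12**2 * c22) / d2
    k2 = (beta21**2 * c11 + 2.0 * beta21 * psi12 + c22) / d2
    M = np.array([[1.0, beta12**2], [beta21**2, 1.0]]) / d2
    psi11, psi22 = np.linalg.solve(M, np.array([1.0 - k1, 1.0 - k2]))
    if psi11 < 0 or psi22 < 0 or psi12**2 > psi11 * psi22 + 1e-12:
        raise InfeasibleCellError(
            "infeasible cell: required Psi not positive semidefinite "
            f"(psi11={psi11:.4g}, psi22={psi22:.4g}, psi12={psi12:.4g})"
        )
    return float(psi11), float(psi22)
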