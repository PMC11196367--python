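"""Finite-sample data generation from the feedback population model.

Samples are drawn from the reduced form ``y = (I - B)^{-1}(Gamma x + zeta)``:
instrument dosages first, then multivariate-normal disturbances, then the
phenotypes by exact linear algebra.  Two instrument modes are offered:

``standardized_biallelic`` (default)
    Allele counts from Binomial(2, maf), centred at ``2*maf`` and scaled by
    ``sqrt(2*maf*(1-maf))`` so the population variance is 1, then scaled to
    the requested ``phi`` — additive SNP dosages with unit variance.
``gaussian``
    Standard normal deviates scaled to ``phi``.  Only second moments enter
    any estimator implemented here, so the two modes are asymptotically
    interchangeable.

Instruments are drawn independently; the simulator covers the
independent-instrument design (``phi12 = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .model import StructuralParams, FeedbackModelError

__all__ = ["SimulationConfig", "simulate_dataset"]

XMode = Literal["standardized_biallelic", "gaussian"]

COLUMNS = ["x1", "x2", "y1", "y2"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one dataset, deterministically.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the same
    config always produces a bit-identical dataset.
    """

    params: StructuralParams
    n: int
    seed: object = 0
    x_mode: XMode = "standardized_biallelic"
    maf: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4 (estimators need residual df)")
        if self.x_mode not in ("standardized_biallelic", "gaussian"):
            raise ValueError(f"unknown x_mode {self.x_mode!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.params.phi12 != 0.0:
            raise FeedbackModelError(
                "simulator draws independent instruments; phi12 must be 0"
            )

    def with_seed(self, seed) -> "SimulationConfig":
        return replace(self, seed=seed)


def _psd_factor(psi: np.ndarray) -> np.ndarray:
    """Factor L with L L' = psi, tolerating a PSD-singular psi."""
    try:
        return np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(psi)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw one n x 4 sample ``(x1, x2, y1, y2)`` from the model.

    Deterministic given ``config.seed``; columns are in the package's fixed
    variable order with no missing values.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.x_mode == "standardized_biallelic":
        counts = rng.binomial(2, config.maf, size=(n, 2)).astype(float)
        x = (counts - 2.0 * config.maf) / np.sqrt(2.0 * config.maf * (1.0 - config.maf))
    else:
        x = rng.standard_normal((n, 2))
    x *= np.sqrt([p.phi11, p.phi22])

    z = rng.standard_normal((n, 2)) @ _psd_factor(p.Psi).T
    y = (x @ p.Gamma.T + z) @ p.reduced_form().T

    return pd.DataFrame(np.hstack([x, y]), columns=COLUMNS)
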