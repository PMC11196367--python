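"""Monte Carlo evaluation of the estimators over a factorial design.

The default grid reproduces the simulation study's design constants:
causal effects beta21 in {0, 0.1, 0.5} and beta12 in {0.1, -0.1, 0.5},
instrument strengths gamma11 in {0.1, 0.3} and gamma22 in {0.1, 0.3, 0.5},
total phenotype correlation r(y1, y2) in {0.1, 0.3, 0.5}, sample sizes
N = 1000..10000 in steps of 1000, 1000 replicates per cell, alpha = 0.05.
Phenotypes are constructed with unit variance by solving the disturbance
covariances per cell; cells whose required Psi is not positive semidefinite
are skipped with a log entry.

Per cell and per method x direction the harness reports the mean estimate,
bias, empirical SD, mean model SE, rejection rate (power, or type I error
when the tested beta is 0), coverage of the nominal 95% interval, and
non-convergence counts — each proportion and mean with its Monte Carlo SE
and 95% CI.

Replicate seeds derive deterministically from (root seed, cell index,
replicate index), so any cell can be recomputed in isolation and grid runs
are reproducible and parallelizable.
"""

from __future__ import annotations

import itertools
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (
    residualized_wald,
    sem_estimate_result,
    sem_ml_fit,
    tsls,
    wald_ratio,
)
from .model import FeedbackModelError, InfeasibleCellError, StructuralParams, solve_residual_covariance
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["GridSpec", "monte_carlo_se", "run_cell", "run_grid", "DEFAULT_METHODS"]

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("wald", "tsls", "residualized_wald", "sem_ml")

_DIRECTIONS = ("y1->y2", "y2->y1")

_POINT_ESTIMATORS = {
    "wald": wald_ratio,
    "tsls": tsls,
    "residualized_wald": residualized_wald,
}


@dataclass(frozen=True)
class GridSpec:
    """Factorial design for the simulation study (defaults = study design)."""

    beta21: tuple = (0.0, 0.1, 0.5)
    beta12: tuple = (0.1, -0.1, 0.5)
    gamma11: tuple = (0.1, 0.3)
    gamma22: tuple = (0.1, 0.3, 0.5)
    target_r: tuple = (0.1, 0.3, 0.5)
    n: tuple = tuple(range(1000, 10001, 1000))
    reps: int = 1000
    alpha: float = 0.05
    root_seed: int = 0
    methods: tuple = DEFAULT_METHODS
    x_mode: str = "standardized_biallelic"
    maf: float = 0.3

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ValueError(
                f"unknown methods {sorted(unknown)}; valid: {list(DEFAULT_METHODS)}"
            )
        for name in ("beta21", "beta12", "gamma11", "gamma22", "target_r", "n"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty grid: no values for {name}")

    def cells(self):
        """Cartesian product of the grid levels, with stable cell indices."""
        prod = itertools.product(
            self.beta21, self.beta12, self.gamma11, self.gamma22, self.target_r, self.n
        )
        for idx, (b21, b12, g11, g22, r, n) in enumerate(prod):
            yield idx, dict(beta21=b21, beta12=b12, gamma11=g11, gamma22=g22, target_r=r, n=n)

    @property
    def n_cells(self) -> int:
        return (
            len(self.beta21)
            * len(self.beta12)
            * len(self.gamma11)
            * len(self.gamma22)
            * len(self.target_r)
            * len(self.n)
        )


def monte_carlo_se(p_hat: float, reps: int) -> float:
    """Monte Carlo standard error of a proportion: sqrt(p(1-p)/reps)."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return math.sqrt(p_hat * (1.0 - p_hat) / reps)


def _replicate_seed(root_seed: int, cell_index: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(cell_index, rep))


@dataclass
class _Tally:
    estimates: list = field(default_factory=list)
    ses: list = field(default_factory=list)
    rejections: list = field(default_factory=list)
    covered: list = field(default_factory=list)
    n_fail: int = 0


def run_cell(
    cell: dict,
    reps: int,
    alpha: float = 0.05,
    root_seed: int = 0,
    cell_index: int = 0,
    methods: tuple = DEFAULT_METHODS,
    x_mode: str = "standardized_biallelic",
    maf: float = 0.3,
) -> pd.DataFrame:
    """Run one grid cell: ``reps`` replicates, all methods, both directions.

    ``cell`` carries beta21, beta12, gamma11, gamma22, target_r, n.  Returns
    one row per method x direction.  Deterministic given ``root_seed`` and
    ``cell_index``.

    Raises
    ------
    InfeasibleCellError
        If no valid Psi achieves unit variances at the cell's target
        correlation (callers skip and log such cells).
    ValueError
        If reps < 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    psi11, psi22, psi12 = solve_residual_covariance(
        cell["beta12"], cell["beta21"], cell["gamma11"], cell["gamma22"], cell["target_r"]
    )
    params = StructuralParams(
        beta12=cell["beta12"],
        beta21=cell["beta21"],
        gamma11=cell["gamma11"],
        gamma22=cell["gamma22"],
        psi11=psi11,
        psi22=psi22,
        psi12=psi12,
    )
    truth = {"y1->y2": cell["beta21"], "y2->y1": cell["beta12"]}
    tallies = {(m, d): _Tally() for m in methods for d in _DIRECTIONS}

    base_config = SimulationConfig(params=params, n=int(cell["n"]), x_mode=x_mode, maf=maf)
    need_sem = "sem_ml" in methods
    for rep in range(reps):
        data = simulate_dataset(base_config.with_seed(_replicate_seed(root_seed, cell_index, rep)))
        arr = data.to_numpy()
        for m in methods:
            if m == "sem_ml":
                continue
            fn = _POINT_ESTIMATORS[m]
            for d in _DIRECTIONS:
                t = tallies[(m, d)]
                try:
                    res = fn(arr, d)
                except FeedbackModelError:
                    t.n_fail += 1
                    continue
                _record(t, res, truth[d], alpha)
        if need_sem:
            try:
                fit = sem_ml_fit(arr)
                if not fit.converged:
                    raise FeedbackModelError("non-convergence")
                for d in _DIRECTIONS:
                    _record(tallies[("sem_ml", d)], sem_estimate_result(fit, d), truth[d], alpha)
            except FeedbackModelError:
                for d in _DIRECTIONS:
                    tallies[("sem_ml", d)].n_fail += 1

    rows = []
    for (m, d), t in tallies.items():
        rows.append(
            _summarize(t, cell, cell_index, m, d, truth[d], reps, alpha, psi11, psi22, psi12)
        )
    return pd.DataFrame(rows)


def _record(t: _Tally, res, true_beta: float, alpha: float) -> None:
    if not (np.isfinite(res.estimate) and np.isfinite(res.pvalue)):
        t.n_fail += 1
        return
    t.estimates.append(res.estimate)
    t.ses.append(res.se)
    t.rejections.append(res.pvalue < alpha)
    t.covered.append(res.ci_low <= true_beta <= res.ci_high)


def _summarize(t, cell, cell_index, method, direction, true_beta, reps, alpha, psi11, psi22, psi12):
    n_ok = len(t.estimates)
    row = dict(cell, cell_index=cell_index, method=method, direction=direction,
               true_beta=true_beta, reps=reps, n_ok=n_ok, n_fail=t.n_fail,
               alpha=alpha, psi11=psi11, psi22=psi22, psi12=psi12)
    if n_ok == 0:
        for key in ("mean_est", "mean_est_mcse", "bias", "emp_sd", "mean_se",
                    "rejection_rate", "rejection_mcse", "rejection_ci_low", "rejection_ci_high",
                    "coverage", "coverage_mcse", "coverage_ci_low", "coverage_ci_high"):
            row[key] = math.nan
        return row
    est = np.asarray(t.estimates)
    emp_sd = float(est.std(ddof=1)) if n_ok > 1 else math.nan
    mean_est = float(est.mean())
    mean_mcse = emp_sd / math.sqrt(n_ok) if n_ok > 1 else math.nan
    rej = float(np.mean(t.rejections))
    cov = float(np.mean(t.covered))
    rej_mcse = monte_carlo_se(rej, n_ok)
    cov_mcse = monte_carlo_se(cov, n_ok)
    row.update(
        mean_est=mean_est,
        mean_est_mcse=mean_mcse,
        bias=mean_est - true_beta,
        emp_sd=emp_sd,
        mean_se=float(np.mean(t.ses)),
        rejection_rate=rej,
        rejection_mcse=rej_mcse,
        rejection_ci_low=rej - 1.96 * rej_mcse,
        rejection_ci_high=rej + 1.96 * rej_mcse,
        coverage=cov,
        coverage_mcse=cov_mcse,
        coverage_ci_low=cov - 1.96 * cov_mcse,
        coverage_ci_high=cov + 1.96 * cov_mcse,
    )
    return row


def run_grid(
    spec: GridSpec,
    out_path: str | None = None,
    scale: float = 1.0,
    subset: dict | None = None,
    resume: bool = True,
) -> pd.DataFrame:
    """Run every (feasible) cell of the factorial design.

    ``scale`` multiplies both reps and n for desk-scale runs (minimum 1 rep,
    minimum n of 50).  ``subset`` restricts grid dimensions, e.g.
    ``{"n": [10000]}``.  With ``out_path`` results are appended cell by cell
    (CSV) and an interrupted run resumes from the cells already on disk.
    Infeasible cells are skipped with a log entry, never silently dropped.
    """
    if subset:
        spec = GridSpec(**{**_spec_dict(spec), **{k: tuple(v) for k, v in subset.items()}})
    reps = max(1, round(spec.reps * scale))
    done: set[int] = set()
    existing: pd.DataFrame | None = None
    if out_path and resume and os.path.exists(out_path):
        existing = pd.read_csv(out_path, comment="#")
        done = set(existing["cell_index"].astype(int))
        logger.info("resuming: %d cells already complete", len(done))

    frames = [] if existing is None else [existing]
    wrote_header = existing is not None
    for idx, cell in spec.cells():
        if idx in done:
            continue
        n_scaled = max(50, round(cell["n"] * scale))
        try:
            summary = run_cell(
                {**cell, "n": n_scaled},
                reps=reps,
                alpha=spec.alpha,
                root_seed=spec.root_seed,
                cell_index=idx,
                methods=spec.methods,
                x_mode=spec.x_mode,
                maf=spec.maf,
            )
        except InfeasibleCellError as exc:
            logger.warning("skipping infeasible cell %d %s: %s", idx, cell, exc)
            continue
        frames.append(summary)
        if out_path:
            summary.to_csv(out_path, mode="a", header=not wrote_header, index=False)
            wrote_header = True
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _spec_dict(spec: GridSpec) -> dict:
    return {
        "beta21": spec.beta21,
        "beta12": spec.beta12,
        "gamma11": spec.gamma11,
        "gamma22": spec.gamma22,
        "target_r": spec.target_r,
        "n": spec.n,
        "reps": spec.reps,
        "alpha": spec.alpha,
        "root_seed": spec.root_seed,
        "methods": spec.methods,
        "x_mode": spec.x_mode,
        "maf": spec.maf,
    }
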