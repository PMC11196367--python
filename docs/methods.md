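# Methods

## The population model

`feedbackmr` studies a pair of continuous phenotypes y₁, y₂ linked by a
simple linear feedback loop and instrumented by two genetic variants x₁,
x₂, one per phenotype.  In LISREL notation,

    y = B y + Γ x + ζ,
    B = [[0, β₁₂], [β₂₁, 0]],  Γ = diag(γ₁₁, γ₂₂),
    Cov(x) = Φ,  Cov(ζ) = Ψ,

with ζ the latent disturbances (pooled residual genetic and environmental
influences); ψ₁₂ is the latent confounding between the phenotypes.  The
model assumes linearity, no effect modification, multivariate-normal
disturbances, and strong valid instruments: each x affects only its own
phenotype directly.  Stability of the loop requires |β₁₂β₂₁| < 1, which
the package enforces with a hard error — the reduced form
y = (I−B)⁻¹(Γx + ζ) diverges otherwise.

All population quantities are closed-form.  The implied covariance of
(x₁, x₂, y₁, y₂) is assembled from Σ_xx = Φ, Σ_xy = ΦΓ′(I−B)⁻¹′ and
Σ_yy = (I−B)⁻¹(ΓΦΓ′+Ψ)(I−B)⁻¹′; the population Wald ratio for a direction
is the ratio of the corresponding implied covariances.  With φ₁₂ = 0 the
algebra collapses to the structural β exactly — the package's consistency
property — and with φ₁₂ ≠ 0 it does not, which `popcheck` and the test
suite demonstrate numerically.

## The simulation design

The simulator draws x, then ζ, then computes y by the reduced form.
Default instrument dosages are additive biallelic counts,
Binomial(2, maf) with maf = 0.3, standardized by their population moments
so var(x) = 1; a Gaussian mode is available and is asymptotically
equivalent because only second moments enter any estimator here.  The
allele frequency is a declared default, not an estimate: nothing in the
evaluated statistics depends on it beyond the unit-variance constraint.

Phenotypes are constructed to have variance exactly one, with a chosen
total correlation r(y₁, y₂), by solving the disturbance covariance in
closed form: Ψ = (I−B) T (I−B)′ − ΓΓ′, T = [[1, r], [r, 1]].  Parameter
combinations whose solution is not positive semidefinite are infeasible
cells; grid runs skip and log them.  The grid's r is interpreted as the
**total (marginal)** correlation; an alternative residual-targeting mode
(`solve_residual_variances`) fixes ψ₁₂ directly and solves the disturbance
variances for unit phenotype variances instead.  The factorial defaults
are β₂₁ ∈ {0, 0.1, 0.5}, β₁₂ ∈ {0.1, −0.1, 0.5}, γ₁₁ ∈ {0.1, 0.3},
γ₂₂ ∈ {0.1, 0.3, 0.5}, r ∈ {0.1, 0.3, 0.5}, N ∈ {1000, …, 10000},
1000 replicates per cell, α = 0.05.

What the generator does **not** emulate: weak or invalid instruments
(pleiotropy), non-normal disturbances, binary or censored phenotypes,
relatedness or population structure, missing data, and instrument
correlation (the simulator requires φ₁₂ = 0; correlated instruments are
handled analytically only).  Passing tests therefore speak to the linear
Gaussian feedback model, not to robustness against these violations.

## Estimators

**Wald ratio.**  β̂* = b_ZY / b_ZX, the ratio of the outcome-on-instrument
and exposure-on-instrument simple regression slopes.  The default SE is
the second-order delta expansion

    var(β̂*) ≈ var(b_ZY)/b_ZX² + b_ZY²·var(b_ZX)/b_ZX⁴
              − 2·b_ZY·cov(b_ZX, b_ZY)/b_ZX³,

with cov(b_ZX, b_ZY) = s₁₂/Sxx estimated from the cross-covariance of the
two regressions' residuals (both slopes come from the same sample, so the
one-sample-overlap term is live); `order="first"` keeps only the leading
term.  Significance is a standard-normal z-test.  A denominator slope
within 1e−10·sd-ratio of zero raises a weak-instrument error.

**2SLS.**  Single-instrument two-stage least squares; the point estimate
is algebraically the Wald ratio (an identity the tests enforce at 1e−10),
the SE is the textbook IV variance with residual df n−2.  It is
cross-checked against `statsmodels`' IV implementation in the suite.

**Residualized Wald.**  The outcome is first residualized on its *own*
instrument, then the Wald ratio is applied.  Because the two instruments
are independent, the probability limit is unchanged, but the
instrument-explained share of the outcome variance no longer contributes
sampling noise — recovering, within the IV framework, most of the SEM's
precision advantage when γ (outcome) is large.

**Maximum-likelihood SEM.**  Minimizes the Wishart discrepancy
F = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − 4 over θ = (β₁₂, β₂₁, γ₁₁, γ₂₂,
φ₁₁, φ₂₂, φ₁₂, ψ₁₁, ψ₂₂, ψ₁₂).  With Φ fully free there are 10 free
parameters against 10 unique covariance elements: the model is
just-identified and reproduces S at the optimum (F ≈ 0), which the
saturated-recovery test asserts.  `fix_phi12=True` gives the
overidentified 9-parameter variant.  Optimization is BFGS with
finite-difference gradients; starting values are the Wald ratios (betas),
OLS slopes (gammas), sample variances (Φ) and Ψ backed out of the sample
phenotype block — for the just-identified model this start is already the
ML solution up to the sample's instrument correlation, so convergence is
immediate; up to 5 jittered restarts guard against failures, and the
search rejects |β₁₂β₂₁| > 0.99.  SEs are from the numerically
differentiated Hessian of F: acov(θ̂) = (2/(n−1))·H⁻¹.  Per-direction
significance is the likelihood-ratio test, refitting with the tested β
fixed at 0 and referring (n−1)·ΔF to χ²₁.  Non-converged fits are flagged
and excluded from Monte Carlo summaries with a reported count.

All methods form nominal 95% intervals as estimate ± 1.96·SE, and each
direction is tested marginally at α = 0.05 (no multiplicity correction) —
the convention of the study the package reproduces.

## Monte Carlo harness

`run_cell` simulates, estimates (all methods, both directions) and
aggregates per cell: mean estimate, bias, empirical SD, mean model SE,
rejection rate (power, or type I error at a null β), 95%-CI coverage,
failure counts.  Every proportion carries its binomial Monte Carlo SE,
√(p̂(1−p̂)/reps), and a 95% CI; means carry SD/√reps.  Replicate seeds are
`SeedSequence(root_seed, spawn_key=(cell_index, replicate))`, so results
are bit-reproducible and cells independent.  `run_grid` iterates the
cartesian product, writes incrementally, and resumes interrupted runs from
the rows already on disk; a `scale` factor shrinks reps and n jointly for
desk-scale runs.

## Numerical and design notes

- **Power mechanics.**  For β̂₂₁ the asymptotic Wald variance reduces to
  (γ₂₂² + ψ₂₂)(1−β₁₂β₂₁)²/(n φ₁₁ γ₁₁²): it is independent of ψ₁₂ given
  ψ₂₂.  Under the unit-variance design, raising the target r lowers ψ₂₂
  and so raises asymptotic power for *both* methods; the
  Wald-gains/SEM-flat contrast visible at finite samples (and checked by
  the acceptance tests with a paired common-random-number design) is a
  genuinely finite-sample phenomenon, not an asymptotic one.
- **Problem sizes.**  The packaged checks use N = 10,000 with 1000
  replicates for calibration (type I error, coverage in the acceptance
  script), 500 replicates for the coverage test and 250 for the
  directional finite-sample patterns, and 10⁵–10⁶ draws for
  moment-convergence tests — sizes at which the Monte Carlo bands quoted
  in each test are decisive.
- **Tolerances.**  Exact algebra is asserted at 1e−12, the solver round
  trip at 1e−10, optimizer-mediated recoveries at ~1e−4, and all
  stochastic quantities at explicit multiples of their Monte Carlo SE.
- **Degenerate inputs.**  Constant columns (non-PD sample covariance),
  irrelevant instruments, unstable loops and infeasible cells raise typed
  errors (`FeedbackModelError` subclasses) rather than returning numbers.

## Known limitations

Two endogenous variables only — no networks, mediators, moderators or
multi-SNP instruments; no robust (sandwich) or weak-instrument-robust
inference; individual-level data only, no GWAS summary statistics; the
LRT and the ±1.96·SE intervals are asymptotic and were not studied below
N = 1000.
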