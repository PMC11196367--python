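# feedbackmr

Mendelian randomization (MR) when the "exposure" and the "outcome" cause
each other.  Many physiological traits sit in feedback loops, yet standard
MR treats causation as one-way.  `feedbackmr` implements the two-phenotype
linear feedback model and everything needed to study how the classical
instrumental-variable estimators and maximum-likelihood structural equation
modelling (SEM) behave under it: exact population algebra, a simulator,
four estimators, and a Monte Carlo harness for bias, power, type I error
and coverage.  It is aimed at statistical geneticists and epidemiologists
designing or sanity-checking bidirectional (reciprocal) MR analyses.

## The model

Two phenotypes y₁, y₂ and two genetic instruments x₁, x₂ follow the
nonrecursive structural equation model

    y = B y + Γ x + ζ,

with

    B = [[0, β₁₂], [β₂₁, 0]],   Γ = diag(γ₁₁, γ₂₂),
    Cov(x) = Φ,                 Cov(ζ) = Ψ,

where β₂₁ is the causal effect y₁→y₂, β₁₂ the effect y₂→y₁, γ₁₁ and γ₂₂
the instrument strengths, and ψ₁₂ the latent confounding between the
phenotypes.  Solving the loop gives the reduced form
y = (I−B)⁻¹(Γx + ζ) and the implied covariances

    Σ_yy = (I−B)⁻¹ (ΓΦΓ′ + Ψ) (I−B)⁻¹′,
    Σ_xy = ΦΓ′ (I−B)⁻¹′,
    Σ_xx = Φ.

With independent instruments (φ₁₂ = 0) the population Wald ratio
COV(x₁, y₂)/COV(x₁, y₁) equals β₂₁ exactly — running MR "both ways" with
the simple ratio remains consistent despite the loop — while with
correlated instruments it does not.  The package's estimators are the Wald
ratio (delta-method SE, second-order by default), single-instrument 2SLS,
a residualized Wald ratio (outcome pre-residualized on its own
instrument), and full maximum-likelihood SEM with likelihood-ratio tests.

## Worked example

```
$ python examples/01_population_consistency.py
Model-implied covariance of (x1, x2, y1, y2):
        x1      x2      y1      y2
x1  1.0000  0.0000  0.3158  0.1579
x2  0.0000  1.0000  0.0316  0.3158
y1  0.3158  0.0316  1.0000  0.3000
y2  0.1579  0.3158  0.3000  1.0000

population Wald y1->y2: 0.500000000000   structural beta: 0.5
population Wald y2->y1: 0.100000000000   structural beta: 0.1
-> with independent instruments both ratios equal the causal effects exactly.

phi12   Wald(y1->y2)   gap from beta21=0.5
 0.00       0.500000   +0.000000
 0.05       0.547264   +0.047264
 0.10       0.594059   +0.094059
 0.20       0.686275   +0.186275
 0.30       0.776699   +0.276699
-> correlated instruments make the Wald ratio inconsistent; the gap
   vanishes only as phi12 -> 0.
```

The covariance of x₁ with y₂ (0.158) is exactly γ₁₁β₂₁/(1−β₁₂β₂₁) — the
instrument's effect transmitted through the loop — and dividing it by
COV(x₁, y₁) returns the generating β₂₁ = 0.5 to machine precision.  The
sweep shows the consistency failure under instrument correlation.

`examples/02_estimate_feedback_effects.py` runs all four estimators on a
simulated sample of 10,000, and `examples/03_power_comparison.py`
reproduces at desk scale the headline finite-sample finding: the SEM's
precision advantage for β₂₁ appears only when the outcome's own instrument
(γ₂₂) is strong.

A thin CLI wraps the same functions:

```
feedbackmr simulate -c params.yaml -o data.csv
feedbackmr estimate -i data.csv
feedbackmr grid -o results.csv --scale 0.05
feedbackmr popcheck -c params.yaml --phi12-sweep 0,0.1,0.3
```

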