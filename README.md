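# ridgepen

Ridge regression with data-driven penalty selection, multicollinearity
diagnostics, and a Monte Carlo harness for comparing ridge-constant rules.

## The problem

In the linear model **y** = β₀ + **X**β + **μ**, strong correlation among the
columns of **X** (multicollinearity) makes the least-squares coefficients
unstable: their variances are inflated by the factors VIFⱼ = (R⁻¹)ⱼⱼ of the
predictor correlation matrix R, and small data perturbations swing the
estimates wildly. Ridge regression trades a little bias for a large variance
reduction by solving

&nbsp;&nbsp;&nbsp;&nbsp;β̂(k) = (X\*ᵀX\* + k·I)⁻¹ X\*ᵀy,&nbsp;&nbsp;k ≥ 0,

on the standardized design X\*. Everything hinges on choosing the ridge
constant k. This package implements a catalog of **14 selection rules** —
the OLS baseline (k = 0), eleven published rules (Hoerl–Kennard `HK`,
Hoerl–Kennard–Baldwin `HKB`, Lawless–Wang `LW`, Hocking–Speed–Lynn `HSL`,
the Kibria mean/geometric-mean/median rules `KAM`/`KGM`/`KMED`,
Khalaf–Shukur `KS`, Khalaf–Månsson–Shukur `KMS`,
Karaibrahimoğlu–Asar–Genç `KAG`, Shabbir–Chand–Iqbal `SCI`) — and two
condition-number-driven rules, `NEW1` and `NEW2`:

&nbsp;&nbsp;&nbsp;&nbsp;k<sub>NEW1</sub> = n·k<sub>KAG</sub>·(λ<sub>max</sub>/λ<sub>min</sub>)<sup>1/(2p)</sup>,&nbsp;&nbsp;
k<sub>NEW2</sub> = n·k<sub>KAG</sub>·(λ<sub>max</sub>/λ<sub>min</sub>)<sup>1/2</sup>,

where λ<sub>max</sub>/λ<sub>min</sub> is the eigenvalue ratio of the predictor
correlation matrix, so the shrinkage strength grows with the severity of
multicollinearity (√(λ<sub>max</sub>/λ<sub>min</sub>) is the condition
number). All rules are computed in the canonical form of the model, where
the ridge solution is the per-coordinate contraction
α̂ᵢ(k) = λᵢ/(λᵢ + k)·α̂ᵢ.

It is aimed at applied statisticians and epidemiologists fitting regression
models on ill-conditioned tabular data, and at methodologists comparing
shrinkage rules by simulation.

## Worked example

```python
import numpy as np
from ridgepen import PenalizedRidge, ScenarioSpec
from ridgepen.datasets import simulate_dataset

# n=100 observations, 4 predictors with pairwise correlation 0.95,
# true slopes (0.5, 0.5, 0.5, 0.5), noise sd 2
df, beta = simulate_dataset(ScenarioSpec(rho=0.95, p=4, sigma=2.0, n=100, N=1, seed=11))
X, y = df[["X1", "X2", "X3", "X4"]].to_numpy(), df["Y"].to_numpy()

model = PenalizedRidge(method="NEW2").fit(X, y)
print(model.k_)       # 20.4669   <- ridge constant chosen by the NEW2 rule
print(model.coef_)    # [0.0834 0.0804 0.0797 0.0866]
ols = PenalizedRidge(method="OLS").fit(X, y)
print(ols.coef_)      # [ 0.3019  0.4984 -0.2708  1.5739]
```

The OLS slopes are badly dispersed around the truth (0.5 each, squared error
1.787); the ridge fit pulls them into a tight, stable bundle (squared error
0.697). `PenalizedRidge` is a scikit-learn estimator, so it clones,
cross-validates and pipelines like any other regressor — e.g.
`GridSearchCV(PenalizedRidge(), {"method": ["HKB", "KMED", "NEW2"]})`.

The same machinery is scriptable from the shell:

```bash
ridgepen fixture --kind bodyfat_correlation --output bf.csv
ridgepen diagnose --input bf.csv --correlation --n 50
# n = 50, p = 13
# condition number           33.2257
# Farrar-Glauber chi2       933.3941
# VIF per predictor:  X1 15.0327  X2 28.9343  ... X11 96.2913 ...
```

The `evaluate` subcommand compares all 14 rules on one CSV dataset
(plug-in MSE, absolute/relative shrinkage, prediction-interval coverage);
`simulate` runs a Monte Carlo EMSE comparison over a scenario grid from a
JSON config and can plot EMSE against sample size.

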