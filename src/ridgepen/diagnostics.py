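"""Correlation-matrix-based multicollinearity diagnostics.

Three classical severity measures, all functions of the predictor
correlation matrix R:

* VIF_j: the j-th diagonal entry of R^{-1}, the factor by which collinearity
  inflates the variance of the j-th standardized coefficient;
* condition number: sqrt(lambda_max / lambda_min) of R;
* Farrar-Glauber statistic: -(n - 1 - (2p+5)/6) * ln det R, asymptotically
  chi-square with p(p-1)/2 degrees of freedom under mutual independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticsReport",
    "correlation_matrix",
    "vif",
    "condition_number",
    "farrar_glauber",
    "diagnose",
]


def _validated_eigvals(correlation: np.ndarray) -> np.ndarray:
    R = np.asarray(correlation, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("not a valid correlation matrix: must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("not a valid correlation matrix: not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("not a valid correlation matrix: diagonal must be 1")
    w = np.linalg.eigvalsh(R)
    if w[0] <= 0:
        raise ValueError("not a valid correlation matrix: not positive definite")
    return w


def correlation_matrix(predictors: np.ndarray) -> np.ndarray:
    """Sample correlation matrix of the columns of ``predictors``."""
    X = np.asarray(predictors, dtype=float)
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    if np.any(norms == 0):
        j = int(np.argmax(norms == 0))
        raise ValueError(f"predictor column {j} is constant")
    Xs = Xc / norms
    return Xs.T @ Xs


def vif(correlation: np.ndarray) -> np.ndarray:
    """Variance inflation factors: the diagonal of the inverse correlation matrix."""
    _validated_eigvals(correlation)
    R = np.asarray(correlation, dtype=float)
    return np.diag(np.linalg.inv(R)).copy()


def condition_number(correlation: np.ndarray) -> float:
    """sqrt(lambda_max / lambda_min) of the correlation matrix."""
    w = _validated_eigvals(correlation)
    return float(np.sqrt(w[-1] / w[0]))


def farrar_glauber(correlation: np.ndarray, n: int, p: int | None = None) -> float:
    """Farrar-Glauber chi-square statistic for the presence of collinearity.

    Computed as -(n - 1 - (2p+5)/6) * ln det R, with the log-determinant
    taken through the eigenvalues for numerical stability.
    """
    w = _validated_eigvals(correlation)
    if p is None:
        p = np.asarray(correlation).shape[0]
    mult = n - 1 - (2 * p + 5) / 6.0
    if mult <= 0:
        raise ValueError(f"n too small for Farrar-Glauber: n={n}, p={p}")
    return float(-mult * np.sum(np.log(w)))


@dataclass
class DiagnosticsReport:
    """Bundle of collinearity diagnostics for one predictor set."""

    correlation: np.ndarray
    vifs: np.ndarray
    condition_number: float
    farrar_glauber: float
    n: int
    p: int
    column_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Per-predictor table (VIFs), one row per column."""
        return pd.DataFrame({"predictor": self.column_names, "vif": self.vifs})

    def summary(self) -> str:
        lines = [
            f"n = {self.n}, p = {self.p}",
            f"condition number      {self.condition_number:12.4f}",
            f"Farrar-Glauber chi2   {self.farrar_glauber:12.4f}",
            "VIF per predictor:",
        ]
        for name, v in zip(self.column_names, self.vifs):
            lines.append(f"  {name:<12s} {v:12.4f}")
        return "\n".join(lines)


def diagnose(
    predictors: np.ndarray | None = None,
    correlation: np.ndarray | None = None,
    n: int | None = None,
    column_names: list[str] | None = None,
) -> DiagnosticsReport:
    """Run all diagnostics from raw predictors or a precomputed correlation.

    Exactly one of ``predictors`` / ``correlation`` must be given; with a bare
    correlation matrix the observation count ``n`` is required for the
    Farrar-Glauber statistic.
    """
    if (predictors is None) == (correlation is None):
        raise ValueError("pass exactly one of predictors or correlation")
    if predictors is not None:
        predictors = np.asarray(predictors, dtype=float)
        R = correlation_matrix(predictors)
        n = predictors.shape[0]
    else:
        R = np.asarray(correlation, dtype=float)
        if n is None:
            raise ValueError("n (number of observations) is required with a correlation matrix")
    p = R.shape[0]
    if column_names is None:
        column_names = [f"X{i + 1}" for i in range(p)]
    return DiagnosticsReport(
        correlation=R,
        vifs=vif(R),
        condition_number=condition_number(R),
        farrar_glauber=farrar_glauber(R, n=n, p=p),
        n=int(n),
        p=p,
        column_names=list(column_names),
    )
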