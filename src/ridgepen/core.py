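"""Canonical-form linear model machinery.

The ridge estimators in this package are all defined on the canonical form of
the standardized linear model: predictor columns are centered and scaled to
unit Euclidean norm (so the cross-product matrix X*'X* equals the sample
correlation matrix of the predictors), the response is centered, and the model
is rotated into the eigenbasis of X*'X*.  In that basis the ridge solution is
the per-coordinate contraction

    alpha_hat(k)_i = lambda_i / (lambda_i + k) * alpha_hat_OLS_i

which makes both the penalty formulas and the theoretical MSE cheap to
evaluate for any k.  Coefficients are mapped back to original predictor units
by undoing the rotation and the column scaling, and the intercept is
recovered from the stored means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dataset",
    "StandardizedDesign",
    "CanonicalFit",
    "RidgeFit",
    "standardize",
    "canonical_transform",
    "fit_ridge",
    "mse_theoretical",
    "mse_ols",
]

#: eigenvalue-ratio threshold below which a design is treated as singular
SINGULARITY_RTOL = 1e-12


@dataclass
class Dataset:
    """A complete-case regression dataset: numeric predictors and a response.

    Invariants (checked in :meth:`validate`): n > p >= 1, no missing values,
    every predictor column has strictly positive sample variance.
    """

    predictors: np.ndarray
    response: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.predictors = np.asarray(self.predictors, dtype=float)
        self.response = np.asarray(self.response, dtype=float).ravel()
        if self.predictors.ndim == 1:
            self.predictors = self.predictors.reshape(-1, 1)
        if not self.column_names:
            self.column_names = [f"X{i + 1}" for i in range(self.predictors.shape[1])]

    @property
    def n(self) -> int:
        return self.predictors.shape[0]

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    def validate(self) -> "Dataset":
        X, y = self.predictors, self.response
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"predictors have {X.shape[0]} rows but response has {y.shape[0]}"
            )
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("dataset contains missing or non-finite values")
        if self.n <= self.p:
            raise ValueError(
                f"underdetermined: n={self.n} observations for p={self.p} predictors"
            )
        spans = X.max(axis=0) - X.min(axis=0)
        if np.any(spans == 0.0):
            j = int(np.argmax(spans == 0.0))
            raise ValueError(
                f"predictor column {self.column_names[j]!r} is constant"
            )
        return self


@dataclass
class StandardizedDesign:
    """Centered, unit-norm predictor matrix with the bookkeeping to invert it.

    ``Xstar`` has columns centered and scaled so each has Euclidean norm 1,
    hence ``Xstar.T @ Xstar`` is the predictor correlation matrix.
    ``column_scales[j]`` is the Euclidean norm of the centered j-th column
    (= sd_j * sqrt(n-1)); dividing scaled coefficients by it returns them to
    original units.  The response is centered but not scaled.
    """

    Xstar: np.ndarray
    y_centered: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    y_mean: float
    column_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.Xstar.shape[0]

    @property
    def p(self) -> int:
        return self.Xstar.shape[1]


@dataclass
class CanonicalFit:
    """Eigenstructure of X*'X* and the OLS solution in the rotated basis.

    ``lambdas`` are the eigenvalues of the predictor correlation matrix in
    descending order (their sum is p); ``E`` the matching orthonormal
    eigenvectors, sign-fixed so each column's largest-magnitude entry is
    positive; ``Z = Xstar @ E``; ``alpha_ols`` solves the diagonal normal
    equations; ``sigma2_hat`` is the residual variance RSS/(n-p) of the OLS
    fit on the centered response.
    """

    E: np.ndarray
    lambdas: np.ndarray
    Z: np.ndarray
    alpha_ols: np.ndarray
    sigma2_hat: float
    df_resid: int


@dataclass
class RidgeFit:
    """A fitted ridge (or, at k=0, OLS) regression in every coordinate system.

    ``alpha_ridge`` lives in the canonical basis, ``beta_scaled`` on the
    standardized-predictor scale, ``beta_original`` and ``intercept`` in the
    units of the raw data.  ``sigma2_hat`` is this fit's own residual variance
    with divisor n - p.
    """

    k: float
    alpha_ridge: np.ndarray
    beta_scaled: np.ndarray
    beta_original: np.ndarray
    intercept: float
    fitted: np.ndarray
    residuals: np.ndarray
    sigma2_hat: float


def standardize(dataset: Dataset) -> StandardizedDesign:
    """Center and unit-norm-scale the predictors; center the response.

    Raises ``ValueError`` for constant predictor columns (named in the
    message) and for underdetermined problems (n <= p).
    """
    dataset.validate()
    X, y = dataset.predictors, dataset.response
    means = X.mean(axis=0)
    Xc = X - means
    scales = np.linalg.norm(Xc, axis=0)
    # validate() already rejects constant columns; scales are > 0 here
    Xstar = Xc / scales
    y_mean = float(y.mean())
    return StandardizedDesign(
        Xstar=Xstar,
        y_centered=y - y_mean,
        column_means=means,
        column_scales=scales,
        y_mean=y_mean,
        column_names=list(dataset.column_names),
    )


def _fix_eigenvector_signs(E: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude entry of each eigenvector to be positive."""
    idx = np.argmax(np.abs(E), axis=0)
    signs = np.sign(E[idx, np.arange(E.shape[1])])
    signs[signs == 0] = 1.0
    return E * signs


def canonical_transform(design: StandardizedDesign) -> CanonicalFit:
    """Rotate the standardized model into the eigenbasis of X*'X*.

    Eigenvalues come back sorted descending; the OLS coefficients solve the
    diagonal system lambda_i * alpha_i = (Z'y)_i.  A numerically singular
    correlation matrix (lambda_min / lambda_max below ``SINGULARITY_RTOL``)
    raises rather than silently pseudo-inverting.
    """
    S = design.Xstar.T @ design.Xstar
    lambdas, E = np.linalg.eigh(S)
    order = np.argsort(lambdas)[::-1]
    lambdas, E = lambdas[order], E[:, order]
    if lambdas[-1] <= SINGULARITY_RTOL * lambdas[0]:
        raise ValueError(
            "singular design: smallest eigenvalue of the correlation matrix "
            f"({lambdas[-1]:.3e}) is numerically zero"
        )
    E = _fix_eigenvector_signs(E)
    Z = design.Xstar @ E
    zty = Z.T @ design.y_centered
    alpha = zty / lambdas
    resid = design.y_centered - Z @ alpha
    df = design.n - design.p
    sigma2 = float(resid @ resid) / df
    return CanonicalFit(
        E=E, lambdas=lambdas, Z=Z, alpha_ols=alpha, sigma2_hat=sigma2, df_resid=df
    )


def fit_ridge(
    canonical: CanonicalFit, design: StandardizedDesign, k: float
) -> RidgeFit:
    """Fit the ridge regression with penalty ``k`` and back-transform.

    At k=0 this reproduces the OLS fit coordinate-wise.  Fitted values and
    residuals are on the original response scale, and ``sigma2_hat`` is this
    fit's residual sum of squares divided by n - p.
    """
    k = float(k)
    if k < 0:
        raise ValueError(f"ridge penalty k must be nonnegative, got {k}")
    shrink = canonical.lambdas / (canonical.lambdas + k)
    alpha_ridge = shrink * canonical.alpha_ols
    beta_scaled = canonical.E @ alpha_ridge
    beta_original = beta_scaled / design.column_scales
    intercept = design.y_mean - float(beta_original @ design.column_means)
    # equals intercept + X_raw @ beta_original without re-materializing X_raw
    fitted = design.y_mean + design.Xstar @ beta_scaled
    y = design.y_centered + design.y_mean
    residuals = y - fitted
    df = design.n - design.p
    sigma2 = float(residuals @ residuals) / df
    return RidgeFit(
        k=k,
        alpha_ridge=alpha_ridge,
        beta_scaled=beta_scaled,
        beta_original=beta_original,
        intercept=intercept,
        fitted=fitted,
        residuals=residuals,
        sigma2_hat=sigma2,
    )


def mse_ols(canonical: CanonicalFit) -> float:
    """Theoretical MSE of the canonical OLS estimator: sigma^2 * sum(1/lambda_i)."""
    return canonical.sigma2_hat * float(np.sum(1.0 / canonical.lambdas))


def mse_theoretical(canonical: CanonicalFit, k: float) -> float:
    """Plug-in MSE of the canonical ridge estimator at penalty ``k``.

    sigma^2 * sum lambda_i/(lambda_i+k)^2  +  k^2 * sum alpha_i^2/(lambda_i+k)^2.

    The variance term is computed as (lambda/(lambda+k)) * (1/(lambda+k)) so
    that at k=0 it reduces to sum(1/lambda) exactly, bit for bit, matching
    :func:`mse_ols`.
    """
    k = float(k)
    if k < 0:
        raise ValueError(f"ridge penalty k must be nonnegative, got {k}")
    lam = canonical.lambdas
    denom = lam + k
    var_terms = (lam / denom) * (1.0 / denom)
    variance = canonical.sigma2_hat * float(np.sum(var_terms))
    bias = (k * k) * float(np.sum(canonical.alpha_ols**2 / denom**2))
    return variance + bias
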