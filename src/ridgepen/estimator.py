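"""Scikit-learn estimator surface over the canonical-form ridge machinery."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .core import (
    Dataset,
    canonical_transform,
    fit_ridge,
    mse_theoretical,
    standardize,
)
from .penalties import METHODS, PenaltyInputs, ridge_k

__all__ = ["PenalizedRidge"]


class PenalizedRidge(RegressorMixin, BaseEstimator):
    """Ridge regression with a data-driven penalty chosen from the catalog.

    The model is fit in canonical form: predictors are centered and scaled
    to unit column norm, the response is centered, and the ridge contraction
    is applied in the eigenbasis of the predictor correlation matrix.  The
    penalty ``k`` is either computed from the fitted canonical statistics by
    one of the 14 registry rules, or supplied directly.

    Parameters
    ----------
    method : str, default "NEW2"
        Penalty rule from the registry ("OLS", "HK", "HKB", "LW", "HSL",
        "KAM", "KGM", "KMED", "KS", "KMS", "KAG", "SCI", "NEW1", "NEW2").
        "OLS" means k = 0.  Ignored when ``k`` is given.
    k : float or None, default None
        Explicit nonnegative ridge constant overriding ``method``.
    literal_ratio : bool, default False
        Use the inverted eigenvalue ratio lambda_min/lambda_max inside the
        NEW1/NEW2 rules (audit variant; shrinkage then decreases with
        collinearity severity).

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Slope coefficients in original predictor units.
    intercept_ : float
    k_ : float
        The penalty actually used.
    alpha_ols_, alpha_ : ndarray of shape (p,)
        Canonical OLS and ridge coefficients.
    lambdas_ : ndarray of shape (p,)
        Eigenvalues of the predictor correlation matrix, descending.
    eigenvectors_ : ndarray of shape (p, p)
        Matching sign-fixed eigenvectors (columns).
    sigma2_ols_, sigma2_ : float
        Residual variance (divisor n - p) of the OLS fit and of this fit.
    coef_scaled_ : ndarray of shape (p,)
        Coefficients on the standardized-predictor scale.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(40, 3)); y = X @ [1., -1., 0.5] + rng.normal(size=40)
    >>> model = PenalizedRidge(method="HKB").fit(X, y)
    >>> model.k_ > 0
    True
    """

    def __init__(
        self,
        method: str = "NEW2",
        k: float | None = None,
        literal_ratio: bool = False,
    ):
        self.method = method
        self.k = k
        self.literal_ratio = literal_ratio

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True, ensure_min_samples=2)
        names = getattr(self, "feature_names_in_", None)
        dataset = Dataset(
            predictors=X,
            response=y,
            column_names=list(names) if names is not None else [],
        )
        design = standardize(dataset)
        canonical = canonical_transform(design)
        if self.k is not None:
            k_value = float(self.k)
            if k_value < 0:
                raise ValueError(f"k must be nonnegative, got {k_value}")
        else:
            inputs = PenaltyInputs.from_canonical(canonical, n=dataset.n)
            k_value = ridge_k(
                self.method, inputs, literal_ratio=self.literal_ratio
            ).k
        ridge = fit_ridge(canonical, design, k_value)

        self.design_ = design
        self.canonical_ = canonical
        self.ridge_fit_ = ridge
        self.k_ = ridge.k
        self.coef_ = ridge.beta_original
        self.coef_scaled_ = ridge.beta_scaled
        self.intercept_ = ridge.intercept
        self.alpha_ols_ = canonical.alpha_ols
        self.alpha_ = ridge.alpha_ridge
        self.lambdas_ = canonical.lambdas
        self.eigenvectors_ = canonical.E
        self.sigma2_ols_ = canonical.sigma2_hat
        self.sigma2_ = ridge.sigma2_hat
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.intercept_ + X @ self.coef_

    def plugin_mse(self) -> float:
        """Theoretical (plug-in) MSE of the canonical coefficients at ``k_``."""
        check_is_fitted(self)
        return mse_theoretical(self.canonical_, self.k_)

    @staticmethod
    def available_methods() -> tuple[str, ...]:
        return METHODS
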