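"""The 14-rule ridge-penalty catalog.

Every rule maps the canonical-form summary statistics — residual variance
sigma^2, canonical OLS coefficients alpha_i, eigenvalues lambda_i of the
predictor correlation matrix, and the sample sizes n and p — to a single
nonnegative ridge constant k.  The catalog covers the OLS baseline (k = 0),
eleven published rules (Hoerl-Kennard and descendants), and two
condition-number-driven rules, NEW1 and NEW2, that scale the Karaibrahimoglu-
Asar-Genc constant by the sample size and a power of the eigenvalue ratio so
that the shrinkage strength grows with the severity of multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "METHODS",
    "PROPOSED_METHODS",
    "PenaltyInputs",
    "PenaltyValue",
    "ridge_k",
    "proposed_k",
    "penalty_table",
]

#: registry of ridge-constant rules, in catalog order
METHODS: tuple[str, ...] = (
    "OLS",
    "HK",
    "HKB",
    "LW",
    "HSL",
    "KAM",
    "KGM",
    "KMED",
    "KS",
    "KMS",
    "KAG",
    "SCI",
    "NEW1",
    "NEW2",
)

#: the two condition-number-driven rules
PROPOSED_METHODS: tuple[str, ...] = ("NEW1", "NEW2")

# rules whose formula divides by individual canonical coefficients
_NEEDS_ALL_NONZERO = frozenset({"KAM", "KGM", "KMED"})


@dataclass
class PenaltyValue:
    """A named ridge constant."""

    method: str
    k: float


@dataclass
class PenaltyInputs:
    """Summary statistics every penalty rule is computed from."""

    sigma2: float
    alpha: np.ndarray
    lambdas: np.ndarray
    n: int
    p: int

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.lambdas = np.asarray(self.lambdas, dtype=float).ravel()
        self.sigma2 = float(self.sigma2)
        if self.alpha.shape != self.lambdas.shape:
            raise ValueError("alpha and lambdas must have the same length")
        if self.alpha.shape[0] != self.p:
            raise ValueError(f"expected {self.p} coefficients, got {self.alpha.shape[0]}")
        if self.n <= self.p:
            raise ValueError(f"need n > p, got n={self.n}, p={self.p}")
        if self.sigma2 < 0 or not np.isfinite(self.sigma2):
            raise ValueError(f"sigma2 must be finite and nonnegative, got {self.sigma2}")
        if np.any(self.lambdas <= 0):
            raise ValueError("eigenvalues must be strictly positive")

    @classmethod
    def from_canonical(cls, canonical, n: int) -> "PenaltyInputs":
        """Build from a :class:`~ridgepen.core.CanonicalFit`."""
        p = canonical.lambdas.shape[0]
        return cls(
            sigma2=canonical.sigma2_hat,
            alpha=canonical.alpha_ols,
            lambdas=canonical.lambdas,
            n=int(n),
            p=p,
        )


def _check_divisible(method: str, inputs: PenaltyInputs) -> None:
    if method in _NEEDS_ALL_NONZERO and np.any(inputs.alpha == 0.0):
        raise ValueError(
            f"degenerate canonical coefficient: {method} divides by alpha_i "
            "and at least one alpha_i is exactly zero"
        )


def proposed_k(
    method: str, inputs: PenaltyInputs, literal_ratio: bool = False
) -> PenaltyValue:
    """Condition-number-driven ridge constants NEW1 and NEW2.

    Both start from n times the KAG constant, base = n * 5 sigma^2 /
    (lambda_max * sum alpha_i^2), and multiply by a power of the eigenvalue
    ratio r = lambda_max / lambda_min: NEW1 uses r^(1/(2p)), NEW2 uses
    r^(1/2) (the condition number itself).  With ``literal_ratio=True`` the
    ratio is inverted to lambda_min / lambda_max, under which both rules
    shrink less as collinearity worsens.
    """
    if method not in PROPOSED_METHODS:
        raise ValueError(f"unknown proposed method {method!r}; expected one of {PROPOSED_METHODS}")
    lam = inputs.lambdas
    lmax, lmin = float(lam.max()), float(lam.min())
    if lmin <= 0:
        raise ValueError("eigenvalues must be strictly positive")
    ssq = float(np.sum(inputs.alpha**2))
    if ssq == 0.0:
        raise ValueError("degenerate canonical coefficient: all alpha_i are zero")
    base = inputs.n * 5.0 * inputs.sigma2 / (lmax * ssq)
    r = lmin / lmax if literal_ratio else lmax / lmin
    exponent = 0.5 / inputs.p if method == "NEW1" else 0.5
    return PenaltyValue(method=method, k=base * r**exponent)


def ridge_k(
    method: str, inputs: PenaltyInputs, literal_ratio: bool = False
) -> PenaltyValue:
    """Compute one ridge constant from the catalog.

    Raises ``ValueError`` for a method outside the registry (the message
    lists it) and for formulas that would divide by a zero canonical
    coefficient.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; registry: {', '.join(METHODS)}")
    if method in PROPOSED_METHODS:
        return proposed_k(method, inputs, literal_ratio=literal_ratio)
    _check_divisible(method, inputs)

    s2 = inputs.sigma2
    alpha = inputs.alpha
    lam = inputs.lambdas
    n, p = inputs.n, inputs.p
    a2 = alpha**2
    amax2 = float(a2.max())
    lmax = float(lam.max())

    if method == "OLS":
        return PenaltyValue(method, 0.0)
    if method == "HK":
        if amax2 == 0.0:
            raise ValueError("degenerate canonical coefficient: max alpha_i^2 is zero")
        return PenaltyValue(method, s2 / amax2)
    if method == "HKB":
        ssq = float(a2.sum())
        if ssq == 0.0:
            raise ValueError("degenerate canonical coefficient: all alpha_i are zero")
        return PenaltyValue(method, p * s2 / ssq)
    if method == "LW":
        w = float((lam * a2).sum())
        if w == 0.0:
            raise ValueError("degenerate canonical coefficient: all alpha_i are zero")
        return PenaltyValue(method, p * s2 / w)
    if method == "HSL":
        w = float((lam * a2).sum())
        if w == 0.0:
            raise ValueError("degenerate canonical coefficient: all alpha_i are zero")
        return PenaltyValue(method, s2 * float((lam**2 * a2).sum()) / w**2)
    if method == "KAM":
        return PenaltyValue(method, (s2 / p) * float(np.sum(1.0 / a2)))
    if method == "KGM":
        # geometric mean of sigma^2/alpha_i^2, computed in log space
        return PenaltyValue(method, s2 * float(np.exp(-np.mean(np.log(a2)))))
    if method == "KMED":
        return PenaltyValue(method, float(np.median(s2 / a2)))
    if method == "KS":
        denom = (n - p) * s2 + lmax * amax2
        if denom == 0.0:
            raise ValueError("degenerate canonical coefficient: KS denominator is zero")
        return PenaltyValue(method, s2 * lmax / denom)
    if method == "KMS":
        asum = float(np.abs(alpha).sum())
        if asum == 0.0 or amax2 == 0.0:
            raise ValueError("degenerate canonical coefficient: all alpha_i are zero")
        return PenaltyValue(method, (lmax / asum) * (s2 / amax2))
    if method == "KAG":
        ssq = float(a2.sum())
        if ssq == 0.0:
            raise ValueError("degenerate canonical coefficient: all alpha_i are zero")
        return PenaltyValue(method, 5.0 * s2 / (lmax * ssq))
    if method == "SCI":
        return PenaltyValue(method, (p + 1) * s2)
    raise AssertionError(f"unhandled method {method}")  # pragma: no cover


def penalty_table(
    inputs: PenaltyInputs,
    methods: tuple[str, ...] | list[str] = METHODS,
    literal_ratio: bool = False,
) -> dict[str, float]:
    """Compute several ridge constants at once; returns {method: k}."""
    return {
        m: ridge_k(m, inputs, literal_ratio=literal_ratio).k for m in methods
    }
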