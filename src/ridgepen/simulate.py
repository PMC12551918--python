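"""Monte Carlo EMSE comparison of the ridge-penalty catalog.

The simulation scheme: draw an n x p design from a mean-zero multivariate
normal with unit variances and common pairwise correlation rho; fix a
unit-norm slope vector beta (intercept zero); then, over N replications,
redraw normal errors with standard deviation sigma, form the response,
refit every estimator in the catalog, and average the squared coefficient
error (beta_hat - beta)'(beta_hat - beta) over the p slopes in original
units.  By default the design is drawn once and held fixed across
replications (``redraw_X=True`` redraws it each time).

With a fixed design the standardization and eigenstructure of X never
change, so they are computed once per scenario and only the response-side
quantities are recomputed per replication — algebraically identical to
rerunning the full pipeline each time, just cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Dataset, canonical_transform, standardize
from .penalties import METHODS, PenaltyInputs, penalty_table

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "equicorrelated_sigma",
    "make_beta",
    "run_scenario",
    "run_grid",
    "results_to_frame",
]

#: fraction of degenerate replications tolerated before a scenario errors out
MAX_SKIP_FRACTION = 0.01


def equicorrelated_sigma(p: int, rho: float) -> np.ndarray:
    """Unit-diagonal covariance with all off-diagonal entries equal to rho.

    Positive definite iff -1/(p-1) < rho < 1 (eigenvalues 1 + (p-1) rho and
    1 - rho).
    """
    if p < 1:
        raise ValueError(f"p must be positive, got {p}")
    lo = -1.0 / (p - 1) if p > 1 else -1.0
    if not (lo < rho < 1.0):
        raise ValueError(
            f"rho={rho} outside the positive-definite range ({lo:.4g}, 1) for p={p}"
        )
    S = np.full((p, p), float(rho))
    np.fill_diagonal(S, 1.0)
    return S


def make_beta(
    rule: str, p: int, design: np.ndarray | None = None
) -> np.ndarray:
    """Unit-norm slope vector for the simulation.

    ``equal``: every entry 1/sqrt(p).  ``eigvec_max``: the unit eigenvector
    of the design correlation matrix for its largest eigenvalue, sign-fixed
    so the entries sum positive (for an equicorrelated design with rho > 0
    this coincides with ``equal``).
    """
    if rule == "equal":
        return np.full(p, 1.0 / np.sqrt(p))
    if rule == "eigvec_max":
        if design is None:
            raise ValueError("eigvec_max rule requires a design matrix")
        from .diagnostics import correlation_matrix

        R = correlation_matrix(np.asarray(design, dtype=float))
        w, V = np.linalg.eigh(R)
        v = V[:, -1]
        if v.sum() < 0:
            v = -v
        return v / np.linalg.norm(v)
    raise ValueError(f"unknown beta rule {rule!r}; expected 'equal' or 'eigvec_max'")


@dataclass
class ScenarioSpec:
    """One simulation cell: correlation level, dimensions, noise, replications."""

    rho: float
    p: int
    sigma: float
    n: int
    N: int = 10000
    seed: int = 0
    beta_rule: str = "equal"
    redraw_X: bool = False

    def __post_init__(self) -> None:
        if self.n <= self.p:
            raise ValueError(f"need n > p, got n={self.n}, p={self.p}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.N < 1:
            raise ValueError(f"N must be positive, got {self.N}")
        equicorrelated_sigma(self.p, self.rho)  # validates rho range

    def label(self) -> tuple:
        """Scenario identity (excludes seed and N)."""
        return (self.rho, self.p, self.sigma, self.n, self.beta_rule, self.redraw_X)


@dataclass
class ScenarioResult:
    """Per-method EMSE (and its Monte Carlo standard error) for one scenario."""

    spec: ScenarioSpec
    emse: dict[str, float]
    mc_stderr: dict[str, float]
    best_method: str
    n_skipped: int = 0
    methods: tuple[str, ...] = field(default=METHODS)


def _draw_design(rng: np.random.Generator, spec: ScenarioSpec) -> np.ndarray:
    S = equicorrelated_sigma(spec.p, spec.rho)
    L = np.linalg.cholesky(S)
    return rng.standard_normal((spec.n, spec.p)) @ L.T


def _sq_errors_fixed_design(
    X: np.ndarray,
    beta: np.ndarray,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    methods: tuple[str, ...],
    literal_ratio: bool,
) -> tuple[np.ndarray, int]:
    """Per-replication squared coefficient errors with X held fixed.

    Returns an (N_kept, n_methods) array and the number of skipped
    replications (exact-zero canonical coefficients; measure-zero events).
    """
    design = standardize(Dataset(predictors=X, response=np.zeros(spec.n)).validate())
    canonical = canonical_transform(design)
    E, lam, Z = canonical.E, canonical.lambdas, canonical.Z
    scales = design.column_scales
    n, p = spec.n, spec.p
    df = n - p
    signal = X @ beta
    errors = np.empty((spec.N, len(methods)))
    skipped = 0
    row = 0
    for _ in range(spec.N):
        mu = spec.sigma * rng.standard_normal(n)
        y = signal + mu
        yc = y - y.mean()
        w = Z.T @ yc
        alpha = w / lam
        if np.any(alpha == 0.0):
            skipped += 1
            continue
        rss = float(yc @ yc - w @ alpha)
        sigma2 = max(rss, 0.0) / df
        inputs = PenaltyInputs(sigma2=sigma2, alpha=alpha, lambdas=lam, n=n, p=p)
        ks = penalty_table(inputs, methods, literal_ratio=literal_ratio)
        for j, m in enumerate(methods):
            shrink = lam / (lam + ks[m])
            beta_hat = (E @ (shrink * alpha)) / scales
            d = beta_hat - beta
            errors[row, j] = float(d @ d)
        row += 1
    return errors[:row], skipped


def run_scenario(
    spec: ScenarioSpec,
    methods: tuple[str, ...] | list[str] = METHODS,
    literal_ratio: bool = False,
) -> ScenarioResult:
    """Run one simulation cell and return per-method EMSE summaries.

    Fully reproducible from ``spec.seed``: the generator first draws the
    design (once, or per replication with ``redraw_X``), then consumes one
    error vector per replication, independent of which methods are
    requested.
    """
    methods = tuple(methods)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; registry: {', '.join(METHODS)}")
    rng = np.random.default_rng(spec.seed)

    if not spec.redraw_X:
        X = _draw_design(rng, spec)
        beta = make_beta(spec.beta_rule, spec.p, design=X)
        errors, skipped = _sq_errors_fixed_design(
            X, beta, spec, rng, methods, literal_ratio
        )
    else:
        rows = []
        skipped = 0
        one = replace(spec, N=1, redraw_X=False)
        for _ in range(spec.N):
            X = _draw_design(rng, spec)
            beta = make_beta(spec.beta_rule, spec.p, design=X)
            try:
                err, sk = _sq_errors_fixed_design(
                    X, beta, one, rng, methods, literal_ratio
                )
            except ValueError:
                skipped += 1
                continue
            skipped += sk
            if err.shape[0]:
                rows.append(err[0])
        errors = np.asarray(rows)

    if skipped > MAX_SKIP_FRACTION * spec.N:
        raise ValueError(
            f"{skipped} of {spec.N} replications degenerate (> {MAX_SKIP_FRACTION:.0%})"
        )
    kept = errors.shape[0]
    emse = {m: float(errors[:, j].mean()) for j, m in enumerate(methods)}
    stderr = {
        m: float(errors[:, j].std(ddof=1) / np.sqrt(kept)) if kept > 1 else float("nan")
        for j, m in enumerate(methods)
    }
    best = min(emse, key=emse.get)
    return ScenarioResult(
        spec=spec,
        emse=emse,
        mc_stderr=stderr,
        best_method=best,
        n_skipped=skipped,
        methods=methods,
    )


def run_grid(
    specs: list[ScenarioSpec],
    master_seed: int | None = None,
    methods: tuple[str, ...] | list[str] = METHODS,
    literal_ratio: bool = False,
) -> list[ScenarioResult]:
    """Run a list of scenarios; optionally derive per-scenario seeds.

    With ``master_seed`` given, each scenario's seed is replaced by a
    deterministic child of the master seed (same order as ``specs``), so the
    whole grid is reproducible from one integer.  Duplicate scenario labels
    are rejected.
    """
    if not specs:
        raise ValueError("empty scenario list")
    labels = [s.label() for s in specs]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValueError(f"duplicate scenario label {dup}")
    if master_seed is not None:
        children = np.random.SeedSequence(master_seed).spawn(len(specs))
        specs = [
            replace(s, seed=int(c.generate_state(1)[0] % (2**31)))
            for s, c in zip(specs, children)
        ]
    return [
        run_scenario(s, methods=methods, literal_ratio=literal_ratio) for s in specs
    ]


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy table: one row per scenario x method, with the row minimum flagged."""
    rows = []
    for res in results:
        s = res.spec
        for m in res.methods:
            rows.append(
                {
                    "rho": s.rho,
                    "p": s.p,
                    "sigma": s.sigma,
                    "n": s.n,
                    "N": s.N,
                    "seed": s.seed,
                    "beta_rule": s.beta_rule,
                    "redraw_X": s.redraw_X,
                    "method": m,
                    "emse": res.emse[m],
                    "mc_stderr": res.mc_stderr[m],
                    "best_flag": m == res.best_method,
                }
            )
    return pd.DataFrame(rows)
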