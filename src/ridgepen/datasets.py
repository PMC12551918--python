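"""Packaged reference matrices and synthetic-fixture generation.

Two published predictor correlation matrices ship with the package as CSV:

* ``bodyfat_correlation``: 13 anthropometric predictors of body-fat
  percentage, n = 50 (chest, abdomen, hip, thigh, knee, ankle, biceps,
  forearm, neck, wrist circumferences, weight, height, density);
* ``livestock_correlation``: 5 livestock-population predictors of hair
  production, n = 18 (buffalos, cattle, goats, sheep, poultry).

Both exhibit severe multicollinearity and drive the diagnostics examples.
``make_fixture`` additionally writes synthetic regression datasets drawn
from the equicorrelated simulation scheme, with the true coefficients
recorded in a JSON sidecar.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ScenarioSpec, equicorrelated_sigma, make_beta

__all__ = [
    "BODYFAT_N",
    "LIVESTOCK_N",
    "load_bodyfat_correlation",
    "load_livestock_correlation",
    "simulate_dataset",
    "make_fixture",
    "FIXTURE_KINDS",
]

#: observation counts behind the packaged correlation matrices
BODYFAT_N = 50
LIVESTOCK_N = 18

FIXTURE_KINDS = ("simulated", "bodyfat_correlation", "livestock_correlation")


def _load_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("ridgepen").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_bodyfat_correlation() -> pd.DataFrame:
    """13 x 13 predictor correlation matrix of the body-fat application."""
    return _load_packaged_csv("bodyfat_correlation.csv")


def load_livestock_correlation() -> pd.DataFrame:
    """5 x 5 predictor correlation matrix of the livestock application."""
    return _load_packaged_csv("livestock_correlation.csv")


def simulate_dataset(
    spec: ScenarioSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw one synthetic dataset from the equicorrelated scheme.

    Returns the dataset (predictors X1..Xp plus response Y) and the true
    unit-norm slope vector (intercept is zero).
    """
    rng = np.random.default_rng(spec.seed)
    S = equicorrelated_sigma(spec.p, spec.rho)
    X = rng.standard_normal((spec.n, spec.p)) @ np.linalg.cholesky(S).T
    beta = make_beta(spec.beta_rule, spec.p, design=X)
    y = X @ beta + spec.sigma * rng.standard_normal(spec.n)
    df = pd.DataFrame(X, columns=[f"X{i + 1}" for i in range(spec.p)])
    df["Y"] = y
    return df, beta


def make_fixture(kind: str, path: str | Path, spec: ScenarioSpec | None = None) -> Path:
    """Write a fixture CSV; returns the path written.

    Kinds: ``simulated`` (a dataset drawn from ``spec``, with the true
    coefficients and seed in a ``<path>.meta.json`` sidecar) and the two
    packaged correlation matrices.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "simulated":
        if spec is None:
            raise ValueError("kind 'simulated' requires a ScenarioSpec")
        df, beta = simulate_dataset(spec)
        df.to_csv(path, index=False)
        meta = {
            "rho": spec.rho,
            "p": spec.p,
            "sigma": spec.sigma,
            "n": spec.n,
            "seed": spec.seed,
            "beta_rule": spec.beta_rule,
            "beta_true": beta.tolist(),
            "intercept_true": 0.0,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        return path
    if kind == "bodyfat_correlation":
        load_bodyfat_correlation().to_csv(path, index=False)
        return path
    if kind == "livestock_correlation":
        load_livestock_correlation().to_csv(path, index=False)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
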