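"""Data-generating process: latent normals, Likertization, and the nine
generating formulas.

Latent predictors x1..xk are i.i.d. N(3, 1).  The observed Likert scores
X1..Xk are the latent values rounded *up* to the next integer and clipped
to the 1..5 range — the only measurement error in the predictors.  The
continuous outcome Y is always computed from the latent values: a linear
part, a complexity-dependent nonlinear part (two-way interactions,
quadratics, and for the high-complexity cells one extra term), and
additive standard-normal noise scaled by the condition's error
multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditions import (
    COEFFICIENT_RANGES,
    Complexity,
    ConditionSpec,
    ConfigurationError,
    condition_index,
)

# ---------------------------------------------------------------------------
# formula registry
# ---------------------------------------------------------------------------
# A term is a tuple: ("main", j), ("prod", j, k), ("square", j) or ("exp", j)
# with 1-based variable indices.  Each nonlinear term carries the 0-based
# index of the nonlinear coefficient that multiplies it; the high-complexity
# 5-IV formula reuses its first nonlinear coefficient for both interaction
# terms, so terms can share a coefficient.

Term = tuple


@dataclass(frozen=True)
class Formula:
    """Right-hand side of one generating equation (noise excluded)."""

    linear_vars: tuple[int, ...]                  # 1-based, coefficient cof_j
    nonlinear_terms: tuple[tuple[Term, int], ...]  # (term, conf index)

    @property
    def n_cof(self) -> int:
        return len(self.linear_vars)

    @property
    def n_conf(self) -> int:
        return 1 + max(ci for _, ci in self.nonlinear_terms)

    def terms(self) -> list[Term]:
        """All distinct regressor terms, mains first, in formula order."""
        out: list[Term] = [("main", j) for j in self.linear_vars]
        for term, _ in self.nonlinear_terms:
            if term not in out:
                out.append(term)
        return out


FORMULAS: dict[tuple[Complexity, int], Formula] = {
    (Complexity.SIMPLE, 3): Formula(
        (1, 2, 3),
        ((("prod", 1, 2), 0), (("prod", 2, 3), 1)),
    ),
    (Complexity.MEDIUM, 3): Formula(
        (1, 2, 3),
        ((("prod", 1, 2), 0), (("prod", 2, 3), 1), (("square", 1), 2), (("square", 2), 3)),
    ),
    (Complexity.HIGH, 3): Formula(
        (1, 2, 3),
        (
            (("prod", 1, 2), 0),
            (("prod", 2, 3), 1),
            (("square", 1), 2),
            (("square", 2), 3),
            (("exp", 1), 4),
        ),
    ),
    (Complexity.SIMPLE, 5): Formula(
        (1, 2, 3),
        ((("prod", 1, 2), 0), (("prod", 4, 5), 1)),
    ),
    (Complexity.MEDIUM, 5): Formula(
        (1, 2, 3),
        ((("prod", 1, 2), 0), (("prod", 4, 5), 1), (("square", 1), 2), (("square", 5), 3)),
    ),
    # the published high-complexity 5-IV equation reuses conf1 for both
    # interactions, so it has five nonlinear terms but four coefficients
    (Complexity.HIGH, 5): Formula(
        (1, 2, 3),
        (
            (("prod", 1, 2), 0),
            (("prod", 4, 5), 0),
            (("square", 1), 1),
            (("square", 5), 2),
            (("exp", 4), 3),
        ),
    ),
    (Complexity.SIMPLE, 10): Formula(
        (1, 2, 3, 4, 5, 6),
        ((("prod", 7, 8), 0), (("prod", 9, 10), 1)),
    ),
    (Complexity.MEDIUM, 10): Formula(
        (1, 2, 3, 4, 5, 6),
        ((("prod", 7, 8), 0), (("prod", 9, 10), 1), (("square", 5), 2), (("square", 10), 3)),
    ),
    # the final term of the high-complexity 10-IV equation is the plain
    # main effect conf5*x9, implemented literally as published
    (Complexity.HIGH, 10): Formula(
        (1, 2, 3, 4, 5, 6),
        (
            (("prod", 7, 8), 0),
            (("prod", 9, 10), 1),
            (("square", 5), 2),
            (("square", 10), 3),
            (("main", 9), 4),
        ),
    ),
}


def formula_for(condition: ConditionSpec) -> Formula:
    return FORMULAS[(condition.complexity, condition.n_iv)]


def term_values(matrix: np.ndarray, term: Term) -> np.ndarray:
    """Evaluate one term column-wise on an n x k matrix (latent or Likert)."""
    kind = term[0]
    if kind == "main":
        return matrix[:, term[1] - 1]
    if kind == "prod":
        out = matrix[:, term[1] - 1].copy()
        for j in term[2:]:
            out = out * matrix[:, j - 1]
        return out
    if kind == "square":
        return matrix[:, term[1] - 1] ** 2
    if kind == "exp":
        return np.exp(matrix[:, term[1] - 1])
    raise ConfigurationError(f"unknown term kind {kind!r}")


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoefficientSet:
    """Drawn linear (cof) and nonlinear (conf) coefficients plus the noise
    multiplier (coferr) for one condition."""

    cof: tuple[float, ...]
    conf: tuple[float, ...]
    coferr: float

    def validate(self, condition: ConditionSpec) -> None:
        f = formula_for(condition)
        if len(self.cof) != f.n_cof or len(self.conf) != f.n_conf:
            raise ConfigurationError(
                f"coefficient lengths (cof={len(self.cof)}, conf={len(self.conf)}) "
                f"do not match formula (needs {f.n_cof}, {f.n_conf})"
            )


_COEF_DOMAIN = 17  # namespaces the coefficient stream within a master seed


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    if seed < 0:
        raise ConfigurationError("seed must be a non-negative integer")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


def draw_coefficients(condition: ConditionSpec, seed: int) -> CoefficientSet:
    """Draw a coefficient set for one condition.

    Linear coefficients are i.i.d. uniform over the condition's linear
    range, nonlinear coefficients over its nonlinear range; the noise
    multiplier is fixed by the condition.  The stream is namespaced by
    the condition id, so one master seed yields independent draws per
    cell and the same (condition, seed) pair always reproduces the same
    set.
    """
    f = formula_for(condition)
    rng = _rng(seed, _COEF_DOMAIN, condition_index(condition))
    lo, hi = COEFFICIENT_RANGES[condition.linear_level]
    cof = tuple(rng.uniform(lo, hi, size=f.n_cof))
    lo, hi = COEFFICIENT_RANGES[condition.nonlinear_level]
    conf = tuple(rng.uniform(lo, hi, size=f.n_conf))
    return CoefficientSet(cof=cof, conf=conf, coferr=float(condition.error_coef))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_latent(n: int, n_iv: int, seed: int) -> np.ndarray:
    """Draw an n x n_iv matrix of i.i.d. N(3, 1) latent predictors."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if n_iv not in (3, 5, 10):
        raise ConfigurationError(f"n_iv must be 3, 5 or 10, got {n_iv}")
    return _rng(seed).normal(loc=3.0, scale=1.0, size=(n, n_iv))


def likertize(latent: np.ndarray, method: str = "ceil") -> np.ndarray:
    """Discretize latent scores to the 1..5 Likert range.

    The default rounds *up* to the next integer before clipping.
    ``method="round"`` (nearest integer) is offered for sensitivity
    analysis only; it shifts the cell probabilities and hence every
    attenuation-dependent quantity downstream.
    """
    if method == "ceil":
        coded = np.ceil(latent)
    elif method == "round":
        coded = np.round(latent)
    else:
        raise ConfigurationError(f"unknown likertization method {method!r}")
    return np.clip(coded, 1, 5).astype(np.int64)


def evaluate_outcome(
    latent: np.ndarray,
    condition: ConditionSpec,
    coefs: CoefficientSet,
    noise_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate the generating formula on latent values and add noise.

    Noise is coferr-scaled standard normal; pass ``noise_seed`` (or an
    explicit generator) to make it reproducible.  With ``coferr == 0``
    the result is the deterministic signal.
    """
    coefs.validate(condition)
    f = formula_for(condition)
    y = np.zeros(latent.shape[0])
    for c, j in zip(coefs.cof, f.linear_vars):
        y += c * latent[:, j - 1]
    for term, ci in f.nonlinear_terms:
        y += coefs.conf[ci] * term_values(latent, term)
    if coefs.coferr != 0:
        if rng is None:
            rng = _rng(noise_seed if noise_seed is not None else 0)
        y = y + coefs.coferr * rng.standard_normal(latent.shape[0])
    return y


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated dataset: observed Likert predictors X, continuous
    outcome Y, and the latent predictors retained for oracle use."""

    X: np.ndarray
    Y: np.ndarray
    latent: np.ndarray
    condition: ConditionSpec
    coefficients: CoefficientSet
    seed: int = field(default=0)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def generate_dataset(
    condition: ConditionSpec, n: int, coefs: CoefficientSet, seed: int
) -> SimulatedDataset:
    """Simulate latent predictors, Likertize them, and compute the outcome.

    Latent and noise streams use sub-seeds derived deterministically from
    ``seed``, so the whole dataset is reproducible from
    (condition, n, coefs, seed).
    """
    root = np.random.SeedSequence(entropy=seed)
    latent_rng, noise_rng = (np.random.default_rng(s) for s in root.spawn(2))
    latent = latent_rng.normal(3.0, 1.0, size=(n, condition.n_iv))
    y = evaluate_outcome(latent, condition, coefs, rng=noise_rng)
    return SimulatedDataset(
        X=likertize(latent), Y=y, latent=latent,
        condition=condition, coefficients=coefs, seed=seed,
    )


def dataset_to_frame(dataset: SimulatedDataset):
    """Export a dataset as a DataFrame with integer X1..Xk and float Y."""
    import pandas as pd

    k = dataset.X.shape[1]
    df = pd.DataFrame(dataset.X, columns=[f"X{j}" for j in range(1, k + 1)])
    df["Y"] = dataset.Y
    return df
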