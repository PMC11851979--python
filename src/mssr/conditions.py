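"""The 108-cell simulation design grid.

Each cell crosses the complexity of the nonlinear predictor-outcome
relationship (simple / medium / high), the number of Likert independent
variables (3, 5, 10), the magnitude class of the linear and nonlinear
coefficients (small: U[0.1, 0.3]; large: U[0.5, 1]), and the noise
multiplier (1, 4, 10).  Condition ids 1..108 follow the canonical row
order of the published results table: complexity cycles fastest, then
the nonlinear coefficient level, then the linear level, then the noise
level, and the number of IVs slowest.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator


class Complexity(IntEnum):
    """Complexity of the nonlinear part of the generating formula."""

    SIMPLE = 1   # two-way interactions only
    MEDIUM = 2   # interactions + quadratics
    HIGH = 3     # interactions + quadratics + one extra nonlinear term


#: coefficient magnitude classes -> uniform sampling ranges
COEFFICIENT_RANGES: dict[str, tuple[float, float]] = {
    "small": (0.1, 0.3),
    "large": (0.5, 1.0),
}

ERROR_LEVELS: tuple[float, ...] = (1.0, 4.0, 10.0)
IV_COUNTS: tuple[int, ...] = (3, 5, 10)
COEF_LEVELS: tuple[str, str] = ("small", "large")


class ConfigurationError(ValueError):
    """Raised when a condition or configuration value is outside the design."""


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design.

    Parameters
    ----------
    complexity
        Nonlinear complexity level (1=simple, 2=medium, 3=high).
    n_iv
        Number of Likert independent variables (3, 5 or 10).
    linear_level, nonlinear_level
        Magnitude class of the linear / nonlinear coefficients,
        ``"small"`` (U[0.1, 0.3]) or ``"large"`` (U[0.5, 1]).
    error_coef
        Multiplier of the standard-normal noise term (1, 4 or 10).
    """

    complexity: Complexity
    n_iv: int
    linear_level: str
    nonlinear_level: str
    error_coef: float

    def __post_init__(self) -> None:
        if self.n_iv not in IV_COUNTS:
            raise ConfigurationError(f"n_iv must be one of {IV_COUNTS}, got {self.n_iv}")
        for name in ("linear_level", "nonlinear_level"):
            if getattr(self, name) not in COEFFICIENT_RANGES:
                raise ConfigurationError(f"{name} must be 'small' or 'large'")
        if float(self.error_coef) not in ERROR_LEVELS:
            raise ConfigurationError(f"error_coef must be one of {ERROR_LEVELS}")
        object.__setattr__(self, "complexity", Complexity(self.complexity))

    @property
    def condition_id(self) -> int:
        return condition_index(self)


def condition_index(spec: ConditionSpec) -> int:
    """Map a condition to its 1-based id under the canonical row order."""
    c = int(spec.complexity) - 1
    nl = COEF_LEVELS.index(spec.nonlinear_level)
    lin = COEF_LEVELS.index(spec.linear_level)
    err = ERROR_LEVELS.index(float(spec.error_coef))
    iv = IV_COUNTS.index(spec.n_iv)
    return 1 + c + 3 * nl + 6 * lin + 12 * err + 36 * iv


def condition_from_index(index: int) -> ConditionSpec:
    """Inverse of :func:`condition_index` for ids 1..108."""
    if not 1 <= index <= 108:
        raise ConfigurationError(f"condition index must be in 1..108, got {index}")
    i = index - 1
    return ConditionSpec(
        complexity=Complexity(i % 3 + 1),
        nonlinear_level=COEF_LEVELS[(i // 3) % 2],
        linear_level=COEF_LEVELS[(i // 6) % 2],
        error_coef=ERROR_LEVELS[(i // 12) % 3],
        n_iv=IV_COUNTS[i // 36],
    )


def all_conditions() -> Iterator[ConditionSpec]:
    """Yield the full grid in canonical order (ids 1..108)."""
    for index in range(1, 109):
        yield condition_from_index(index)
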