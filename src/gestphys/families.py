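"""Candidate functional forms for gestational growth-curve modelling.

Fourteen families are supported: polynomials up to degree three (with and
without an intercept, the intercept-free variants being "growth" models that
vanish at the start of gestation), Gompertz and logistic sigmoids (plus
"modified" variants carrying an additive baseline), and allometric power laws
(plain, modified, and the two-exponent form ``y = θ0·x^(θ1 + θ2·ln x)`` used
for tissue-mass-on-body-mass scaling, plus its modified variant).

Every family is evaluated from an ordered parameter vector θ and a scalar or
array covariate (gestational age in weeks, or a body mass for the allometric
forms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ModelFamily",
    "ModelSpec",
    "ScreenResult",
    "FAMILIES",
    "get_family",
    "evaluate",
    "feasibility_screen",
]

AGE_WEEKS = "age_weeks"
BODY_MASS = "body_mass"


class DomainError(ValueError):
    """Covariate outside the mathematical domain of a family."""


def _stable_logistic(theta0: float, theta1: float, theta2: float, x: np.ndarray) -> np.ndarray:
    # sign-split sigmoid: never exponentiates a positive argument
    z = theta1 * (x - theta2)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = theta0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = theta0 * ez / (1.0 + ez)
    return out


def _gompertz(theta0: float, theta1: float, theta2: float, x: np.ndarray) -> np.ndarray:
    if theta2 == 0.0:
        raise DomainError("gompertz rate parameter theta2 must be nonzero")
    # -expm1(-θ2 x) = 1 - exp(-θ2 x), accurate for θ2 x near 0
    return theta0 * np.exp(theta1 / theta2 * -np.expm1(-theta2 * x))


def _power(theta0: float, theta1: float, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("power law requires a nonnegative covariate")
    if np.any(x == 0) and theta1 < 0:
        raise DomainError("power law at x=0 with negative exponent")
    with np.errstate(divide="ignore"):
        out = theta0 * np.power(x, theta1)
    # continuity extension: x^θ1 -> 0 as x -> 0+ for θ1 > 0
    if theta1 > 0:
        out = np.where(x == 0, 0.0, out)
    return out


def _luecke(theta0: float, theta1: float, theta2: float, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("allometric form requires a nonnegative covariate")
    if np.any(x == 0):
        # limit of exp(θ1 ln x + θ2 (ln x)^2) as x -> 0+
        if theta2 > 0 or (theta2 == 0 and theta1 < 0):
            raise DomainError("allometric form diverges at x=0 for these exponents")
        limit = theta0 if (theta2 == 0 and theta1 == 0) else 0.0
        out = np.full_like(x, limit, dtype=float)
        nz = x > 0
        lx = np.log(x[nz])
        out[nz] = theta0 * np.exp((theta1 + theta2 * lx) * lx)
        return out
    lx = np.log(x)
    return theta0 * np.exp((theta1 + theta2 * lx) * lx)


@dataclass(frozen=True)
class ModelFamily:
    """One candidate functional form.

    Attributes
    ----------
    family_id : str
        Stable lowercase identifier used in config files, CLI flags and
        fit-result JSON.
    k : int
        Number of free parameters θ0..θ(k-1).
    fn : callable
        ``fn(theta, x) -> ndarray`` evaluating the form.
    is_growth : bool
        True when y(0; θ) = 0 by construction (no baseline term).
    """

    family_id: str
    k: int
    fn: Callable[[Sequence[float], np.ndarray], np.ndarray] = field(repr=False)
    is_growth: bool = False

    def __call__(self, theta: Sequence[float], x) -> np.ndarray:
        theta = tuple(float(v) for v in theta)
        if len(theta) != self.k:
            raise ValueError(
                f"{self.family_id} expects {self.k} parameters, got {len(theta)}"
            )
        arr = np.asarray(x, dtype=float)
        out = self.fn(theta, np.atleast_1d(arr))
        return out.reshape(arr.shape) if arr.ndim else float(out[0])


def _poly(theta: Sequence[float], x: np.ndarray, *, growth: bool) -> np.ndarray:
    coeffs = (0.0, *theta) if growth else theta
    return np.polynomial.polynomial.polyval(x, coeffs)


FAMILIES: dict[str, ModelFamily] = {
    f.family_id: f
    for f in (
        ModelFamily("linear", 2, lambda th, x: _poly(th, x, growth=False)),
        ModelFamily("linear_growth", 1, lambda th, x: _poly(th, x, growth=True), is_growth=True),
        ModelFamily("quadratic", 3, lambda th, x: _poly(th, x, growth=False)),
        ModelFamily("quadratic_growth", 2, lambda th, x: _poly(th, x, growth=True), is_growth=True),
        ModelFamily("cubic", 4, lambda th, x: _poly(th, x, growth=False)),
        ModelFamily("cubic_growth", 3, lambda th, x: _poly(th, x, growth=True), is_growth=True),
        ModelFamily("gompertz", 3, lambda th, x: _gompertz(*th, x)),
        ModelFamily("modified_gompertz", 4, lambda th, x: _gompertz(th[0], th[1], th[2], x) + th[3]),
        ModelFamily("logistic", 3, lambda th, x: _stable_logistic(*th, x)),
        ModelFamily("modified_logistic", 4, lambda th, x: _stable_logistic(th[0], th[1], th[2], x) + th[3]),
        ModelFamily("power_law", 2, lambda th, x: _power(*th, x)),
        ModelFamily("modified_power_law", 3, lambda th, x: _power(th[0], th[1], x) + th[2]),
        ModelFamily("luecke_power_law", 3, lambda th, x: _luecke(*th, x)),
        ModelFamily("modified_luecke_power_law", 4, lambda th, x: _luecke(th[0], th[1], th[2], x) + th[3]),
    )
}


def get_family(family_id: str) -> ModelFamily:
    try:
        return FAMILIES[family_id]
    except KeyError:
        raise KeyError(
            f"unknown family {family_id!r}; choose from {sorted(FAMILIES)}"
        ) from None


@dataclass(frozen=True)
class ModelSpec:
    """A family together with a concrete parameter vector."""

    family: ModelFamily
    theta: tuple[float, ...]
    covariate_kind: str = AGE_WEEKS

    def __post_init__(self):
        object.__setattr__(self, "theta", tuple(float(v) for v in self.theta))
        if len(self.theta) != self.family.k:
            raise ValueError(
                f"{self.family.family_id} expects {self.family.k} parameters, "
                f"got {len(self.theta)}"
            )
        if not all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")

    def __call__(self, x):
        return self.family(self.theta, x)


def make_spec(family_id: str, theta: Iterable[float], covariate_kind: str = AGE_WEEKS) -> ModelSpec:
    return ModelSpec(get_family(family_id), tuple(theta), covariate_kind)


def evaluate(spec: ModelSpec, x):
    """Evaluate ``y(x; θ)`` for a scalar or array covariate."""
    return spec(x)


@dataclass(frozen=True)
class ScreenResult:
    nonnegative: bool
    first_violation: float | None


def feasibility_screen(
    spec: ModelSpec,
    interval: tuple[float, float] = (0.0, 42.0),
    step: float = 0.1,
) -> ScreenResult:
    """Scan an inclusive covariate grid for negative model values.

    Mirrors the plausibility check used in preferred-model selection: a
    candidate is infeasible if it predicts a negative mass, volume, flow or
    percentage anywhere on the domain of applicability.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    grid[-1] = hi
    values = np.asarray(spec(grid), dtype=float)
    neg = values < 0
    if not neg.any():
        return ScreenResult(True, None)
    return ScreenResult(False, float(grid[int(np.argmax(neg))]))
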