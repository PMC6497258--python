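"""Synthetic summary-statistic datasets for exercising the calibration engine.

The generator emulates the structure of curated gestational summary data:
per-age sample means, sample SDs and subject counts.  Two styles are
provided: a multi-subject design (the default mirrors a typical curated
spread — 16 ages from 10 to 40 weeks, 25 subjects per age, 10% coefficient
of variation), and a "digitised" style of single observations with no SD,
as produced by extracting points from published figures, which downstream
imputation restores with a 20% CV and n = 1.

Noise is Gaussian on the natural scale; an optional truncation at zero is
available for early-gestation designs where cv·curve is not small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import SummaryDataset, SummaryPoint
from .families import ModelSpec

__all__ = ["SamplingDesign", "generate_summary_dataset", "generate_digitized_style"]

DEFAULT_AGES = tuple(np.arange(10.0, 40.0 + 1e-9, 2.0))  # 16 ages


@dataclass(frozen=True)
class SamplingDesign:
    """Covariate grid, per-point subject count, noise model and seed.

    Exactly one of ``gaussian_cv`` (SD proportional to the curve) or
    ``gaussian_sd`` (absolute SD) defines the noise scale.
    """

    grid: tuple[float, ...] = DEFAULT_AGES
    n: int = 25
    gaussian_cv: float | None = 0.10
    gaussian_sd: float | None = None
    truncate_at_zero: bool = False
    seed: int = 0

    def __post_init__(self):
        grid = tuple(float(g) for g in self.grid)
        object.__setattr__(self, "grid", grid)
        if len(grid) >= 2 and not all(a < b for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if (self.gaussian_cv is None) == (self.gaussian_sd is None):
            raise ValueError("specify exactly one of gaussian_cv or gaussian_sd")
        scale = self.gaussian_cv if self.gaussian_sd is None else self.gaussian_sd
        if scale < 0:
            raise ValueError("noise scale must be nonnegative")

    def sigma(self, curve: np.ndarray) -> np.ndarray:
        if self.gaussian_sd is not None:
            return np.full_like(curve, float(self.gaussian_sd))
        return self.gaussian_cv * np.abs(curve)


def generate_summary_dataset(spec: ModelSpec, design: SamplingDesign) -> SummaryDataset:
    """Draw per-age subject samples and summarise them.

    At each grid point, ``design.n`` values are drawn from
    Normal(y(x; θ), σ(x)); the record keeps the sample mean, the sample SD
    (ddof=1; omitted when n = 1) and n.  Byte-identical output for identical
    seed, design and spec.
    """
    grid = np.array(design.grid)
    curve = np.asarray(spec(grid), dtype=float)
    sigma = design.sigma(curve)
    rng = np.random.default_rng(design.seed)
    points = []
    for x, mu, s in zip(grid, curve, sigma):
        draws = rng.normal(mu, s, size=design.n) if s > 0 else np.full(design.n, mu)
        if design.truncate_at_zero:
            draws = np.clip(draws, 0.0, None)
        mean = float(np.mean(draws))
        sd = float(np.std(draws, ddof=1)) if design.n > 1 else None
        points.append(SummaryPoint(float(x), mean, sd=sd, n=design.n))
    return SummaryDataset(
        tuple(points),
        covariate_kind=spec.covariate_kind,
        label=spec.family.family_id,
    )


def generate_digitized_style(
    spec: ModelSpec,
    ages,
    cv: float = 0.2,
    seed: int = 0,
) -> SummaryDataset:
    """Emulate figure-extracted data: one noisy observation per age, with SD
    and sample size left missing (to be imputed downstream)."""
    grid = np.asarray(ages, dtype=float)
    curve = np.asarray(spec(grid), dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.normal(curve, cv * np.abs(curve))
    points = [
        SummaryPoint(float(x), float(v), sd=None, n=None)
        for x, v in zip(grid, draws)
    ]
    return SummaryDataset(
        tuple(points),
        covariate_kind=spec.covariate_kind,
        label=spec.family.family_id,
    )
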