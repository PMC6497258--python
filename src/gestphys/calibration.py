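"""Maximum-likelihood calibration and AIC model selection for summary data.

The calibration input is summary-statistic data: ordered records of
(covariate, sample mean, sample SD, sample size).  Records missing an SD or a
sample size — typical of observations digitised from published figures — are
imputed with a 20% coefficient of variation and n = 1.

Each record is treated as n i.i.d. Gaussian observations with sample mean m
and sample SD s, under a model mean y(x; θ) and known variance s²; summing
the per-record sufficient-statistic contributions gives

    ℓ(θ) = Σᵢ [ −(nᵢ/2)·log(2π sᵢ²) − ((nᵢ−1)sᵢ² + nᵢ(mᵢ − y(xᵢ; θ))²) / (2 sᵢ²) ]

so the MLE coincides with weighted least squares (weights nᵢ/sᵢ²) and the
log-likelihood magnitude scales with the total number of subjects.  Model
parsimony is scored by AIC = 2k − 2ℓ(θ̂), and the preferred model is the
lowest-AIC candidate that stays nonnegative over the domain of applicability
(a negative predicted mass, volume or flow disqualifies a candidate even if
it wins on AIC).

The engine is exposed both as plain functions (``fit_mle``, ``select_model``)
and as a scikit-learn compatible estimator (:class:`GrowthCurveMLE`) so fits
can participate in sklearn pipelines and model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from . import fetal
from .families import (
    AGE_WEEKS,
    BODY_MASS,
    FAMILIES,
    DomainError,
    ModelFamily,
    ModelSpec,
    ScreenResult,
    get_family,
)

__all__ = [
    "SummaryPoint",
    "SummaryDataset",
    "FitResult",
    "SelectionReport",
    "DegenerateVarianceError",
    "NoFeasibleModelError",
    "impute_summary",
    "log_likelihood",
    "fit_mle",
    "aic",
    "select_model",
    "GrowthCurveMLE",
    "PreferredModelSelector",
]

IMPUTED_CV = 0.2
IMPUTED_N = 1


class DegenerateVarianceError(ValueError):
    """A summary point with zero variance cannot enter a Gaussian likelihood."""


class NoFeasibleModelError(RuntimeError):
    """Every candidate model was screened out for producing negative values."""


@dataclass(frozen=True)
class SummaryPoint:
    covariate: float
    mean: float
    sd: float | None = None
    n: int | None = None
    imputed_sd: bool = False
    imputed_n: bool = False

    def __post_init__(self):
        if not math.isfinite(self.covariate) or not math.isfinite(self.mean):
            raise ValueError("covariate and mean must be finite")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass(frozen=True)
class SummaryDataset:
    """Ordered summary records plus covariate/quantity metadata."""

    points: tuple[SummaryPoint, ...]
    covariate_kind: str = AGE_WEEKS
    label: str = ""
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))

    def __len__(self):
        return len(self.points)

    @property
    def covariate(self) -> np.ndarray:
        return np.array([p.covariate for p in self.points])

    @property
    def mean(self) -> np.ndarray:
        return np.array([p.mean for p in self.points])

    @property
    def sd(self) -> np.ndarray:
        return np.array([np.nan if p.sd is None else p.sd for p in self.points])

    @property
    def n(self) -> np.ndarray:
        return np.array([0 if p.n is None else p.n for p in self.points])

    @property
    def is_imputed(self) -> bool:
        return all(p.sd is not None and p.n is not None for p in self.points)


def impute_summary(dataset: SummaryDataset) -> SummaryDataset:
    """Fill missing SDs (20% CV) and sample sizes (n = 1); flag what was filled.

    A record with mean 0 and no SD would get zero variance, which is rejected
    rather than silently degenerating the likelihood.
    """
    points = []
    for p in dataset.points:
        sd, n = p.sd, p.n
        imputed_sd, imputed_n = p.imputed_sd, p.imputed_n
        if sd is None:
            if p.mean == 0:
                raise DegenerateVarianceError(
                    f"cannot impute sd for zero mean at covariate {p.covariate}"
                )
            sd = IMPUTED_CV * abs(p.mean)
            imputed_sd = True
        if n is None:
            n = IMPUTED_N
            imputed_n = True
        points.append(
            SummaryPoint(p.covariate, p.mean, sd, n, imputed_sd, imputed_n)
        )
    return replace(dataset, points=tuple(points))


def log_likelihood(spec: ModelSpec, dataset: SummaryDataset) -> float:
    """Summary-data Gaussian log-likelihood ℓ(θ; D) (see module docstring)."""
    if not dataset.is_imputed:
        raise ValueError("dataset has missing sd/n; run impute_summary first")
    s = dataset.sd
    if np.any(s <= 0):
        raise DegenerateVarianceError("all summary points need sd > 0")
    n = dataset.n.astype(float)
    m = dataset.mean
    y = np.asarray(spec(dataset.covariate), dtype=float)
    var = s**2
    terms = -(n / 2.0) * np.log(2.0 * np.pi * var) - (
        (n - 1.0) * var + n * (m - y) ** 2
    ) / (2.0 * var)
    return float(np.sum(terms))


def aic(k: int, loglik: float) -> float:
    """Akaike information criterion, 2k − 2ℓ."""
    return 2.0 * k - 2.0 * loglik


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    loglik: float
    k: int
    aic: float
    converged: bool
    n_starts: int
    seed: int

    def __post_init__(self):
        if self.aic != 2.0 * self.k - 2.0 * self.loglik:
            raise ValueError("AIC identity 2k - 2*loglik violated")

    @property
    def family_id(self) -> str:
        return self.spec.family.family_id

    def to_dict(self) -> dict:
        return {
            "family": self.family_id,
            "theta": list(self.spec.theta),
            "covariate_kind": self.spec.covariate_kind,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# initial guesses

def _wls_polynomial(x, m, w, degree, growth):
    powers = range(1, degree + 1) if growth else range(0, degree + 1)
    design = np.stack([x**p for p in powers], axis=1)
    sw = np.sqrt(w)
    theta, *_ = np.linalg.lstsq(design * sw[:, None], m * sw, rcond=None)
    return theta


def _initial_theta(family: ModelFamily, x, m, w) -> np.ndarray:
    fid = family.family_id
    span = max(x.max() - x.min(), 1e-6)
    top = float(m.max())
    bottom = float(m.min())
    pos_floor = max(1e-6 * max(abs(top), 1.0), 1e-12)

    if fid in ("linear", "quadratic", "cubic"):
        return _wls_polynomial(x, m, w, {"linear": 1, "quadratic": 2, "cubic": 3}[fid], False)
    if fid in ("linear_growth", "quadratic_growth", "cubic_growth"):
        deg = {"linear_growth": 1, "quadratic_growth": 2, "cubic_growth": 3}[fid]
        return _wls_polynomial(x, m, w, deg, True)

    if fid in ("gompertz", "modified_gompertz"):
        offset = bottom if fid == "modified_gompertz" else 0.0
        base = m - offset
        theta0 = max(float(base[np.argmin(x)]), pos_floor)
        theta2 = 2.0 / span
        amax = max(float(base.max()), theta0 * 1.5)
        theta1 = theta2 * np.log(amax / theta0)
        init = [theta0, theta1, theta2]
        return np.array(init + [offset]) if fid == "modified_gompertz" else np.array(init)

    if fid in ("logistic", "modified_logistic"):
        offset = bottom if fid == "modified_logistic" else 0.0
        base = m - offset
        theta0 = max(float(base.max()), pos_floor)
        theta2 = float(x[np.argmin(np.abs(base - theta0 / 2.0))])
        theta1 = 4.0 / span
        init = [theta0, theta1, theta2]
        return np.array(init + [offset]) if fid == "modified_logistic" else np.array(init)

    # allometric forms: fit in log space on the strictly positive points
    offset = 0.0
    base = m.copy()
    if fid.startswith("modified"):
        offset = bottom - 0.05 * abs(bottom) - pos_floor
        base = m - offset
    ok = (x > 0) & (base > 0)
    if ok.sum() >= 2:
        lx, ly = np.log(x[ok]), np.log(base[ok])
        quadratic = "luecke" in fid
        design = np.stack([np.ones_like(lx), lx] + ([lx**2] if quadratic else []), axis=1)
        coef, *_ = np.linalg.lstsq(design, ly, rcond=None)
        init = [float(np.exp(coef[0])), float(coef[1])]
        if quadratic:
            init.append(float(coef[2]))
    else:
        init = [max(top, pos_floor), 0.75] + ([0.0] if "luecke" in fid else [])
    if fid.startswith("modified"):
        init.append(offset)
    return np.array(init)


def _neg_loglik_factory(family: ModelFamily, dataset: SummaryDataset):
    def neg(theta):
        if not np.all(np.isfinite(theta)):
            return np.inf
        try:
            # wild exploratory starts may overflow a sigmoid; that simply
            # makes the candidate infinitely bad
            with np.errstate(over="ignore", invalid="ignore"):
                ll = log_likelihood(
                    ModelSpec(family, tuple(theta), dataset.covariate_kind), dataset
                )
        except (DomainError, FloatingPointError, ValueError, OverflowError):
            return np.inf
        if not np.isfinite(ll):
            return np.inf
        return -ll

    return neg


def fit_mle(
    family,
    dataset: SummaryDataset,
    seed: int = 0,
    n_starts: int = 20,
) -> FitResult:
    """Maximum-likelihood fit of one family by multi-start local optimisation.

    Starts are the family-specific heuristic initialisation plus seeded
    multiplicative/additive jitters of it; each start is run through
    Nelder-Mead and polished with L-BFGS-B.  Deterministic given ``seed``.
    Non-convergence is reported through ``converged=False``, never silently.
    """
    if isinstance(family, str):
        family = get_family(family)
    dataset = impute_summary(dataset)
    if len(dataset) <= family.k:
        raise ValueError(
            f"need more than {family.k} points to fit {family.family_id}, "
            f"got {len(dataset)}"
        )
    x, m = dataset.covariate, dataset.mean
    w = dataset.n / dataset.sd**2
    init = np.asarray(_initial_theta(family, x, m, w), dtype=float)
    neg = _neg_loglik_factory(family, dataset)

    rng = np.random.default_rng(seed)
    scale = np.where(np.abs(init) > 1e-8, np.abs(init), 1.0)
    starts = [init]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(init + scale * rng.normal(0.0, 0.3, size=init.shape))

    best_theta, best_obj, best_ok = init, np.inf, False
    for start in starts:
        try:
            res = optimize.minimize(
                neg, start, method="Nelder-Mead",
                options={"maxiter": 2000 * family.k, "xatol": 1e-10, "fatol": 1e-12},
            )
            polish = optimize.minimize(neg, res.x, method="L-BFGS-B")
            cand = polish if polish.fun <= res.fun else res
            ok = bool(res.success or polish.success)
        except Exception:
            continue
        if np.isfinite(cand.fun) and cand.fun < best_obj:
            best_theta, best_obj, best_ok = cand.x, float(cand.fun), ok

    converged = bool(best_ok and np.isfinite(best_obj) and np.all(np.isfinite(best_theta)))
    loglik = -best_obj if np.isfinite(best_obj) else -np.inf
    spec = ModelSpec(family, tuple(best_theta), dataset.covariate_kind)
    return FitResult(
        spec=spec,
        loglik=loglik,
        k=family.k,
        aic=aic(family.k, loglik),
        converged=converged,
        n_starts=n_starts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# selection

@dataclass(frozen=True)
class SelectionReport:
    ranked: tuple[FitResult, ...]
    screened_out: dict = field(default_factory=dict)
    preferred: str = ""
    rationale: str = ""

    @property
    def preferred_fit(self) -> FitResult:
        for f in self.ranked:
            if f.family_id == self.preferred:
                return f
        raise LookupError(self.preferred)


def _screen_fit(fit: FitResult, interval, step) -> ScreenResult:
    """Nonnegativity screen over a gestational-age grid.

    Body-mass-covariate models are screened through the composed
    age → fetal mass → quantity map, so all candidates face the same
    age window.
    """
    lo, hi = float(interval[0]), float(interval[1])
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    grid[-1] = hi
    x = fetal.fetal_mass(grid) if fit.spec.covariate_kind == BODY_MASS else grid
    try:
        values = np.asarray(fit.spec(x), dtype=float)
    except DomainError:
        return ScreenResult(False, float(grid[0]))
    neg = ~(values >= 0)  # NaN counts as a violation
    if not neg.any():
        return ScreenResult(True, None)
    return ScreenResult(False, float(grid[int(np.argmax(neg))]))


def select_model(
    fits,
    screen_interval=(0.0, 42.0),
    step: float = 0.1,
    tie_delta: float = 0.1,
) -> SelectionReport:
    """Rank converged fits by AIC and pick the preferred (feasible) model.

    The preferred model is the lowest-AIC fit whose predictions stay
    nonnegative on the screen interval.  Among feasible fits within
    ``tie_delta`` AIC of the best, ties break toward fewer parameters, then
    toward an age-based covariate (which avoids an intermediate body-mass
    model at evaluation time).
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("need at least one converged fit")
    ranked = tuple(sorted(fits, key=lambda f: f.aic))
    screened_out = {}
    feasible = []
    for f in ranked:
        result = _screen_fit(f, screen_interval, step)
        if result.nonnegative:
            feasible.append(f)
        else:
            screened_out[f.family_id] = result.first_violation
    if not feasible:
        raise NoFeasibleModelError(
            "all candidate models produce negative values on the screen interval"
        )
    best_aic = feasible[0].aic
    tied = [f for f in feasible if f.aic - best_aic < tie_delta]
    winner = min(
        tied, key=lambda f: (f.k, f.spec.covariate_kind != AGE_WEEKS, f.aic)
    )
    if winner.family_id != ranked[0].family_id:
        rationale = "tiebreak" if len(tied) > 1 and winner is not feasible[0] else "lowest_nonneg_aic"
    else:
        rationale = "lowest_aic"
    return SelectionReport(
        ranked=ranked,
        screened_out=screened_out,
        preferred=winner.family_id,
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# sklearn-compatible surface

class GrowthCurveMLE(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the multi-start summary-data MLE.

    Parameters
    ----------
    family : str, default "gompertz"
        Family identifier (see :data:`gestphys.families.FAMILIES`).
    n_starts : int, default 20
        Number of optimisation starts (first is the heuristic init).
    random_state : int, default 0
        Seed for the start jitter; fits are deterministic given it.
    covariate_kind : str, default "age_weeks"

    Attributes (after fit)
    ----------------------
    theta_ : ndarray, MLE parameter vector
    loglik_, k_, aic_, converged_ : fit diagnostics
    result_ : FitResult
    """

    def __init__(self, family: str = "gompertz", n_starts: int = 20,
                 random_state: int = 0, covariate_kind: str = AGE_WEEKS):
        self.family = family
        self.n_starts = n_starts
        self.random_state = random_state
        self.covariate_kind = covariate_kind

    def _as_dataset(self, X, y, sd, n) -> SummaryDataset:
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must align")
        sd_arr = np.broadcast_to(
            np.asarray(np.nan if sd is None else sd, dtype=float), x.shape
        )
        n_arr = np.broadcast_to(np.asarray(0 if n is None else n), x.shape)
        points = [
            SummaryPoint(
                xi, yi,
                sd=None if np.isnan(si) else float(si),
                n=None if int(ni) < 1 else int(ni),
            )
            for xi, yi, si, ni in zip(x, y, sd_arr, n_arr)
        ]
        return SummaryDataset(tuple(points), covariate_kind=self.covariate_kind)

    def fit(self, X, y, sd=None, n=None):
        """Fit to covariates X and sample means y.

        ``sd``/``n`` may be scalars, arrays, or None (None triggers the 20%
        CV and n = 1 imputation).
        """
        dataset = self._as_dataset(X, y, sd, n)
        self.result_ = fit_mle(
            self.family, dataset, seed=int(self.random_state or 0),
            n_starts=self.n_starts,
        )
        self.spec_ = self.result_.spec
        self.theta_ = np.array(self.result_.spec.theta)
        self.loglik_ = self.result_.loglik
        self.k_ = self.result_.k
        self.aic_ = self.result_.aic
        self.converged_ = self.result_.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(self.spec_(x), dtype=float)


class PreferredModelSelector(BaseEstimator):
    """Fit several families and select the preferred one by screened AIC."""

    def __init__(self, families=None, n_starts: int = 20, random_state: int = 0,
                 covariate_kind: str = AGE_WEEKS,
                 screen_interval=(0.0, 42.0), screen_step: float = 0.1,
                 tie_delta: float = 0.1):
        self.families = families
        self.n_starts = n_starts
        self.random_state = random_state
        self.covariate_kind = covariate_kind
        self.screen_interval = screen_interval
        self.screen_step = screen_step
        self.tie_delta = tie_delta

    def fit(self, X, y, sd=None, n=None):
        family_ids = list(self.families) if self.families else sorted(FAMILIES)
        proto = GrowthCurveMLE(covariate_kind=self.covariate_kind)
        dataset = proto._as_dataset(X, y, sd, n)
        fits = []
        for fid in family_ids:
            if len(dataset) <= FAMILIES[fid].k:
                continue
            fits.append(
                fit_mle(fid, dataset, seed=int(self.random_state or 0),
                        n_starts=self.n_starts)
            )
        self.report_ = select_model(
            fits, self.screen_interval, self.screen_step, self.tie_delta
        )
        self.preferred_ = self.report_.preferred
        self.spec_ = self.report_.preferred_fit.spec
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(self.spec_(x), dtype=float)
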