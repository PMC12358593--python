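"""Nonlinear least-squares fitting and R²/RSS model selection.

Each candidate model is fitted to one dataset by minimising the ordinary
(unweighted) residual sum of squares

    RSS = sum_i (y_i - yhat_i)^2,        R^2 = 1 - RSS / TSS,

with TSS the total sum of squares about the mean.  The GAB and Peleg
objectives are multimodal, so every fit is a seeded multi-start: a
model-specific deterministic grid of initial guesses (data-scaled) is
extended with seeded random perturbations, each start is polished with a
bounded trust-region-reflective solver, and the best converged objective
is kept.  Model selection ranks candidates by R² (rounded to 4 decimals),
breaking ties by lower RSS, then by fewer free parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    ValidationError,
)
from .isotherms import ISOTHERM_MODELS
from .kinetics import KINETIC_MODELS, KineticSeries

__all__ = [
    "SorptionDataset",
    "FitResult",
    "goodness_of_fit",
    "fit_model",
    "fit_all_models",
    "select_best",
]


@dataclass(frozen=True)
class SorptionDataset:
    """One temperature's equilibrium sorption points.

    ``points`` are (water activity fraction, EMC %) pairs; they are sorted
    by aw on construction and must be unique with 0 <= aw < 1.
    ``initial_aw`` records the material's water activity before
    equilibration (metadata only).
    """

    temperature_k: float
    points: tuple[tuple[float, float], ...]
    initial_aw: float | None = None
    label: str = ""

    def __post_init__(self):
        pts = sorted((float(a), float(e)) for a, e in self.points)
        if len(pts) < 2:
            raise ValidationError("a sorption dataset needs at least 2 points")
        aws = [a for a, _ in pts]
        if any(not 0.0 <= a < 1.0 for a in aws):
            raise ValidationError("water activities must lie in [0, 1)")
        if len(set(aws)) != len(aws):
            raise ValidationError("water activities must be unique")
        if self.temperature_k <= 0:
            raise ValidationError("temperature must be positive (K)")
        object.__setattr__(self, "points", tuple(pts))

    @property
    def aw(self) -> np.ndarray:
        return np.array([a for a, _ in self.points])

    @property
    def emc(self) -> np.ndarray:
        return np.array([e for _, e in self.points])


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit: estimates, goodness of fit, diagnostics.

    ``param_se`` are asymptotic standard errors from the Jacobian at the
    optimum (sqrt of diag of (J'J)^-1 * RSS/(n-p)); ``seed_trace`` records
    the seed, start count and winning start for reproducibility.
    """

    model_name: str
    params: Mapping[str, float]
    r2: float
    rss: float
    n_points: int
    converged: bool
    param_se: Mapping[str, float] | None = None
    seed_trace: str = ""

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        if self.param_se is not None:
            object.__setattr__(self, "param_se", dict(self.param_se))
        if self.rss < 0:
            raise ValidationError("RSS cannot be negative")
        if self.r2 > 1 + 1e-12:
            raise ValidationError("R^2 cannot exceed 1")

    @property
    def n_free_params(self) -> int:
        return len(self.params)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "params": dict(self.params),
            "r2": self.r2,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "param_se": dict(self.param_se) if self.param_se is not None else None,
            "seed_trace": self.seed_trace,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(**d)


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """(R², RSS) of predictions against observations.

    R² = 1 - RSS/TSS with TSS about the observed mean; raises
    :class:`DegenerateDataError` when the observations carry no variance.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValidationError("observed and predicted must be equal-length vectors")
    if o.size < 2:
        raise ValidationError("need at least 2 points")
    rss = float(np.sum((o - p) ** 2))
    tss = float(np.sum((o - o.mean()) ** 2))
    if tss == 0.0:
        raise DegenerateDataError("observations are all identical (zero TSS)")
    return 1.0 - rss / tss, rss


# ---------------------------------------------------------------------------
# initial-guess grids
# ---------------------------------------------------------------------------

def _smith_start(x, y):
    # linear in (a, b): exact OLS start
    z = np.log1p(-x)
    A = np.vstack([np.ones_like(z), z]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return [coef]


def _gab_starts(x, y):
    ymax = max(float(np.max(np.abs(y))), 1e-6)
    return [
        np.array([k, c, x0])
        for k in (0.5, 0.7, 0.9)
        for c in (1.0, 10.0, 50.0)
        for x0 in (0.5 * ymax, ymax, 5.0 * ymax)
    ]


def _peleg_starts(x, y):
    ymax = max(float(np.max(np.abs(y))), 1e-6)
    return [
        np.array([a, b, c, d])
        for a in (0.5 * ymax, ymax)
        for b in (0.5, 1.0, 3.0)
        for c in (0.5 * ymax, ymax)
        for d in (3.0, 8.0)
    ]


def _log_linearised_start(x, y, kind):
    # Halsey: ln y = (ln a - ln(-ln x))/b ; Henderson: ln(-ln(1-x)) = ln a + b ln y
    pos = y > 0
    if pos.sum() >= 2:
        try:
            if kind == "Halsey":
                u = np.log(-np.log(x[pos]))
                v = np.log(y[pos])
                slope, intercept = np.polyfit(u, v, 1)
                b = -1.0 / slope if slope != 0 else 1.0
                a = math.exp(intercept * b) if abs(intercept * b) < 50 else 1.0
            else:
                u = np.log(y[pos])
                v = np.log(-np.log1p(-x[pos]))
                slope, intercept = np.polyfit(u, v, 1)
                b = slope
                a = math.exp(intercept) if abs(intercept) < 50 else 1.0
            if a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b):
                return [np.array([a, b])]
        except (ValueError, FloatingPointError):
            pass
    return []


def _halsey_starts(x, y):
    grid = [np.array([a, b]) for a in (1.0, 10.0, 100.0) for b in (0.5, 1.0, 2.0)]
    return _log_linearised_start(x, y, "Halsey") + grid


def _henderson_starts(x, y):
    grid = [np.array([a, b]) for a in (0.01, 0.1, 1.0) for b in (0.5, 1.0, 2.0)]
    return _log_linearised_start(x, y, "Henderson") + grid


def _zero_start(x, y):
    return [np.polyfit(x, y, 1)[::-1].copy()]


def _first_starts(x, y):
    ymax = max(float(np.max(y)), 1e-6)
    return [np.array([a, b]) for a in (ymax, 1.2 * ymax) for b in (0.5, 1.0, 2.0, 4.0)]


def _second_starts(x, y):
    ymax = max(float(np.max(y)), 1e-6)
    return [np.array([a, b]) for a in (ymax, 1.5 * ymax) for b in (0.1, 0.5, 1.0, 2.0)]


def _biexp_starts(x, y):
    ymax = max(float(np.max(y)), 1e-6)
    return [
        np.array([-0.5 * ymax, -0.5 * ymax, c, d, ymax])
        for c in (0.3, 1.0)
        for d in (0.5, 3.0)
    ]


_START_GRIDS = {
    "GAB": _gab_starts,
    "Peleg": _peleg_starts,
    "Smith": _smith_start,
    "Halsey": _halsey_starts,
    "Henderson": _henderson_starts,
    "zero_order": _zero_start,
    "first_order": _first_starts,
    "second_order": _second_starts,
    "biexponential": _biexp_starts,
}


def _bounds_arrays(spec) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([-np.inf if b[0] is None else b[0] for b in spec.bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in spec.bounds])
    return lo, hi


def _start_stream(grid: list[np.ndarray], lo, hi, rng) -> Iterable[np.ndarray]:
    """Deterministic grid first, then seeded multiplicative perturbations."""
    for g in grid:
        yield np.clip(g, lo, hi)
    base = grid[rng.integers(len(grid))] if grid else np.ones(len(lo))
    while True:
        pert = base * np.exp(rng.normal(0.0, 0.7, size=base.shape))
        pert = np.where(base == 0.0, rng.normal(0.0, 1.0, size=base.shape), pert)
        yield np.clip(pert, lo, hi)


def _extract_xy(data, include_time_zero: bool) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(data, SorptionDataset):
        return data.aw, data.emc, "isotherm"
    if isinstance(data, KineticSeries):
        t, y = data.times, data.mgr
        if include_time_zero and t[0] > 0.0:
            t = np.concatenate([[0.0], t])
            y = np.concatenate([[0.0], y])
        return t, y, "kinetic"
    raise ValidationError(f"cannot fit data of type {type(data).__name__}")


def fit_model(
    data: "SorptionDataset | KineticSeries",
    model_name: str,
    *,
    n_starts: int = 16,
    seed: int = 0,
    include_time_zero: bool = True,
    max_nfev: int = 10_000,
) -> FitResult:
    """Fit one named model to a sorption dataset or kinetic series.

    Parameters
    ----------
    data
        :class:`SorptionDataset` (isotherm models) or
        :class:`~capsorb.kinetics.KineticSeries` (kinetic models).
    model_name
        A key of :data:`~capsorb.isotherms.ISOTHERM_MODELS` or
        :data:`~capsorb.kinetics.KINETIC_MODELS`.
    n_starts
        Number of multi-start initial guesses; the best converged objective
        wins, so adding starts can only improve (never worsen) the fit.
    seed
        Seeds the random perturbation starts; the deterministic grid starts
        are seed-independent.
    include_time_zero
        Kinetic fits prepend the implicit (t=0, Mgr=0) anchor when the
        series starts later (the usual weighing protocol starts at 0.5 h).

    Raises
    ------
    ValidationError
        If the data has no more points than the model has free parameters.
    ConvergenceError
        If no start converges; carries per-start diagnostics.
    """
    x, y, kind = _extract_xy(data, include_time_zero)
    registry = ISOTHERM_MODELS if kind == "isotherm" else KINETIC_MODELS
    if model_name not in registry:
        raise ValidationError(
            f"model {model_name!r} is not a {kind} model; expected one of {sorted(registry)}"
        )
    spec = registry[model_name]
    n_free = len(spec.param_names)
    if len(x) <= n_free:
        raise ValidationError(
            f"{model_name} has {n_free} free parameters but only {len(x)} data "
            f"points were given; need at least {n_free + 1}"
        )

    fn = spec.fn
    names = spec.param_names
    lo, hi = _bounds_arrays(spec)

    def residual(theta):
        with np.errstate(all="ignore"):
            pred = fn(dict(zip(names, theta)), x)
        r = y - pred
        return np.where(np.isfinite(r), r, 1e12)

    rng = np.random.default_rng(seed)
    grid = _START_GRIDS[model_name](x, y)
    starts = itertools.islice(_start_stream(grid, lo, hi, rng), max(n_starts, 1))

    best = None
    best_idx = -1
    diagnostics = []
    for i, p0 in enumerate(starts):
        try:
            res = least_squares(
                residual,
                p0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=max_nfev,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:  # start outside domain etc.
            diagnostics.append({"start": i, "error": str(exc)})
            continue
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.cost):
            diagnostics.append({"start": i, "error": "non-finite optimum"})
            continue
        diagnostics.append({"start": i, "cost": float(res.cost), "success": bool(res.success)})
        if best is None or res.cost < best.cost:
            best, best_idx = res, i
    if best is None:
        raise ConvergenceError(
            f"no start converged for {model_name}", diagnostics=diagnostics
        )

    params = dict(zip(names, (float(v) for v in best.x)))
    pred = fn(params, x)
    r2, rss = goodness_of_fit(y, pred)
    param_se = _asymptotic_se(best.jac, rss, len(x), n_free, names)
    return FitResult(
        model_name=model_name,
        params=params,
        r2=r2,
        rss=rss,
        n_points=len(x),
        converged=bool(best.success),
        param_se=param_se,
        seed_trace=f"seed={seed};n_starts={n_starts};best_start={best_idx}",
    )


def _asymptotic_se(jac, rss, n, p, names) -> dict | None:
    if n <= p:
        return None
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / (n - p)
        diag = np.diag(cov)
        if np.any(diag < 0):
            return None
        return dict(zip(names, np.sqrt(diag).tolist()))
    except np.linalg.LinAlgError:
        return None


def fit_all_models(
    data: "SorptionDataset | KineticSeries", **options
) -> list[FitResult]:
    """Fit every registered model of the data's kind; returns one
    :class:`FitResult` per model in registry order."""
    registry = ISOTHERM_MODELS if isinstance(data, SorptionDataset) else KINETIC_MODELS
    return [fit_model(data, name, **options) for name in registry]


def select_best(fits: Sequence[FitResult]) -> str:
    """Name of the best-fitting model under the R²/RSS criterion.

    Highest R² wins; R² ties at 4 decimal places are broken by lower RSS,
    then by fewer free parameters, then alphabetically (so the choice is
    deterministic and independent of input order).
    """
    if not fits:
        raise ValidationError("select_best needs a non-empty list of fits")
    ranked = sorted(
        fits,
        key=lambda f: (-round(f.r2, 4), f.rss, f.n_free_params, f.model_name),
    )
    return ranked[0].model_name
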