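"""Sorption-isotherm models for water uptake of hygroscopic biomaterials.

Five classical equilibrium moisture-sorption models relating water activity
``aw`` (dimensionless fraction, 0-1) to equilibrium moisture change EMC (%):

=========  =============================================  ==========
model      EMC(aw)                                        parameters
=========  =============================================  ==========
GAB        k*c*aw*x0 / ((1-k*aw)*(1-k*aw+k*c*aw))         k, c, x0
Peleg      a*aw**b + c*aw**d                              a, b, c, d
Smith      a + b*ln(1-aw)                                 a, b
Halsey     (-a/ln(aw))**(1/b)                             a, b
Henderson  (-(1/a)*ln(1-aw))**(1/b)                       a, b
=========  =============================================  ==========

The GAB (Guggenheim-Anderson-de Boer) model describes multilayer sorption
with monolayer capacity ``x0``, energy constant ``c`` and multilayer
correction ``k``; it produces the sigmoid Type-II isotherms typical of
gelatin and other biopolymers.  The Smith model (with b < 0 in the sign
convention used here) is the common two-parameter alternative on the
multilayer region.  All models take water activity as a fraction, never
as RH %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, RangeError, ValidationError

__all__ = [
    "ISOTHERM_MODELS",
    "IsothermParams",
    "evaluate_isotherm",
    "invert_isotherm",
    "attainable_emc_range",
]

_EPS = 1e-12


def _gab(p: Mapping[str, float], x):
    k, c, x0 = p["k"], p["c"], p["x0"]
    kx = k * x
    return (k * c * x * x0) / ((1.0 - kx) * (1.0 - kx + c * kx))


def _peleg(p: Mapping[str, float], x):
    return p["a"] * x ** p["b"] + p["c"] * x ** p["d"]


def _smith(p: Mapping[str, float], x):
    return p["a"] + p["b"] * np.log1p(-x)


def _halsey(p: Mapping[str, float], x):
    return (-p["a"] / np.log(x)) ** (1.0 / p["b"])


def _henderson(p: Mapping[str, float], x):
    return (-np.log1p(-x) / p["a"]) ** (1.0 / p["b"])


@dataclass(frozen=True)
class _ModelSpec:
    """Registry entry: parameter order, fitting bounds and the forward map."""

    param_names: tuple[str, ...]
    fn: Callable
    # per-parameter (lo, hi) for the fitter; None means unbounded on that side
    bounds: tuple[tuple[float | None, float | None], ...]


ISOTHERM_MODELS: dict[str, _ModelSpec] = {
    "GAB": _ModelSpec(("k", "c", "x0"), _gab, ((_EPS, 1.0), (_EPS, None), (_EPS, None))),
    "Peleg": _ModelSpec(
        ("a", "b", "c", "d"), _peleg, ((0.0, None), (_EPS, None), (0.0, None), (_EPS, None))
    ),
    "Smith": _ModelSpec(("a", "b"), _smith, ((None, None), (None, None))),
    "Halsey": _ModelSpec(("a", "b"), _halsey, ((_EPS, None), (_EPS, None))),
    "Henderson": _ModelSpec(("a", "b"), _henderson, ((_EPS, None), (_EPS, None))),
}


@dataclass(frozen=True)
class IsothermParams:
    """Parameter set of one isotherm model.

    Parameters are stored in the model's canonical order (see
    :data:`ISOTHERM_MODELS`).  Construction validates the physical
    constraints: GAB needs 0 < k <= 1, c > 0, x0 > 0; Halsey and Henderson
    need positive a, b; Smith's slope b may be negative (and is, for
    materials whose uptake grows with aw under the ``a + b*ln(1-aw)``
    convention).
    """

    model_name: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model_name not in ISOTHERM_MODELS:
            raise ValidationError(
                f"unknown isotherm model {self.model_name!r}; "
                f"expected one of {sorted(ISOTHERM_MODELS)}"
            )
        spec = ISOTHERM_MODELS[self.model_name]
        missing = set(spec.param_names) - set(self.params)
        extra = set(self.params) - set(spec.param_names)
        if missing or extra:
            raise ValidationError(
                f"{self.model_name} expects parameters {spec.param_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        object.__setattr__(self, "params", dict(self.params))
        p = self.params
        if self.model_name == "GAB":
            if not (0.0 < p["k"] <= 1.0):
                raise ValidationError(f"GAB requires k in (0, 1], got k={p['k']}")
            if p["c"] <= 0 or p["x0"] <= 0:
                raise ValidationError("GAB requires c > 0 and x0 > 0")
        elif self.model_name == "Peleg":
            if p["a"] < 0 or p["c"] < 0:
                raise ValidationError("Peleg requires a >= 0 and c >= 0")
            if p["b"] <= 0 or p["d"] <= 0:
                raise ValidationError("Peleg requires b > 0 and d > 0")
        elif self.model_name in ("Halsey", "Henderson"):
            if p["a"] <= 0 or p["b"] <= 0:
                raise ValidationError(f"{self.model_name} requires a > 0 and b > 0")

    @property
    def values(self) -> np.ndarray:
        """Parameter vector in canonical order."""
        spec = ISOTHERM_MODELS[self.model_name]
        return np.array([self.params[n] for n in spec.param_names], dtype=float)

    def aw_upper(self, aw_max: float = 0.9999) -> float:
        """Largest admissible water activity for this model (``aw_max`` capped
        at 1/k - 1e-9 for GAB, whose formula poles at aw = 1/k)."""
        if self.model_name == "GAB":
            return min(aw_max, 1.0 / self.params["k"] - 1e-9)
        return aw_max


def _check_domain(params: IsothermParams, aw: float) -> None:
    if not 0.0 <= aw < 1.0:
        raise DomainError(
            f"{params.model_name}: water activity must satisfy 0 <= aw < 1, got {aw}"
        )
    if params.model_name == "GAB":
        k = params.params["k"]
        if aw * k >= 1.0:
            raise DomainError(
                f"GAB: aw must be below 1/k = {1.0 / k:.6g}, got {aw}"
            )
    if params.model_name == "Halsey" and aw == 0.0:
        raise DomainError("Halsey: aw must be strictly positive (ln aw pole at 0)")


def evaluate_isotherm(params: IsothermParams, aw) -> float | np.ndarray:
    """Equilibrium moisture change EMC (%) predicted at water activity ``aw``.

    ``aw`` may be a scalar or array; every element must lie in the model's
    domain (``[0, 1)``, additionally ``aw < 1/k`` for GAB and ``aw > 0`` for
    Halsey), else :class:`DomainError`.
    """
    arr = np.asarray(aw, dtype=float)
    for a in np.atleast_1d(arr):
        _check_domain(params, float(a))
    out = ISOTHERM_MODELS[params.model_name].fn(params.params, arr)
    return float(out) if np.isscalar(aw) or arr.ndim == 0 else out


def attainable_emc_range(
    params: IsothermParams, aw_lo: float = 0.0, aw_hi: float | None = None
) -> tuple[float, float]:
    """EMC interval the model spans over ``[aw_lo, aw_hi]``.

    All five models are monotone in aw for physically valid parameters
    (Smith monotone for either sign of b), so the interval is the sorted
    pair of endpoint values.  Halsey's lower endpoint is evaluated just
    above 0 where its limit is 0.
    """
    hi = params.aw_upper() if aw_hi is None else min(aw_hi, params.aw_upper())
    lo = aw_lo
    if params.model_name == "Halsey" and lo == 0.0:
        y_lo = 0.0
    else:
        y_lo = evaluate_isotherm(params, lo)
    y_hi = evaluate_isotherm(params, hi)
    return (min(y_lo, y_hi), max(y_lo, y_hi))


def _invert_gab(params: IsothermParams, emc: float) -> float:
    # emc*(1-u)*(1-u+c*u) = c*x0*u with u = k*aw expands to the quadratic
    # emc*(1-c)*u^2 - (emc*(2-c) + c*x0)*u + emc = 0
    k, c, x0 = (params.params[n] for n in ("k", "c", "x0"))
    A = emc * (1.0 - c)
    B = -(emc * (2.0 - c) + c * x0)
    C = emc
    if abs(A) < _EPS * max(abs(B), abs(C), 1.0):  # c == 1 degenerates to linear
        roots = [-C / B]
    else:
        disc = B * B - 4.0 * A * C
        if disc < 0:
            raise RangeError(f"GAB: no real root for EMC {emc}")
        sq = math.sqrt(disc)
        roots = [(-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)]
    # physical root: u = k*aw in (0, 1); if both qualify take the smaller
    candidates = sorted(u for u in roots if 0.0 < u < 1.0)
    if not candidates:
        raise RangeError(
            f"GAB: EMC {emc} has no root with aw in (0, 1/k)",
            attainable=attainable_emc_range(params),
        )
    return candidates[0] / k


def invert_isotherm(
    params: IsothermParams, emc_percent: float, aw_max: float | None = None
) -> float:
    """Water activity at which the model attains ``emc_percent``.

    Closed forms are used where they exist (Smith: ``1 - exp((y-a)/b)``;
    GAB: the physical root of its quadratic); Peleg, Halsey and Henderson
    are inverted by bracketed root finding on the forward formula.  The
    returned aw reproduces ``emc_percent`` to better than 1e-9 EMC units.

    Raises :class:`RangeError` (carrying the attainable interval) when the
    model cannot reach ``emc_percent`` on ``(0, aw_max)``.
    """
    hi = params.aw_upper(0.9999 if aw_max is None else aw_max)
    name = params.model_name
    if name == "Smith":
        a, b = params.params["a"], params.params["b"]
        aw = 1.0 - math.exp((emc_percent - a) / b)
        if not 0.0 <= aw <= hi:
            raise RangeError(
                f"Smith: EMC {emc_percent} maps to aw={aw:.6g} outside [0, {hi:.6g}]",
                attainable=attainable_emc_range(params, aw_hi=hi),
            )
        return aw
    if name == "GAB":
        if emc_percent == 0.0:
            return 0.0
        aw = _invert_gab(params, emc_percent)
        if aw > hi:
            raise RangeError(
                f"GAB: EMC {emc_percent} requires aw={aw:.6g} > aw_max={hi:.6g}",
                attainable=attainable_emc_range(params, aw_hi=hi),
            )
        return aw
    # Peleg / Halsey / Henderson: monotone increasing -> bracketed root find
    lo = 1e-12 if name == "Halsey" else 0.0
    y_lo = evaluate_isotherm(params, lo) if lo > 0 else 0.0
    y_hi = evaluate_isotherm(params, hi)
    lo_v, hi_v = min(y_lo, y_hi), max(y_lo, y_hi)
    if not lo_v <= emc_percent <= hi_v:
        raise RangeError(
            f"{name}: EMC {emc_percent} outside attainable [{lo_v:.6g}, {hi_v:.6g}] "
            f"on aw in [{lo:g}, {hi:g}]",
            attainable=(lo_v, hi_v),
        )
    if emc_percent == y_lo:
        return lo
    f = lambda aw: evaluate_isotherm(params, aw) - emc_percent
    return brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
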