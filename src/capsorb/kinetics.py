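"""Hygroscopic (moisture-uptake) kinetics models.

Four empirical models for the moisture gain rate Mgr (%) of a material
stored at fixed temperature and humidity, as a function of time t (hours):

==============  ========================================  ================
model           Mgr(t)                                    parameters
==============  ========================================  ================
zero_order      a + b*t                                   a, b
first_order     a*(1 - exp(-b*t))                         a, b
second_order    a*b^2*t / (1 + a*b*t)                     a, b
biexponential   A1*exp(-t/c) + A2*exp(-t/d) + y0          A1, A2, c, d, y0
==============  ========================================  ================

For the first-order model ``a`` is the saturation moisture gain (%) and
``b`` the uptake rate constant (1/h); uptake reaches a fraction ``f`` of
saturation at ``t = -ln(1-f)/b``.  The biexponential form is kept exactly
as written — the fitted amplitudes A1, A2 may come out negative for a
rising uptake curve, which is allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import DomainError, UnsupportedModelError, ValidationError

__all__ = [
    "KINETIC_MODELS",
    "KineticParams",
    "KineticSeries",
    "evaluate_kinetic",
    "time_to_fraction",
]

_EPS = 1e-12


def _zero(p, t):
    return p["a"] + p["b"] * t


def _first(p, t):
    return p["a"] * -np.expm1(-p["b"] * t)


def _second(p, t):
    ab = p["a"] * p["b"]
    return ab * p["b"] * t / (1.0 + ab * t)


def _biexp(p, t):
    return p["A1"] * np.exp(-t / p["c"]) + p["A2"] * np.exp(-t / p["d"]) + p["y0"]


@dataclass(frozen=True)
class _ModelSpec:
    param_names: tuple[str, ...]
    fn: object
    bounds: tuple[tuple[float | None, float | None], ...]


KINETIC_MODELS: dict[str, _ModelSpec] = {
    "zero_order": _ModelSpec(("a", "b"), _zero, ((None, None), (None, None))),
    "first_order": _ModelSpec(("a", "b"), _first, ((_EPS, None), (_EPS, None))),
    "second_order": _ModelSpec(("a", "b"), _second, ((_EPS, None), (_EPS, None))),
    "biexponential": _ModelSpec(
        ("A1", "A2", "c", "d", "y0"),
        _biexp,
        ((None, None), (None, None), (_EPS, None), (_EPS, None), (None, None)),
    ),
}


@dataclass(frozen=True)
class KineticParams:
    """Parameter set of one kinetic model (canonical order per registry)."""

    model_name: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model_name not in KINETIC_MODELS:
            raise ValidationError(
                f"unknown kinetic model {self.model_name!r}; "
                f"expected one of {sorted(KINETIC_MODELS)}"
            )
        spec = KINETIC_MODELS[self.model_name]
        missing = set(spec.param_names) - set(self.params)
        extra = set(self.params) - set(spec.param_names)
        if missing or extra:
            raise ValidationError(
                f"{self.model_name} expects parameters {spec.param_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        object.__setattr__(self, "params", dict(self.params))
        p = self.params
        if self.model_name in ("first_order", "second_order"):
            if p["a"] <= 0 or p["b"] <= 0:
                raise ValidationError(f"{self.model_name} requires a > 0 and b > 0")
        elif self.model_name == "biexponential":
            if p["c"] <= 0 or p["d"] <= 0:
                raise ValidationError("biexponential requires time constants c, d > 0")

    @property
    def values(self) -> np.ndarray:
        spec = KINETIC_MODELS[self.model_name]
        return np.array([self.params[n] for n in spec.param_names], dtype=float)


@dataclass(frozen=True)
class KineticSeries:
    """One moisture-uptake time course at a fixed storage condition.

    ``condition`` is (temperature in K, relative humidity in %); points are
    (time in h, Mgr in %) with strictly increasing times.
    """

    condition: tuple[float, float]
    points: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self):
        pts = tuple((float(t), float(y)) for t, y in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValidationError("a kinetic series needs at least 2 points")
        times = [t for t, _ in pts]
        if any(t < 0 for t in times):
            raise ValidationError("times must be non-negative")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def mgr(self) -> np.ndarray:
        return np.array([y for _, y in self.points])


def evaluate_kinetic(params: KineticParams, t) -> float | np.ndarray:
    """Moisture gain rate Mgr (%) at time ``t`` (hours, scalar or array)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{params.model_name}: time must be >= 0, got {t}")
    out = KINETIC_MODELS[params.model_name].fn(params.params, arr)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def time_to_fraction(params: KineticParams, fraction: float) -> float:
    """Time (h) at which first-order uptake reaches ``fraction`` of saturation.

    Inverts Mgr(t) = a*(1 - exp(-b*t)) at Mgr = fraction*a, giving
    ``-ln(1 - fraction)/b``.  Only defined for the first-order model;
    a handy diagnostic for "saturates within N hours" statements.
    """
    if params.model_name != "first_order":
        raise UnsupportedModelError(
            f"time_to_fraction applies to first_order only, got {params.model_name}"
        )
    if not 0.0 <= fraction < 1.0:
        raise DomainError(f"fraction must be in [0, 1), got {fraction}")
    return -math.log1p(-fraction) / params.params["b"]
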