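"""Differential thermodynamics of water sorption.

From isotherm fits at two or more temperatures the full differential
chain is computed:

* Gibbs free energy of sorption,  dG = -R*T*ln(aw)  [J/mol] — positive
  for aw < 1, so sorption from a sub-saturated atmosphere is
  non-spontaneous.
* Net isosteric heat qst and differential entropy dSd at fixed moisture
  content, from the Clausius-Clapeyron relation: at each EMC the
  isotherms are inverted to aw(T) and ``ln aw = -qst/(R*T) + dSd/R`` is
  fitted by ordinary least squares of ln aw on 1/T; qst = -R*slope,
  dSd = R*intercept.
* Spreading pressure (surface potential) from GAB constants,
  phi = (kB*T/AM) * ln((1 - k*aw + k*c*aw)/(1 - k*aw))  [J/m^2],
  with AM the area of a sorbed water molecule.
* Enthalpy-entropy compensation: qst = T_beta*dSd + dG_beta fitted by OLS
  over the EMC grid.  Following Krug's criterion the compensation is
  meaningful only when the isokinetic temperature T_beta differs from the
  harmonic-mean experimental temperature T_hm; T_hm < T_beta marks an
  enthalpy-driven process, T_hm > T_beta an entropy-driven one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DomainError, RangeError, ValidationError, DegenerateDataError
from .isotherms import IsothermParams, attainable_emc_range, invert_isotherm

__all__ = [
    "GAS_CONSTANT",
    "BOLTZMANN",
    "WATER_MOLECULE_AREA",
    "LATENT_HEAT_WATER",
    "ThermoPoint",
    "CompensationFit",
    "gibbs_free_energy",
    "isosteric_analysis",
    "spreading_pressure",
    "harmonic_mean_temperature",
    "compensation_fit",
    "default_emc_grid",
]

GAS_CONSTANT = 8.314  # J/(mol K)
BOLTZMANN = 1.38e-23  # J/K
WATER_MOLECULE_AREA = 1.06e-19  # m^2, area of one sorbed water molecule
LATENT_HEAT_WATER = 44_000.0  # J/mol, vaporisation latent heat (reference only)


@dataclass(frozen=True)
class ThermoPoint:
    """Isosteric quantities at one fixed equilibrium moisture content.

    ``qst`` is the net isosteric heat (J/mol), ``dS`` the differential
    entropy (J/(mol K)); ``per_temperature_aw`` maps each temperature (K)
    to the inverted water activity; ``fit_r2`` is the R² of the ln aw vs
    1/T regression (identically 1 with two temperatures).
    """

    emc_percent: float
    qst: float
    dS: float
    per_temperature_aw: Mapping[float, float]
    fit_r2: float

    def __post_init__(self):
        aw = dict(self.per_temperature_aw)
        if len(aw) < 2:
            raise ValidationError("a ThermoPoint needs at least 2 temperatures")
        if any(not 0.0 < a < 1.0 for a in aw.values()):
            raise ValidationError("inverted water activities must lie in (0, 1)")
        object.__setattr__(self, "per_temperature_aw", MappingProxyType(aw))

    def to_dict(self) -> dict:
        return {
            "emc_percent": self.emc_percent,
            "qst_j_per_mol": self.qst,
            "dS_j_per_mol_k": self.dS,
            "per_temperature_aw": {f"{t:g}": a for t, a in self.per_temperature_aw.items()},
            "fit_r2": self.fit_r2,
        }


@dataclass(frozen=True)
class CompensationFit:
    """Enthalpy-entropy compensation line and Krug classification.

    ``t_beta`` (K) is the slope of qst on dSd (isokinetic temperature) and
    ``dG_beta`` (J/mol) the intercept (Gibbs energy at T_beta; positive
    means sorption stays non-spontaneous).  ``driving`` is "enthalpy" when
    t_hm < t_beta, "entropy" when t_hm > t_beta; ``applicable`` is False
    when |t_beta - t_hm| falls within the tolerance (compensation theory
    then makes no claim and the report layer labels the driver
    "indeterminate").
    """

    t_beta: float
    dG_beta: float
    r2: float
    t_hm: float
    driving: str
    applicable: bool

    @property
    def spontaneous(self) -> bool:
        return self.dG_beta < 0

    def to_dict(self) -> dict:
        return {
            "t_beta_k": self.t_beta,
            "dG_beta_j_per_mol": self.dG_beta,
            "r2": self.r2,
            "t_hm_k": self.t_hm,
            "driving": self.driving if self.applicable else "indeterminate",
            "applicable": self.applicable,
            "spontaneous": self.spontaneous,
        }


def gibbs_free_energy(temperature_k: float, aw: float) -> float:
    """Gibbs free energy of sorption, -R*T*ln(aw) in J/mol.

    Positive for aw < 1 (water must be driven onto the sorbent), zero at
    saturation.  ``aw`` must lie in (0, 1]."""
    if temperature_k <= 0:
        raise DomainError(f"temperature must be positive, got {temperature_k} K")
    if not 0.0 < aw <= 1.0:
        raise DomainError(f"water activity must be in (0, 1], got {aw}")
    return -GAS_CONSTANT * temperature_k * math.log(aw)


def default_emc_grid(
    fits: Mapping[float, IsothermParams],
    n: int = 20,
    aw_lo: float = 0.43,
    aw_hi: float = 0.92,
) -> np.ndarray:
    """Evenly spaced EMC values attainable at every temperature.

    The grid spans the intersection of the per-temperature attainable EMC
    intervals over ``[aw_lo, aw_hi]`` (defaults matching a 43-92% RH
    experimental span), shrunk marginally so endpoints stay strictly
    invertible at all temperatures.
    """
    if len(fits) < 2:
        raise ValidationError("need isotherm fits at >= 2 temperatures")
    lo = -np.inf
    hi = np.inf
    for params in fits.values():
        a, b = attainable_emc_range(params, aw_lo, aw_hi)
        lo, hi = max(lo, a), min(hi, b)
    if not lo < hi:
        raise RangeError(
            f"attainable EMC ranges do not overlap (intersection [{lo:.4g}, {hi:.4g}])",
            attainable=(lo, hi),
        )
    pad = 1e-9 * max(1.0, abs(hi - lo))
    return np.linspace(lo + pad, hi - pad, n)


def isosteric_analysis(
    best_fits: Mapping[float, IsothermParams],
    emc_grid: Sequence[float],
) -> list[ThermoPoint]:
    """Clausius-Clapeyron analysis over an EMC grid.

    For each EMC value every temperature's isotherm is inverted to its
    water activity and ``ln aw`` is regressed on ``1/T``; the slope gives
    the net isosteric heat qst = -R*slope and the intercept the
    differential entropy dSd = R*intercept.

    ``best_fits`` maps temperature (K) to the selected isotherm's
    parameters.  An EMC outside any temperature's attainable range raises
    :class:`RangeError` naming that temperature.
    """
    if len(best_fits) < 2:
        raise ValidationError("isosteric analysis needs >= 2 temperatures")
    temps = sorted(best_fits)
    inv_t = np.array([1.0 / t for t in temps])
    points: list[ThermoPoint] = []
    for emc in emc_grid:
        aw_by_t: dict[float, float] = {}
        for t in temps:
            try:
                aw_by_t[t] = invert_isotherm(best_fits[t], float(emc))
            except RangeError as exc:
                raise RangeError(
                    f"EMC {emc:.6g}% unattainable at T={t} K: {exc}",
                    attainable=exc.attainable,
                ) from exc
        ln_aw = np.array([math.log(aw_by_t[t]) for t in temps])
        slope, intercept = np.polyfit(inv_t, ln_aw, 1)
        pred = slope * inv_t + intercept
        ss_res = float(np.sum((ln_aw - pred) ** 2))
        ss_tot = float(np.sum((ln_aw - ln_aw.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        points.append(
            ThermoPoint(
                emc_percent=float(emc),
                qst=-GAS_CONSTANT * float(slope),
                dS=GAS_CONSTANT * float(intercept),
                per_temperature_aw=aw_by_t,
                fit_r2=r2,
            )
        )
    return points


def spreading_pressure(gab: IsothermParams, temperature_k: float, aw: float) -> float:
    """Spreading pressure (surface potential) phi in J/m² from GAB constants.

    phi = (kB*T/AM) * ln((1 - k*aw + k*c*aw) / (1 - k*aw)); zero at aw = 0
    and increasing in aw whenever c >= 1.  Requires the GAB model and
    0 <= aw < 1/k.
    """
    if gab.model_name != "GAB":
        raise ValidationError(f"spreading pressure needs GAB constants, got {gab.model_name}")
    if temperature_k <= 0:
        raise DomainError("temperature must be positive")
    k, c = gab.params["k"], gab.params["c"]
    if not 0.0 <= aw < 1.0 / k:
        raise DomainError(f"GAB spreading pressure needs 0 <= aw < 1/k = {1.0 / k:.6g}")
    num = 1.0 - k * aw + k * c * aw
    den = 1.0 - k * aw
    return BOLTZMANN * temperature_k / WATER_MOLECULE_AREA * math.log(num / den)


def harmonic_mean_temperature(temps_k: Sequence[float]) -> float:
    """Harmonic mean N / sum(1/T_i) of the experimental temperatures (K)."""
    if len(temps_k) == 0:
        raise ValidationError("temperature list must be non-empty")
    if any(t <= 0 for t in temps_k):
        raise ValidationError("temperatures must be positive (K)")
    return len(temps_k) / sum(1.0 / t for t in temps_k)


def compensation_fit(
    points: Sequence[ThermoPoint],
    temps_k: Sequence[float],
    *,
    tolerance_k: float = 1.0,
) -> CompensationFit:
    """Fit the compensation line qst = T_beta * dSd + dG_beta by OLS.

    Needs at least 3 thermo points with finite (qst, dSd) and non-constant
    dSd.  ``driving`` follows Krug's comparison of T_beta with the
    harmonic-mean temperature of ``temps_k``; when the two agree within
    ``tolerance_k`` the compensation is flagged not applicable.
    """
    finite = [p for p in points if math.isfinite(p.qst) and math.isfinite(p.dS)]
    if len(finite) < 3:
        raise ValidationError(
            f"compensation fit needs >= 3 finite thermo points, got {len(finite)}"
        )
    ds = np.array([p.dS for p in finite])
    q = np.array([p.qst for p in finite])
    if float(np.ptp(ds)) == 0.0:
        raise DegenerateDataError("differential entropy has zero variance")
    slope, intercept = np.polyfit(ds, q, 1)
    pred = slope * ds + intercept
    ss_res = float(np.sum((q - pred) ** 2))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    t_hm = harmonic_mean_temperature(temps_k)
    t_beta = float(slope)
    return CompensationFit(
        t_beta=t_beta,
        dG_beta=float(intercept),
        r2=r2,
        t_hm=t_hm,
        driving="enthalpy" if t_hm < t_beta else "entropy",
        applicable=abs(t_beta - t_hm) > tolerance_k,
    )
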