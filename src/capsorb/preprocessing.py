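"""Raw-measurement preprocessing and reference data.

Converts gravimetric measurements into the normalized quantities the
sorption models consume:

* equilibrium moisture change  EMC% = 100 * (W1 - W0) / (W0 * Mfs)
* moisture gain rate           Mgr% = 100 * (m1 - m0) / (m0 * Mfs)

where W0/m0 and W1/m1 are whole-capsule masses before and after moisture
uptake and Mfs is the skin (shell) mass fraction — both changes are
expressed per unit of shell mass because only the gelatin shell sorbs
water.  Also provides the saturated-salt-solution relative-humidity
reference table used to set chamber humidities at 25/32/37 degC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import ValidationError, DomainError, CapsorbError

__all__ = [
    "MassRecord",
    "SALT_RH_TABLE",
    "compute_emc",
    "compute_mgr",
    "salt_rh",
    "skin_mass_fraction",
    "celsius_to_kelvin",
]


@dataclass(frozen=True)
class MassRecord:
    """Whole-capsule mass before (`w0`, g) and after (`w1`, g) uptake, with
    the skin mass fraction `mfs` (shell mass / whole-capsule mass)."""

    w0: float
    w1: float
    mfs: float

    def __post_init__(self):
        if self.w0 <= 0:
            raise ValidationError(f"mass before uptake must be positive, got {self.w0}")
        if not 0.0 < self.mfs <= 1.0:
            raise ValidationError(f"skin mass fraction must be in (0, 1], got {self.mfs}")


# Saturated-salt relative humidities (%) at the three study temperatures.
# Keyed (salt, temperature degC).  Values are retained exactly as tabulated
# in the source experiment, including Na2CO3's 97% at 37 degC.
SALT_RH_TABLE: dict[tuple[str, int], float] = {
    ("K2CO3", 25): 45, ("K2CO3", 32): 46, ("K2CO3", 37): 45,
    ("KBr", 25): 62, ("KBr", 32): 61, ("KBr", 37): 58,
    ("KI", 25): 73, ("KI", 32): 72, ("KI", 37): 71,
    ("NaCl", 25): 79, ("NaCl", 32): 77, ("NaCl", 37): 79,
    ("KCl", 25): 88, ("KCl", 32): 84, ("KCl", 37): 87,
    ("Na2CO3", 25): 92, ("Na2CO3", 32): 92, ("Na2CO3", 37): 97,
}

SALTS: tuple[str, ...] = ("K2CO3", "KBr", "KI", "NaCl", "KCl", "Na2CO3")


class SaltLookupError(CapsorbError, KeyError):
    """Unknown (salt, temperature) key; message lists the valid keys."""


def compute_emc(rec: MassRecord) -> float:
    """Equilibrium moisture change (%) per unit shell mass.

    Negative values (net mass loss, i.e. desorption) are allowed and
    returned unclipped.
    """
    return 100.0 * (rec.w1 - rec.w0) / (rec.w0 * rec.mfs)


def compute_mgr(rec: MassRecord) -> float:
    """Moisture gain rate (%) per unit shell mass — same formula as
    :func:`compute_emc` applied to a time-resolved mass pair."""
    return compute_emc(rec)


def salt_rh(salt: str, temp_c: float) -> float:
    """Tabulated chamber RH (%) over a saturated solution of ``salt`` at
    ``temp_c`` degC; raises :class:`SaltLookupError` for untabulated keys."""
    key = (salt, int(temp_c))
    if key not in SALT_RH_TABLE or temp_c != int(temp_c):
        raise SaltLookupError(
            f"no tabulated RH for {salt!r} at {temp_c} degC; "
            f"valid keys: {sorted(SALT_RH_TABLE)}"
        )
    return float(SALT_RH_TABLE[key])


def skin_mass_fraction(
    capsule_masses_g: Sequence[float], skin_masses_g: Sequence[float]
) -> float:
    """Mfs estimated from per-capsule (whole, shell) weighings as
    mean shell mass / mean whole-capsule mass."""
    if len(capsule_masses_g) == 0 or len(skin_masses_g) == 0:
        raise ValidationError("need at least one capsule and one skin mass")
    if any(m <= 0 for m in capsule_masses_g) or any(m <= 0 for m in skin_masses_g):
        raise ValidationError("masses must be positive")
    mfs = (sum(skin_masses_g) / len(skin_masses_g)) / (
        sum(capsule_masses_g) / len(capsule_masses_g)
    )
    if not 0.0 < mfs <= 1.0:
        raise ValidationError(f"computed skin mass fraction {mfs:.4g} outside (0, 1]")
    return mfs


def celsius_to_kelvin(t_c: float) -> float:
    """Absolute temperature (K); rejects inputs below absolute zero."""
    if t_c <= -273.15:
        raise DomainError(f"temperature {t_c} degC is at or below absolute zero")
    return t_c + 273.15
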