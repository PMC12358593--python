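"""Synthetic sorption studies with the structure the analysis assumes.

The generator emulates a salt-slurry humidistat study: three storage
temperatures (25/32/37 degC), six chamber humidities set by saturated
salt solutions (K2CO3 ... Na2CO3, ~45-97% RH), equilibrium moisture
change measured per humidity, plus a first-order moisture-uptake time
course at 68% RH weighed every half hour.  Measurement error is additive
homoscedastic Gaussian on EMC/Mgr (an optional heteroscedastic mode
scales the sd with the signal); each reported point is the mean of
``replicate_count`` noisy weighings, mirroring the mean-of-replicates
convention of gravimetric work.  Every generator is a pure function of
(config, seed): identical inputs give bit-identical output.

The default ground truth mirrors the fitted models of a gelatin-shell
capsule study: Smith isotherms at 25 and 37 degC and a GAB isotherm at
32 degC whose monolayer capacity x0 is set to a physically coherent 4.0
(NOT the anomalously scaled value printed in the source fit table), with
first-order kinetics at all three temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DomainError, ValidationError
from .fitting import SorptionDataset
from .isotherms import IsothermParams, evaluate_isotherm
from .kinetics import KineticParams, KineticSeries, evaluate_kinetic
from .preprocessing import SALTS, celsius_to_kelvin, salt_rh
from .thermo import GAS_CONSTANT, ThermoPoint

__all__ = [
    "StudyConfig",
    "default_isotherm_truth",
    "default_kinetic_truth",
    "simulate_isotherm_study",
    "simulate_kinetics",
    "simulate_compensation_series",
]


def default_isotherm_truth() -> dict[float, IsothermParams]:
    """Per-temperature ground-truth isotherms for demos and tests.

    Smith at 25 and 37 degC uses published fit values; the 32 degC GAB
    keeps the published k and c but a docs-scale x0 = 4.0 so all three
    curves live on the same EMC scale.
    """
    return {
        25.0: IsothermParams("Smith", {"a": -8.05, "b": -17.01}),
        32.0: IsothermParams("GAB", {"k": 0.89, "c": 13.17, "x0": 4.0}),
        37.0: IsothermParams("Smith", {"a": -2.63, "b": -7.98}),
    }


def default_kinetic_truth() -> dict[float, KineticParams]:
    """First-order uptake truth at 68% RH per temperature (a in Mgr %, b in 1/h)."""
    return {
        25.0: KineticParams("first_order", {"a": 8.48, "b": 2.05}),
        32.0: KineticParams("first_order", {"a": 7.95, "b": 1.84}),
        37.0: KineticParams("first_order", {"a": 7.13, "b": 2.40}),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Design and noise model of one synthetic study.

    ``noise_sd_emc``/``noise_sd_mgr`` are Gaussian sds in % units applied
    per weighing; with ``heteroscedastic=True`` the sd is instead
    ``noise_sd * |true value|`` (relative error).  ``seed`` is mandatory:
    the whole study is reproducible from it.
    """

    seed: int
    temperatures_c: tuple[float, ...] = (25.0, 32.0, 37.0)
    salts: tuple[str, ...] = SALTS
    isotherm_truth: Mapping[float, IsothermParams] = field(
        default_factory=default_isotherm_truth
    )
    kinetic_truth: Mapping[float, KineticParams] = field(
        default_factory=default_kinetic_truth
    )
    kinetic_rh_percent: float = 68.0
    noise_sd_emc: float = 0.0
    noise_sd_mgr: float = 0.0
    replicate_count: int = 1
    heteroscedastic: bool = False
    initial_aw: Mapping[float, float] = field(
        default_factory=lambda: {25.0: 0.3838, 32.0: 0.3874, 37.0: 0.4156}
    )

    def __post_init__(self):
        if self.noise_sd_emc < 0 or self.noise_sd_mgr < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is mandatory and must be an integer")
        object.__setattr__(self, "temperatures_c", tuple(self.temperatures_c))
        object.__setattr__(self, "salts", tuple(self.salts))
        object.__setattr__(self, "isotherm_truth", dict(self.isotherm_truth))
        object.__setattr__(self, "kinetic_truth", dict(self.kinetic_truth))
        object.__setattr__(self, "initial_aw", dict(self.initial_aw))


def _noisy_mean(rng, truth: np.ndarray, sd: float, replicates: int, hetero: bool):
    if sd == 0.0:
        return truth.copy()
    scale = sd * np.abs(truth) if hetero else np.full_like(truth, sd)
    draws = truth[None, :] + rng.normal(0.0, 1.0, size=(replicates, truth.size)) * scale
    return draws.mean(axis=0)


def simulate_isotherm_study(cfg: StudyConfig) -> list[SorptionDataset]:
    """One :class:`SorptionDataset` per temperature.

    Water activities are the tabulated salt RH / 100 at that temperature;
    each EMC point is the mean of ``replicate_count`` noisy weighings of
    the true isotherm value.  A truth model undefined at any generated aw
    raises :class:`DomainError` (configuration error).
    """
    rng = np.random.default_rng(cfg.seed)
    datasets = []
    for t_c in cfg.temperatures_c:
        if t_c not in cfg.isotherm_truth:
            raise ValidationError(f"no isotherm truth configured for {t_c} degC")
        truth = cfg.isotherm_truth[t_c]
        aw = np.array([salt_rh(s, t_c) / 100.0 for s in cfg.salts])
        try:
            emc_true = np.array([evaluate_isotherm(truth, float(a)) for a in aw])
        except DomainError as exc:
            raise DomainError(
                f"isotherm truth at {t_c} degC undefined at a generated aw: {exc}"
            ) from exc
        emc = _noisy_mean(rng, emc_true, cfg.noise_sd_emc, cfg.replicate_count,
                          cfg.heteroscedastic)
        datasets.append(
            SorptionDataset(
                temperature_k=celsius_to_kelvin(t_c),
                points=tuple(zip(aw.tolist(), emc.tolist())),
                initial_aw=cfg.initial_aw.get(t_c),
                label=f"synthetic isotherm {t_c:g} degC (seed={cfg.seed})",
            )
        )
    return datasets


def simulate_kinetics(
    cfg: StudyConfig, times_h: Sequence[float] | None = None
) -> list[KineticSeries]:
    """One :class:`KineticSeries` per configured temperature at the study's
    kinetic RH; default sampling is every 0.5 h from 0.5 to 6 h."""
    if times_h is None:
        times_h = np.arange(0.5, 6.0 + 1e-9, 0.5)
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the isotherm stream
    series = []
    for t_c in cfg.temperatures_c:
        if t_c not in cfg.kinetic_truth:
            raise ValidationError(f"no kinetic truth configured for {t_c} degC")
        truth = cfg.kinetic_truth[t_c]
        mgr_true = np.asarray(evaluate_kinetic(truth, t), dtype=float)
        mgr = _noisy_mean(rng, mgr_true, cfg.noise_sd_mgr, cfg.replicate_count,
                          cfg.heteroscedastic)
        series.append(
            KineticSeries(
                condition=(celsius_to_kelvin(t_c), cfg.kinetic_rh_percent),
                points=tuple(zip(t.tolist(), mgr.tolist())),
                label=f"synthetic kinetics {t_c:g} degC / "
                      f"{cfg.kinetic_rh_percent:g}% RH (seed={cfg.seed})",
            )
        )
    return series


def simulate_compensation_series(
    t_beta: float,
    dG_beta: float,
    dS_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    temperatures_k: Sequence[float] = (298.15, 305.15, 310.15),
) -> list[ThermoPoint]:
    """Thermo points lying (up to noise) on a compensation line.

    Each point gets qst = t_beta*dS + dG_beta + Gaussian(0, noise_sd); its
    per-temperature water activities are reconstructed from the
    Clausius-Clapeyron identity aw(T) = exp(-qst/(R T) + dS/R) so the
    points are internally consistent; under extreme noise the
    reconstruction is clamped into (0, 1) (the qst/dS pair stays
    authoritative — the compensation fit never reads aw).
    """
    if len(dS_grid) == 0:
        raise ValidationError("dS_grid must be non-empty")
    rng = np.random.default_rng(seed)
    points = []
    for i, ds in enumerate(dS_grid):
        qst = t_beta * ds + dG_beta
        if noise_sd > 0:
            qst += rng.normal(0.0, noise_sd)
        aw_by_t = {
            float(T): float(
                np.clip(
                    np.exp(-qst / (GAS_CONSTANT * T) + ds / GAS_CONSTANT),
                    1e-12,
                    1.0 - 1e-12,
                )
            )
            for T in temperatures_k
        }
        points.append(
            ThermoPoint(
                emc_percent=float(i),  # placeholder index; no isotherm behind it
                qst=float(qst),
                dS=float(ds),
                per_temperature_aw=aw_by_t,
                fit_r2=1.0,
            )
        )
    return points
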