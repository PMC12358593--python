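"""End-to-end analysis pipeline and its JSON report.

Stages, in order: fit all five isotherm models per temperature and select
the best by R²/RSS; fit all four kinetic models per storage condition and
select likewise; invert the selected isotherms over an EMC grid for the
Clausius-Clapeyron isosteric analysis; fit the enthalpy-entropy
compensation line and classify the driving force against the
harmonic-mean temperature; tabulate Gibbs-energy and spreading-pressure
curves (the latter always from GAB constants — a GAB fit is performed at
every temperature regardless of which model was selected).  With fewer
than two temperatures the thermodynamic stage is skipped with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._version import __version__
from .exceptions import CapsorbError, ValidationError
from .fitting import FitResult, SorptionDataset, fit_all_models, select_best
from .isotherms import IsothermParams, evaluate_isotherm
from .kinetics import KineticSeries
from .synthetic import StudyConfig, simulate_isotherm_study, simulate_kinetics
from .thermo import (
    CompensationFit,
    ThermoPoint,
    compensation_fit,
    default_emc_grid,
    gibbs_free_energy,
    isosteric_analysis,
    spreading_pressure,
)

logger = logging.getLogger("capsorb")

__all__ = ["AnalysisReport", "run_pipeline", "run_synthetic_study"]


@dataclass(frozen=True)
class AnalysisReport:
    """Full pipeline output; serialises to/from a plain JSON dict."""

    isotherm_fits: Mapping[str, Mapping[str, FitResult]]  # temp label -> model -> fit
    selected_isotherms: Mapping[str, str]
    kinetic_fits: Mapping[str, Mapping[str, FitResult]]  # condition label -> model -> fit
    selected_kinetics: Mapping[str, str]
    thermo_points: tuple[ThermoPoint, ...] | None
    compensation: CompensationFit | None
    gibbs_curves: Mapping[str, Sequence[Mapping[str, float]]]
    spreading_pressure_curves: Mapping[str, Sequence[Mapping[str, float]]]
    provenance: Mapping[str, object]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "isotherm_fits": {
                t: {m: f.to_dict() for m, f in fits.items()}
                for t, fits in self.isotherm_fits.items()
            },
            "selected_isotherms": dict(self.selected_isotherms),
            "kinetic_fits": {
                c: {m: f.to_dict() for m, f in fits.items()}
                for c, fits in self.kinetic_fits.items()
            },
            "selected_kinetics": dict(self.selected_kinetics),
            "thermo_points": [p.to_dict() for p in self.thermo_points]
            if self.thermo_points is not None
            else None,
            "compensation": self.compensation.to_dict() if self.compensation else None,
            "gibbs_curves": {t: list(c) for t, c in self.gibbs_curves.items()},
            "spreading_pressure_curves": {
                t: list(c) for t, c in self.spreading_pressure_curves.items()
            },
            "provenance": dict(self.provenance),
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _temp_label(t_k: float) -> str:
    return f"{t_k:.2f}K"


def run_pipeline(
    sorption: Sequence[SorptionDataset],
    kinetics: Sequence[KineticSeries] = (),
    *,
    seed: int = 0,
    n_starts: int = 16,
    emc_grid_n: int = 20,
    aw_lo: float = 0.43,
    aw_hi: float = 0.92,
    curve_points: int = 25,
    compensation_tolerance_k: float = 1.0,
) -> AnalysisReport:
    """Run the full analysis on sorption datasets and kinetic series.

    ``aw_lo``/``aw_hi`` bound both the EMC grid used for the isosteric
    analysis and the reported Gibbs / spreading-pressure curves;
    ``emc_grid_n`` sets the grid resolution.  ``seed`` drives the fitting
    multi-starts only — the pipeline is deterministic given its inputs.
    """
    if not sorption:
        raise ValidationError("pipeline needs at least one sorption dataset")
    warnings: list[str] = []

    isotherm_fits: dict[str, dict[str, FitResult]] = {}
    selected: dict[str, str] = {}
    best_params: dict[float, IsothermParams] = {}
    gab_params: dict[float, IsothermParams] = {}
    for ds in sorption:
        label = _temp_label(ds.temperature_k)
        logger.info("fitting isotherm models at %s (seed=%d)", label, seed)
        fits = fit_all_models(ds, seed=seed, n_starts=n_starts)
        isotherm_fits[label] = {f.model_name: f for f in fits}
        best = select_best(fits)
        selected[label] = best
        best_params[ds.temperature_k] = IsothermParams(
            best, isotherm_fits[label][best].params
        )
        gab_params[ds.temperature_k] = IsothermParams(
            "GAB", isotherm_fits[label]["GAB"].params
        )

    kinetic_fits: dict[str, dict[str, FitResult]] = {}
    selected_kin: dict[str, str] = {}
    for series in kinetics:
        t_k, rh = series.condition
        label = f"{_temp_label(t_k)}/{rh:g}%RH"
        logger.info("fitting kinetic models at %s (seed=%d)", label, seed)
        fits = fit_all_models(series, seed=seed, n_starts=n_starts)
        kinetic_fits[label] = {f.model_name: f for f in fits}
        selected_kin[label] = select_best(fits)

    thermo_points = None
    comp = None
    if len(best_params) >= 2:
        grid = default_emc_grid(best_params, n=emc_grid_n, aw_lo=aw_lo, aw_hi=aw_hi)
        thermo_points = tuple(isosteric_analysis(best_params, grid))
        temps = sorted(best_params)
        try:
            comp = compensation_fit(
                thermo_points, temps, tolerance_k=compensation_tolerance_k
            )
        except CapsorbError as exc:  # degenerate grids stay reportable
            warnings.append(f"compensation fit failed: {exc}")
            comp = None
    else:
        warnings.append(
            "thermodynamic stage skipped: need >= 2 temperatures, "
            f"got {len(best_params)}"
        )
        logger.warning(warnings[-1])

    aw_grid = np.linspace(aw_lo, aw_hi, curve_points)
    gibbs_curves = {
        _temp_label(t): [
            {
                "aw": float(a),
                "dG_j_per_mol": gibbs_free_energy(t, float(a)),
                "emc_percent": float(evaluate_isotherm(best_params[t], float(a)))
                if a < best_params[t].aw_upper()
                else None,
            }
            for a in aw_grid
        ]
        for t in best_params
    }
    phi_curves = {}
    for t, gp in gab_params.items():
        hi = min(aw_hi, gp.aw_upper())
        phi_curves[_temp_label(t)] = [
            {"aw": float(a), "phi_j_per_m2": spreading_pressure(gp, t, float(a))}
            for a in np.linspace(0.0, hi, curve_points)
        ]

    options = {
        "seed": seed,
        "n_starts": n_starts,
        "emc_grid_n": emc_grid_n,
        "aw_lo": aw_lo,
        "aw_hi": aw_hi,
        "curve_points": curve_points,
        "compensation_tolerance_k": compensation_tolerance_k,
    }
    provenance = {
        "version": __version__,
        "seed": seed,
        "options": options,
        "config_hash": hashlib.sha256(
            json.dumps(options, sort_keys=True).encode()
        ).hexdigest(),
        "n_sorption_datasets": len(sorption),
        "n_kinetic_series": len(kinetics),
    }
    return AnalysisReport(
        isotherm_fits=isotherm_fits,
        selected_isotherms=selected,
        kinetic_fits=kinetic_fits,
        selected_kinetics=selected_kin,
        thermo_points=thermo_points,
        compensation=comp,
        gibbs_curves=gibbs_curves,
        spreading_pressure_curves=phi_curves,
        provenance=provenance,
        warnings=tuple(warnings),
    )


def run_synthetic_study(cfg: StudyConfig, **pipeline_options) -> AnalysisReport:
    """Simulate a study from ``cfg`` and push it through the pipeline."""
    sorption = simulate_isotherm_study(cfg)
    kinetics = simulate_kinetics(cfg)
    pipeline_options.setdefault("seed", cfg.seed)
    return run_pipeline(sorption, kinetics, **pipeline_options)
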