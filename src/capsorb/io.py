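"""CSV / YAML input-output.

Schemas (all plain CSV, ``#``-prefixed header lines carry metadata):

* sorption:  columns ``temperature_c``, ``aw`` **or** ``rh_percent``
  (mutually exclusive), ``emc_percent``; one row per equilibrium point,
  grouped into one :class:`SorptionDataset` per temperature.
* kinetics:  columns ``temperature_c``, ``rh_percent``, ``time_h``,
  ``mgr_percent``; grouped per (temperature, RH) condition.
* masses:    columns ``time_h``, ``mass_g`` with ``# mfs:``,
  ``# temperature_c:``, ``# rh_percent:`` metadata; the first row is the
  dry baseline and later rows are converted to Mgr % against it.
* config:    YAML mirroring :class:`~capsorb.synthetic.StudyConfig`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .exceptions import ValidationError
from .fitting import SorptionDataset
from .isotherms import IsothermParams
from .kinetics import KineticParams, KineticSeries
from .preprocessing import MassRecord, celsius_to_kelvin, compute_mgr
from .synthetic import StudyConfig

__all__ = [
    "read_sorption_csv",
    "write_sorption_csv",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_mass_series_csv",
    "load_study_config",
]


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    """CSV with optional leading '# key: value' metadata lines."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                k, v = line.lstrip("#").split(":", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    return df, meta


def read_sorption_csv(path) -> list[SorptionDataset]:
    """Parse a sorption CSV into per-temperature datasets.

    ``rh_percent`` values are converted to water activity by /100.  Parse
    failures (missing columns, aw out of [0,1), duplicate (T, aw)) report
    the offending data row number.
    """
    df, meta = _read_csv(path)
    if "temperature_c" not in df.columns or "emc_percent" not in df.columns:
        raise ValidationError(
            f"{path}: need columns temperature_c and emc_percent, got {list(df.columns)}"
        )
    has_aw, has_rh = "aw" in df.columns, "rh_percent" in df.columns
    if has_aw == has_rh:
        raise ValidationError(
            f"{path}: exactly one of 'aw' or 'rh_percent' must be present"
        )
    aw = df["aw"] if has_aw else df["rh_percent"] / 100.0
    for i, a in enumerate(aw):
        if not 0.0 <= a < 1.0:
            raise ValidationError(f"{path}: row {i + 1}: aw={a} outside [0, 1)")
    seen = set()
    for i, key in enumerate(zip(df["temperature_c"], aw)):
        if key in seen:
            raise ValidationError(
                f"{path}: row {i + 1}: duplicate point (T={key[0]}, aw={key[1]})"
            )
        seen.add(key)
    datasets = []
    work = df.assign(_aw=aw)
    for t_c, grp in work.groupby("temperature_c", sort=True):
        datasets.append(
            SorptionDataset(
                temperature_k=celsius_to_kelvin(float(t_c)),
                points=tuple(zip(grp["_aw"].tolist(), grp["emc_percent"].tolist())),
                initial_aw=float(meta["initial_aw"]) if "initial_aw" in meta else None,
                label=meta.get("label", f"{Path(path).name} @ {t_c:g} degC"),
            )
        )
    return datasets


def write_sorption_csv(datasets: Sequence[SorptionDataset], path) -> None:
    rows = []
    for ds in datasets:
        t_c = ds.temperature_k - 273.15
        for aw, emc in ds.points:
            rows.append({"temperature_c": t_c, "aw": aw, "emc_percent": emc})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kinetics_csv(path) -> list[KineticSeries]:
    """Parse a kinetics CSV into one series per (temperature, RH) condition."""
    df, meta = _read_csv(path)
    required = {"temperature_c", "rh_percent", "time_h", "mgr_percent"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    series = []
    for (t_c, rh), grp in df.groupby(["temperature_c", "rh_percent"], sort=True):
        grp = grp.sort_values("time_h")
        series.append(
            KineticSeries(
                condition=(celsius_to_kelvin(float(t_c)), float(rh)),
                points=tuple(zip(grp["time_h"].tolist(), grp["mgr_percent"].tolist())),
                label=meta.get("label", f"{Path(path).name} @ {t_c:g} degC/{rh:g}%RH"),
            )
        )
    return series


def write_kinetics_csv(series: Sequence[KineticSeries], path) -> None:
    rows = []
    for s in series:
        t_k, rh = s.condition
        for t, y in s.points:
            rows.append(
                {
                    "temperature_c": t_k - 273.15,
                    "rh_percent": rh,
                    "time_h": t,
                    "mgr_percent": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mass_series_csv(path) -> KineticSeries:
    """Raw gravimetric series -> Mgr series.

    Needs ``time_h`` and ``mass_g`` columns plus ``# mfs:`` (skin mass
    fraction) metadata; ``# temperature_c:`` and ``# rh_percent:`` default
    to 25 and 68.  The first row is the pre-uptake baseline mass m0.
    """
    df, meta = _read_csv(path)
    if not {"time_h", "mass_g"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns time_h and mass_g")
    if "mfs" not in meta:
        raise ValidationError(f"{path}: '# mfs: <fraction>' metadata line is required")
    mfs = float(meta["mfs"])
    df = df.sort_values("time_h")
    m0 = float(df["mass_g"].iloc[0])
    points = [
        (float(t), compute_mgr(MassRecord(w0=m0, w1=float(m), mfs=mfs)))
        for t, m in zip(df["time_h"], df["mass_g"])
    ]
    return KineticSeries(
        condition=(
            celsius_to_kelvin(float(meta.get("temperature_c", 25.0))),
            float(meta.get("rh_percent", 68.0)),
        ),
        points=tuple(points),
        label=meta.get("label", Path(path).name),
    )


def _params_from_yaml(block: Mapping, cls) -> dict:
    out = {}
    for temp, spec in block.items():
        out[float(temp)] = cls(spec["model"], dict(spec["params"]))
    return out


def load_study_config(path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file.

    Recognised keys mirror the dataclass fields; ``isotherm_truth`` and
    ``kinetic_truth`` are nested ``{temperature_c: {model: name,
    params: {...}}}`` maps and fall back to the package defaults when
    omitted.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in raw:
        raise ValidationError(f"{path}: config must set a seed")
    kwargs: dict = {"seed": int(raw["seed"])}
    for key in (
        "temperatures_c",
        "salts",
        "kinetic_rh_percent",
        "noise_sd_emc",
        "noise_sd_mgr",
        "replicate_count",
        "heteroscedastic",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "isotherm_truth" in raw:
        kwargs["isotherm_truth"] = _params_from_yaml(raw["isotherm_truth"], IsothermParams)
    if "kinetic_truth" in raw:
        kwargs["kinetic_truth"] = _params_from_yaml(raw["kinetic_truth"], KineticParams)
    if "initial_aw" in raw:
        kwargs["initial_aw"] = {float(k): float(v) for k, v in raw["initial_aw"].items()}
    return StudyConfig(**kwargs)
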