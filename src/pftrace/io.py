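"""CSV/JSON readers and writers and run configuration.

Interchange formats: CSV tables with an explicit ``unit`` column (surveys
have no domain-standard file format, and unit-tagged CSV is inspectable by
the survey technicians who collect the data); JSON for results, with
explicit units on every field.  All unit conversion happens here — the
rest of the package works in fixed internal units (flows m³/h,
concentrations µg/m³, dosing rates µg/h).

Schemas
-------
zones.csv          zone,label,area_m2,height_m   (or a volume_m3 column)
concentrations.csv tracer,zone,value,unit        (unit: ug/m3 or mg/m3)
dosers.csv         tracer,zone,dosing_rate,unit[,n_dosers]  (mg/h or ug/h;
                   multiple rows per tracer are summed as separate dosers)
calibration.csv    tracer,recovery,recovery_sd,sampling_rate,sr_sd,lod,loq
                   [,extract_volume]
gravimetry.csv     time_h,weight_mg[,temp_c]
decay.csv          time_h,co2_ppm
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationSet, GravimetrySeries
from .decay import DecaySeries
from .inversion import FlowEstimate, SurveyMeasurement, flow_index
from .model import ConcentrationMatrix, FlowMatrix, TracerSpec, ZoneSystem

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_zones",
    "read_survey_tables",
    "read_calibration_table",
    "read_gravimetry",
    "read_decay",
    "write_survey_tables",
    "estimate_to_dict",
    "write_estimate_json",
    "read_estimate_json",
    "get_logger",
]

logger = logging.getLogger("pftrace")

_CONC_UNITS = {"ug/m3": 1.0, "µg/m³": 1.0, "ug/m^3": 1.0, "mg/m3": 1000.0}
_DOSE_UNITS = {"mg/h": 1000.0, "ug/h": 1.0, "µg/h": 1.0}  # → µg/h


class SchemaError(ValueError):
    """An input table violates its documented schema."""


def get_logger(verbosity: int = 0) -> logging.Logger:
    """Package logger writing structured lines to stderr."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbosity > 0 else logging.INFO)
    return logger


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for one CLI run (logged in full)."""

    method: str = "nnls"
    weighting: str = "raw"
    extract_volume: float = 1.0
    background_ppm: float = 400.0
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 0


def _require_columns(df: pd.DataFrame, cols: set[str], path: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_zones(path: str | Path) -> ZoneSystem:
    """Zone table → ZoneSystem; volume from volume_m3 or area_m2 × height_m."""
    df = _read_csv(path)
    _require_columns(df, {"zone"}, str(path))
    df = df.sort_values("zone")
    zones = df["zone"].to_numpy()
    if not np.array_equal(zones, np.arange(1, len(df) + 1)):
        raise SchemaError(f"{path}: 'zone' must be 1..n without gaps, got {zones}")
    if "volume_m3" in df.columns:
        vols = df["volume_m3"].to_numpy(float)
    elif {"area_m2", "height_m"} <= set(df.columns):
        vols = df["area_m2"].to_numpy(float) * df["height_m"].to_numpy(float)
    else:
        raise SchemaError(f"{path}: need volume_m3 or area_m2+height_m columns")
    labels = (
        tuple(df["label"].astype(str)) if "label" in df.columns else None
    )
    return ZoneSystem(volumes=vols, labels=labels)


def read_survey_tables(
    concentrations_csv: str | Path,
    dosers_csv: str | Path,
    zones_csv: str | Path,
    day_label: str = "day1",
) -> SurveyMeasurement:
    """Assemble a validated SurveyMeasurement from the three input tables.

    Dosing rates are converted to µg/h and summed over a room's dosers;
    duplicate (tracer, zone) concentration rows and missing cells are
    schema errors naming the offending row/column.
    """
    zones = read_zones(zones_csv)
    n = zones.n_zones

    cdf = _read_csv(concentrations_csv)
    _require_columns(cdf, {"tracer", "zone", "value", "unit"}, str(concentrations_csv))
    dup = cdf.duplicated(subset=["tracer", "zone"], keep=False)
    if dup.any():
        first = cdf[dup].iloc[0]
        raise SchemaError(
            f"{concentrations_csv}: duplicate (tracer, zone) row: "
            f"({first['tracer']}, {first['zone']})"
        )
    for row_i, unit in cdf["unit"].items():
        if str(unit).strip() not in _CONC_UNITS:
            raise SchemaError(
                f"{concentrations_csv}: row {row_i}: unknown concentration "
                f"unit {unit!r} (column 'unit')"
            )

    ddf = _read_csv(dosers_csv)
    _require_columns(ddf, {"tracer", "zone", "dosing_rate", "unit"}, str(dosers_csv))
    for row_i, unit in ddf["unit"].items():
        if str(unit).strip() not in _DOSE_UNITS:
            raise SchemaError(
                f"{dosers_csv}: row {row_i}: unknown dosing-rate unit {unit!r} "
                f"(column 'unit')"
            )
    ddf = ddf.assign(
        rate_ug_h=ddf["dosing_rate"].astype(float)
        * ddf["unit"].map(lambda u: _DOSE_UNITS[str(u).strip()]),
        n_dosers=ddf["n_dosers"].astype(int) if "n_dosers" in ddf.columns else 1,
    )
    grouped = ddf.groupby("tracer", sort=False).agg(
        zone=("zone", "first"),
        total_rate=("rate_ug_h", lambda r: float(np.sum(r * ddf.loc[r.index, "n_dosers"]))),
        n_dosers=("n_dosers", "sum"),
    )
    if ddf.groupby("tracer")["zone"].nunique().max() > 1:
        raise SchemaError(f"{dosers_csv}: a tracer appears in more than one zone")

    tracer_ids = list(grouped.index)
    tracers = tuple(
        TracerSpec(
            tracer_id=str(tid),
            source_zone=int(grouped.loc[tid, "zone"]),
            dosing_rate=float(grouped.loc[tid, "total_rate"]),
            n_dosers=int(grouped.loc[tid, "n_dosers"]),
        )
        for tid in tracer_ids
    )

    C = np.full((len(tracer_ids), n), np.nan)
    for _, row in cdf.iterrows():
        tid = str(row["tracer"])
        if tid not in tracer_ids:
            raise SchemaError(
                f"{concentrations_csv}: tracer {tid!r} has no doser row"
            )
        z = int(row["zone"])
        if not 1 <= z <= n:
            raise SchemaError(f"{concentrations_csv}: zone {z} out of range 1..{n}")
        C[tracer_ids.index(tid), z - 1] = (
            float(row["value"]) * _CONC_UNITS[str(row["unit"]).strip()]
        )
    if np.isnan(C).any():
        t_i, z_i = np.argwhere(np.isnan(C))[0]
        raise SchemaError(
            f"{concentrations_csv}: missing concentration for tracer "
            f"{tracer_ids[t_i]!r}, zone {z_i + 1}"
        )

    return SurveyMeasurement(
        concentrations=ConcentrationMatrix(C=C, tracer_ids=tuple(tracer_ids)),
        tracers=tracers,
        zones=zones,
        day_label=day_label,
    )


def read_calibration_table(path: str | Path) -> dict[str, CalibrationSet]:
    df = _read_csv(path)
    _require_columns(
        df, {"tracer", "recovery", "sampling_rate", "lod", "loq"}, str(path)
    )
    out = {}
    for _, row in df.iterrows():
        out[str(row["tracer"])] = CalibrationSet(
            tracer_id=str(row["tracer"]),
            recovery=float(row["recovery"]),
            recovery_sd=float(row.get("recovery_sd", 0.0) or 0.0),
            sampling_rate=float(row["sampling_rate"]),
            sampling_rate_sd=float(row.get("sr_sd", 0.0) or 0.0),
            analytical_lod=float(row["lod"]),
            analytical_loq=float(row["loq"]),
            extract_volume=float(row.get("extract_volume", 1.0) or 1.0),
        )
    return out


def read_gravimetry(path: str | Path) -> GravimetrySeries:
    df = _read_csv(path)
    _require_columns(df, {"time_h", "weight_mg"}, str(path))
    temp = float(df["temp_c"].iloc[0]) if "temp_c" in df.columns else None
    return GravimetrySeries(
        times=df["time_h"].to_numpy(float),
        weights=df["weight_mg"].to_numpy(float),
        temperature=temp,
    )


def read_decay(path: str | Path, background_ppm: float) -> DecaySeries:
    df = _read_csv(path)
    _require_columns(df, {"time_h", "co2_ppm"}, str(path))
    return DecaySeries(
        times=df["time_h"].to_numpy(float),
        concentrations=df["co2_ppm"].to_numpy(float),
        background=background_ppm,
    )


def write_survey_tables(
    measurement: SurveyMeasurement, out_dir: str | Path
) -> dict[str, Path]:
    """Write zones/concentrations/dosers CSVs in the schemas this module reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    zones_path = out / "zones.csv"
    pd.DataFrame(
        {
            "zone": np.arange(1, measurement.zones.n_zones + 1),
            "label": list(measurement.zones.labels),
            "volume_m3": measurement.zones.volumes,
        }
    ).to_csv(zones_path, index=False)

    rows = []
    for t, tid in enumerate(measurement.concentrations.tracer_ids):
        for z in range(measurement.zones.n_zones):
            rows.append(
                {
                    "tracer": tid,
                    "zone": z + 1,
                    "value": measurement.concentrations.C[t, z],
                    "unit": "ug/m3",
                }
            )
    conc_path = out / "concentrations.csv"
    pd.DataFrame(rows).to_csv(conc_path, index=False)

    dosers_path = out / "dosers.csv"
    pd.DataFrame(
        [
            {
                "tracer": t.tracer_id,
                "zone": t.source_zone,
                "dosing_rate": t.dosing_rate / t.n_dosers / 1000.0,  # per doser, mg/h
                "unit": "mg/h",
                "n_dosers": t.n_dosers,
            }
            for t in measurement.tracers
        ]
    ).to_csv(dosers_path, index=False)
    return {"zones": zones_path, "concentrations": conc_path, "dosers": dosers_path}


def estimate_to_dict(estimate: FlowEstimate, zones: ZoneSystem | None = None) -> dict:
    """JSON-ready dict with explicit units on every field."""
    n = estimate.flows.n_zones
    return {
        "n_zones": n,
        "day_label": estimate.day_label,
        "flows": {
            f"Q{i}{j}": estimate.flows.Q[i, j] for i, j in flow_index(n)
        },
        "flows_unit": "m3/h",
        "objective": estimate.objective,
        "per_room_outdoor_ach": list(estimate.per_room_outdoor_ach),
        "per_room_interroom_ach": list(estimate.per_room_interroom_ach),
        "ach_unit": "1/h",
        "zone_volumes_m3": list(zones.volumes) if zones is not None else None,
        "solver_info": estimate.solver_info,
    }


def write_estimate_json(
    estimate: FlowEstimate, path: str | Path, zones: ZoneSystem | None = None
) -> None:
    Path(path).write_text(
        json.dumps(estimate_to_dict(estimate, zones), indent=2, default=float)
    )


def read_estimate_json(path: str | Path) -> FlowEstimate:
    """Reconstruct a FlowEstimate from its JSON serialization (round trip)."""
    data = json.loads(Path(path).read_text())
    n = int(data["n_zones"])
    Q = np.zeros((n + 1, n + 1))
    for i, j in flow_index(n):
        Q[i, j] = float(data["flows"][f"Q{i}{j}"])
    return FlowEstimate(
        flows=FlowMatrix(Q=Q),
        objective=float(data["objective"]),
        per_room_outdoor_ach=np.array(data["per_room_outdoor_ach"], dtype=float),
        per_room_interroom_ach=np.array(data["per_room_interroom_ach"], dtype=float),
        solver_info=dict(data["solver_info"]),
        day_label=str(data["day_label"]),
    )
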