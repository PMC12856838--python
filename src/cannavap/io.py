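"""Delimited-table input/output for measurements, compounds, and results.

Measurement tables are CSV, one row per saturation run.  Carrier gas may
be given as mass (``he_mass_g``) or standard volume (``he_volume_scc``);
trapped analyte as mass (``m2_g``) or as GC peak areas
(``analyte_area``, ``is_area``, ``is_mass_g``) quantitated through a
per-analyte internal-standard calibration line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .saturation import (
    HELIUM,
    CalibrationLine,
    CarrierGasSpec,
    ChromatogramPeakSet,
    CompoundSpec,
    MeasurementRecord,
    VaporPressurePoint,
    carrier_mass_from_standard_volume,
    mass_from_internal_standard,
)

__all__ = [
    "read_measurements",
    "write_measurements",
    "measurements_to_frame",
    "read_compounds",
    "points_to_frame",
    "write_vapor_pressures",
]

MEASUREMENT_COLUMNS = [
    "compound",
    "series_id",
    "T_K",
    "he_mass_g",
    "m2_g",
    "p_ambient_Pa",
    "p_overpressure_Pa",
    "flow_sccm",
    "duration_min",
]


def _row_trapped_mass(row: pd.Series, calibrations) -> float:
    if "m2_g" in row.index and pd.notna(row.get("m2_g")):
        return float(row["m2_g"])
    if calibrations is None:
        raise ValueError(
            "row has no m2_g and no calibration lines were provided for "
            "area-based quantitation"
        )
    cal = calibrations[str(row["compound"])]
    peaks = ChromatogramPeakSet(
        analyte_area=float(row["analyte_area"]),
        internal_standard_area=float(row["is_area"]),
        internal_standard_mass=float(row["is_mass_g"]),
    )
    return mass_from_internal_standard(peaks, cal)


def _row_carrier_mass(row: pd.Series, gas: CarrierGasSpec) -> float:
    if "he_mass_g" in row.index and pd.notna(row.get("he_mass_g")):
        return float(row["he_mass_g"])
    if "he_volume_scc" in row.index and pd.notna(row.get("he_volume_scc")):
        return carrier_mass_from_standard_volume(float(row["he_volume_scc"]), gas=gas)
    raise ValueError("row needs he_mass_g or he_volume_scc")


def read_measurements(
    path: str | Path,
    calibrations: Optional[Mapping[str, CalibrationLine]] = None,
    gas: CarrierGasSpec = HELIUM,
) -> list[MeasurementRecord]:
    """Read a measurement CSV into validated records."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return []
    records = []
    for _, row in df.iterrows():
        records.append(
            MeasurementRecord(
                compound=str(row["compound"]),
                temperature=float(row["T_K"]),
                carrier_mass=_row_carrier_mass(row, gas),
                trapped_mass=_row_trapped_mass(row, calibrations),
                p_ambient=float(row["p_ambient_Pa"]),
                p_overpressure=float(row.get("p_overpressure_Pa", 0.0) or 0.0),
                series_id=str(row.get("series_id", "")),
                flow_rate=float(row["flow_sccm"]) if pd.notna(row.get("flow_sccm")) else None,
                duration=float(row["duration_min"]) if pd.notna(row.get("duration_min")) else None,
            )
        )
    return records


def measurements_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Records to the canonical CSV schema (mass-based columns)."""
    return pd.DataFrame(
        [
            {
                "compound": r.compound,
                "series_id": r.series_id,
                "T_K": r.temperature,
                "he_mass_g": r.carrier_mass,
                "m2_g": r.trapped_mass,
                "p_ambient_Pa": r.p_ambient,
                "p_overpressure_Pa": r.p_overpressure,
                "flow_sccm": r.flow_rate,
                "duration_min": r.duration,
            }
            for r in records
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    # %.17g keeps float round-trips lossless through the CSV boundary
    measurements_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_compounds(path: str | Path) -> dict[str, CompoundSpec]:
    """Read a compound registry (CSV or JSON).

    Columns/keys: ``name, molar_mass, cp_gas_298, purity_area_pct, smiles``.
    The GC area-percent purity is mapped directly to the condensed-phase
    mole fraction x2 (equal-response-factor approximation).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    out: dict[str, CompoundSpec] = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        out[name] = CompoundSpec(
            name=name,
            molar_mass=float(row["molar_mass"]),
            cp_gas=float(row["cp_gas_298"]) if pd.notna(row.get("cp_gas_298")) else None,
            purity_mole_fraction=float(row["purity_area_pct"]) / 100.0,
            smiles=str(row["smiles"]) if pd.notna(row.get("smiles")) else None,
        )
    return out


def points_to_frame(points: Iterable[VaporPressurePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": q.compound,
                "series_id": q.series_id,
                "T_K": q.temperature,
                "p_sat_Pa": q.p_sat,
                "u_c_Pa": q.u_c if q.u_c is not None else np.nan,
            }
            for q in points
        ],
        columns=["compound", "series_id", "T_K", "p_sat_Pa", "u_c_Pa"],
    )


def write_vapor_pressures(points: Iterable[VaporPressurePoint], path: str | Path) -> None:
    points_to_frame(points).to_csv(path, index=False, float_format="%.17g")
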