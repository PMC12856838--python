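"""End-to-end orchestration: raw measurements to partitioning predictions.

Stages, per compound found in the measurement table:

1. Eqs-of-measurement conversion of each run to a vapor-pressure point.
2. Clarke-Glew fit (heat-capacity change fixed from the Chickos estimate
   of the compound's ideal-gas heat capacity), excluding points at or
   below the low-pressure threshold.
3. First-order uncertainty budgets per point, with the temperature
   sensitivity dlnp/dT taken from the fitted correlation -- the fit itself
   is unweighted, so uncertainties are reporting-only and no second fit
   pass is needed.
4. Extrapolation of the correlation to the requested temperatures
   (breath 307.15 K and body 310.15 K by default), flagged when outside
   the fitted span.
5. Enthalpies of vaporization at requested temperatures.
6. Vapor-aerosol partitioning (C*, F_OA, volatility class) per scenario.

One compound's fit failure degrades the batch run (recorded in the
report) without aborting the other compounds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .clarke_glew import (
    FitError,
    FitResult,
    chickos_heat_capacity,
    clarke_glew_pressure,
    extrapolate,
    fit_clarke_glew,
    log_pressure_slope,
    vaporization_enthalpy,
)
from .data import COMPOUNDS
from .io import points_to_frame, read_compounds, read_measurements
from .partitioning import (
    SCENARIO_PRESETS,
    PartitioningResult,
    PartitioningScenario,
    partition,
)
from .saturation import HELIUM, CompoundSpec, VaporPressurePoint, vapor_pressure
from .uncertainty import ProfileLike, first_order_budget, resolve_profile
from ._format import format_enthalpy, format_fraction, format_pressure

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "CompoundReport",
    "PipelineReport",
    "run_pipeline",
    "render_report",
]

log = logging.getLogger(__name__)

ScenarioLike = Union[str, PartitioningScenario]


class PipelineError(RuntimeError):
    """A failure that invalidates the whole pipeline run."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and options of one pipeline run."""

    measurements: str | Path
    registry: Optional[str | Path] = None  # None -> built-in compound registry
    theta: float = 307.15  # K
    exclusion_threshold: float = 0.1  # Pa
    extrapolation_temperatures: Sequence[float] = (307.15, 310.15)
    enthalpy_temperatures: Optional[Sequence[float]] = None  # None -> (298.15, <T>)
    scenarios: Sequence[ScenarioLike] = ("breath-clean", "breath-ambient")
    uncertainty_profile: Optional[ProfileLike] = "standard"
    seed: int = 0
    output_dir: Optional[str | Path] = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.extrapolation_temperatures):
            raise ValueError("extrapolation temperatures must be positive")
        if self.enthalpy_temperatures is not None and any(
            t <= 0 for t in self.enthalpy_temperatures
        ):
            raise ValueError("enthalpy temperatures must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        scenarios = raw.get("scenarios", ("breath-clean", "breath-ambient"))
        parsed: list[ScenarioLike] = []
        for s in scenarios:
            if isinstance(s, str):
                parsed.append(s)
            else:
                parsed.append(
                    PartitioningScenario(
                        temperature=float(s.get("temperature", 307.15)),
                        aerosol_concentration=float(s["aerosol_concentration"]),
                        activity_coefficient=float(s.get("activity_coefficient", 1.0)),
                    )
                )
        raw["scenarios"] = tuple(parsed)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_scenarios(scenarios: Sequence[ScenarioLike]) -> list[PartitioningScenario]:
    out = []
    for s in scenarios:
        out.append(SCENARIO_PRESETS[s] if isinstance(s, str) else s)
    return out


@dataclass
class CompoundReport:
    """Per-compound stage outputs; ``error`` is set when the fit failed."""

    compound: CompoundSpec
    points: pd.DataFrame
    fit: Optional[FitResult] = None
    extrapolation: Optional[pd.DataFrame] = None
    enthalpies: Optional[pd.DataFrame] = None
    partitioning: list[PartitioningResult] = field(default_factory=list)
    error: Optional[str] = None


@dataclass
class PipelineReport:
    """Everything a run produced, serializable at full precision."""

    compounds: dict[str, CompoundReport]
    metadata: dict

    def to_dict(self) -> dict:
        out: dict = {"metadata": dict(self.metadata), "compounds": {}}
        for name, rep in sorted(self.compounds.items()):
            entry: dict = {
                "points": rep.points.to_dict(orient="records"),
                "error": rep.error,
            }
            if rep.fit is not None:
                fr = rep.fit
                entry["fit"] = {
                    "theta_K": fr.params.theta,
                    "p0_Pa": fr.params.p0,
                    "dvap_g_kJ_mol": fr.params.dvap_g,
                    "dvap_h_kJ_mol": fr.params.dvap_h,
                    "dvap_cp_J_K_mol": fr.params.dvap_cp,
                    "n_used": fr.n_used,
                    "n_excluded": fr.n_excluded,
                    "mean_fit_temperature_K": fr.mean_fit_temperature,
                    "stderr_dvap_g_kJ_mol": fr.stderr_dvap_g,
                    "stderr_dvap_h_kJ_mol": fr.stderr_dvap_h,
                    "covariance_kJ2_mol2": fr.covariance.tolist(),
                    "temperature_range_K": list(fr.temperature_range),
                }
            if rep.extrapolation is not None:
                entry["extrapolation"] = rep.extrapolation.to_dict(orient="records")
            if rep.enthalpies is not None:
                entry["enthalpies"] = rep.enthalpies.to_dict(orient="records")
            entry["partitioning"] = [
                {
                    "temperature_K": r.scenario.temperature,
                    "c_oa_ug_m3": r.scenario.aerosol_concentration,
                    "activity_coefficient": r.scenario.activity_coefficient,
                    "c_star_ug_m3": r.c_star,
                    "f_oa": r.f_oa,
                    "f_vapor": r.f_vapor,
                    "volatility_class": r.volatility_class,
                }
                for r in rep.partitioning
            ]
            out["compounds"][name] = entry
        return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full chain; see module docstring for the stage list."""
    records = read_measurements(config.measurements)
    if not records:
        raise PipelineError(f"measurement table {config.measurements} is empty")
    registry = read_compounds(config.registry) if config.registry else dict(COMPOUNDS)
    scenarios = _resolve_scenarios(config.scenarios)

    by_compound: dict[str, list] = {}
    for rec in records:
        by_compound.setdefault(rec.compound, []).append(rec)

    reports: dict[str, CompoundReport] = {}
    for name, recs in sorted(by_compound.items()):
        if name not in registry:
            reports[name] = CompoundReport(
                compound=CompoundSpec(name=name, molar_mass=1.0),
                points=pd.DataFrame(),
                error=f"compound {name!r} not in registry",
            )
            log.warning("skipping %s: not in registry", name)
            continue
        comp = registry[name]
        points = [vapor_pressure(r, comp, HELIUM) for r in recs]
        log.info("%s: %d measurement points read", name, len(points))
        rep = CompoundReport(compound=comp, points=points_to_frame(points))
        reports[name] = rep

        if comp.cp_gas is None:
            rep.error = "cp_gas missing: cannot fix the heat-capacity term"
            continue
        # integer-rounded, the precision at which such correlations are
        # distributed in parameter tables
        dvap_cp = float(round(chickos_heat_capacity(comp.cp_gas)))
        try:
            fit = fit_clarke_glew(
                points,
                theta=config.theta,
                dvap_cp=dvap_cp,
                exclusion_threshold=config.exclusion_threshold,
            )
        except FitError as exc:
            rep.error = str(exc)
            log.warning("%s: fit failed: %s", name, exc)
            continue
        rep.fit = fit
        log.info(
            "%s: fit used %d points (%d excluded), DvapH(theta) = %.2f kJ/mol",
            name, fit.n_used, fit.n_excluded, fit.params.dvap_h,
        )

        # uncertainties: correlation slope supplies the temperature sensitivity
        if config.uncertainty_profile is not None:
            with_u = []
            for rec, pt in zip(recs, points):
                u = resolve_profile(config.uncertainty_profile, rec, comp)
                slope = log_pressure_slope(fit.params, rec.temperature)
                budget = first_order_budget(rec, comp, HELIUM, u, dlnp_dT=slope)
                with_u.append(dataclasses.replace(pt, u_c=budget.total))
            points = with_u
            rep.points = points_to_frame(points)

        rep.extrapolation = extrapolate(
            fit.params, config.extrapolation_temperatures, fit.temperature_range
        )
        h_temps = (
            tuple(config.enthalpy_temperatures)
            if config.enthalpy_temperatures is not None
            else (298.15, fit.mean_fit_temperature)
        )
        rep.enthalpies = pd.DataFrame(
            {
                "T_K": list(h_temps),
                "dvap_h_kJ_mol": [vaporization_enthalpy(fit.params, t) for t in h_temps],
            }
        )
        rep.partitioning = [
            partition(comp, clarke_glew_pressure(fit.params, sc.temperature), sc)
            for sc in scenarios
        ]

    config_payload = dataclasses.asdict(config)
    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "n_compounds": len(by_compound),
    }
    return PipelineReport(compounds=reports, metadata=metadata)


def _text_report(report: PipelineReport) -> str:
    lines = ["cannavap pipeline report", "=" * 40]
    names = sorted(report.compounds)
    for name in names:
        rep = report.compounds[name]
        lines.append(f"\n{name}")
        lines.append("-" * len(name))
        if rep.error:
            lines.append(f"  ERROR: {rep.error}")
            continue
        fr = rep.fit
        lines.append(
            f"  fit: n_used={fr.n_used} n_excluded={fr.n_excluded} "
            f"<T>={fr.mean_fit_temperature:.1f} K"
        )
        lines.append(
            f"  DvapG(theta) = {fr.params.dvap_g:.2f} kJ/mol, "
            f"DvapH(theta) = {fr.params.dvap_h:.2f} kJ/mol, "
            f"DvapCp = {fr.params.dvap_cp:.0f} J/(K mol)"
        )
        for _, row in rep.extrapolation.iterrows():
            tag = " (extrapolated)" if row["extrapolated"] else ""
            lines.append(
                f"  p_corr({row['T_K']:.2f} K) = {format_pressure(row['p_corr_Pa'])} Pa{tag}"
            )
        for _, row in rep.enthalpies.iterrows():
            lines.append(
                f"  DvapH({row['T_K']:.2f} K) = "
                f"{format_enthalpy(row['dvap_h_kJ_mol'])} kJ/mol"
            )
        for r in rep.partitioning:
            lines.append(
                f"  C_OA={r.scenario.aerosol_concentration:g} ug/m3 @ "
                f"{r.scenario.temperature:.2f} K: C*={r.c_star:.3g} ug/m3, "
                f"F_OA={format_fraction(r.f_oa)}, "
                f"F_vapor={format_fraction(r.f_vapor)}, {r.volatility_class}"
            )
    return "\n".join(lines) + "\n"


def render_report(
    report: PipelineReport,
    output_dir: str | Path,
    formats: Sequence[str] = ("json", "csv", "text"),
) -> list[Path]:
    """Write the report; JSON carries full precision, text uses the printed
    rounding conventions (pressures 2 s.f., enthalpies 1 d.p., fractions 2 d.p.)."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = outdir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)
    if "csv" in formats:
        frames = [rep.points for rep in report.compounds.values() if not rep.points.empty]
        if frames:
            path = outdir / "vapor_pressures.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            written.append(path)
        corr = []
        for name, rep in sorted(report.compounds.items()):
            if rep.extrapolation is None:
                continue
            df = rep.extrapolation.copy()
            df.insert(0, "compound", name)
            corr.append(df)
        if corr:
            path = outdir / "correlation.csv"
            pd.concat(corr, ignore_index=True).rename(
                columns={"extrapolated": "extrapolated_flag"}
            ).to_csv(path, index=False)
            written.append(path)
    if "text" in formats:
        path = outdir / "report.txt"
        path.write_text(_text_report(report))
        written.append(path)
    return written
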