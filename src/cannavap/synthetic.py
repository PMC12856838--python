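"""Synthetic gas-saturation (DVME) measurement series.

The generator inverts the measurement equations: given a "true"
Clarke-Glew parameter set it computes the vapor pressure at each run
temperature, converts it to the trapped analyte mass a real experiment
would have collected, and emits raw measurement records that the analysis
chain can process end to end.  This makes parameter-recovery and pipeline
tests possible without laboratory data.

The default design mirrors a realistic campaign: seven nominal
temperatures from 364 K to 424 K in 10 K steps, six replicate series,
50 sccm helium with total flows of 3000 scc (364-394 K), 2000 scc
(404/414 K) and 1200 scc (424 K), and ambient pressure of a high-altitude
laboratory (83 kPa).  Two error mechanisms are modelled:

* multiplicative Gaussian noise on the trapped mass (GC quantitation
  scatter), and
* a Gaussian perturbation plus optional bias on the *generating*
  temperature while the record keeps the nominal setpoint -- the
  incomplete-temperature-equilibration mechanism, where the sample is
  briefly cooler than the thermometer reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .clarke_glew import ClarkeGlewParams, clarke_glew_pressure
from .data import COMPOUNDS, HELIUM, REFERENCE_CORRELATIONS
from .saturation import (
    CarrierGasSpec,
    CompoundSpec,
    MeasurementRecord,
    carrier_mass_from_standard_volume,
)

__all__ = [
    "SyntheticDesign",
    "default_overpressure",
    "invert_to_trapped_mass",
    "generate_series",
    "design_for",
]

DEFAULT_TEMPERATURES = (364.0, 374.0, 384.0, 394.0, 404.0, 414.0, 424.0)
DEFAULT_FLOWS_SCC = (3000.0, 3000.0, 3000.0, 3000.0, 2000.0, 2000.0, 1200.0)


def default_overpressure(temperature: float) -> float:
    """Saturator overpressure model, Pa: linear growth with temperature.

    Viscous flow through the trap capillary raises the vial pressure above
    ambient; gas viscosity grows with temperature, so the default rises
    from 400 Pa at 364 K by 8 Pa/K.  Override per design when measured
    values are available.
    """
    return 400.0 + 8.0 * (temperature - 364.0)


@dataclass(frozen=True)
class SyntheticDesign:
    """Everything defining one synthetic measurement campaign."""

    true_params: ClarkeGlewParams
    compound: CompoundSpec
    gas: CarrierGasSpec = HELIUM
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES  # K, nominal
    n_series: int = 6
    total_flow_scc: Sequence[float] = DEFAULT_FLOWS_SCC  # per temperature
    flow_rate: float = 50.0  # sccm, metadata
    p_ambient: float = 83_000.0  # Pa
    overpressure_by_T: Optional[Mapping[float, float]] = None  # Pa; default model if None
    noise_m2_rel: float = 0.03  # multiplicative sd on trapped mass
    noise_T_sd: float = 0.25  # K, generating-side temperature scatter
    bias_T: float = 0.0  # K, systematic generating-side offset
    seed: int = 0

    def __post_init__(self) -> None:
        temps = tuple(self.temperatures)
        if len(set(temps)) != len(temps):
            raise ValueError("temperatures must be distinct")
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        if len(self.total_flow_scc) != len(temps):
            raise ValueError(
                f"need one total flow per temperature: {len(self.total_flow_scc)} "
                f"vs {len(temps)}"
            )
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")
        if self.noise_m2_rel < 0 or self.noise_T_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.p_ambient <= 0:
            raise ValueError("p_ambient must be > 0")

    def overpressure(self, temperature: float) -> float:
        if self.overpressure_by_T is not None:
            return float(self.overpressure_by_T[temperature])
        return default_overpressure(temperature)


def invert_to_trapped_mass(
    p_true: float,
    m1: float,
    p_saturator: float,
    x2: float,
    compound: CompoundSpec,
    gas: CarrierGasSpec = HELIUM,
) -> float:
    """Trapped mass that yields ``p_true`` under the measurement equations.

    Algebraic inverse of p = p_saturator * y2 / x2 with
    y2 = (m2/M2)/(m1/M1 + m2/M2):

        y2 = p_true * x2 / p_saturator
        m2 = M2 * (y2 / (1 - y2)) * (m1 / M1)
    """
    if p_true < 0:
        raise ValueError(f"p_true must be >= 0, got {p_true}")
    if m1 <= 0 or p_saturator <= 0 or not 0 < x2 <= 1:
        raise ValueError("m1, p_saturator must be positive and x2 in (0, 1]")
    y2 = p_true * x2 / p_saturator
    if y2 >= 1:
        raise ValueError(
            f"implied vapor mole fraction {y2} >= 1: analyte pressure exceeds "
            "saturator pressure"
        )
    return compound.molar_mass * (y2 / (1.0 - y2)) * (m1 / gas.molar_mass)


def generate_series(design: SyntheticDesign) -> list[MeasurementRecord]:
    """Generate all replicate series of a design; deterministic per seed."""
    rng = np.random.default_rng(design.seed)
    x2 = design.compound.purity_mole_fraction
    records: list[MeasurementRecord] = []
    for s in range(1, design.n_series + 1):
        for t_nominal, flow in zip(design.temperatures, design.total_flow_scc):
            # error mechanism: the sample sits at a perturbed temperature
            # while the record carries the nominal setpoint
            t_actual = t_nominal + design.bias_T + rng.normal(0.0, design.noise_T_sd)
            p_true = clarke_glew_pressure(design.true_params, t_actual)
            p_vial = design.p_ambient + design.overpressure(t_nominal)
            m1 = carrier_mass_from_standard_volume(flow, gas=design.gas)
            m2 = invert_to_trapped_mass(
                p_true, m1, p_vial, x2, design.compound, design.gas
            )
            m2 *= 1.0 + rng.normal(0.0, design.noise_m2_rel)
            records.append(
                MeasurementRecord(
                    compound=design.compound.name,
                    temperature=t_nominal,
                    carrier_mass=m1,
                    trapped_mass=max(m2, 0.0),
                    p_ambient=design.p_ambient,
                    p_overpressure=design.overpressure(t_nominal),
                    series_id=f"S{s}",
                    flow_rate=design.flow_rate,
                    duration=flow / design.flow_rate,
                )
            )
    return records


def design_for(name: str, **overrides) -> SyntheticDesign:
    """Fixture design for a registered compound, truth = its published correlation.

    The CBN fixture doubles the 364 K total flow to 6000 scc, mirroring
    the practice of collecting longer where the pressure (and hence the
    trapped mass) is smallest.
    """
    key = name.upper()
    compound = COMPOUNDS[key]
    params = REFERENCE_CORRELATIONS[key]
    design = SyntheticDesign(true_params=params, compound=compound)
    if key == "CBN" and "total_flow_scc" not in overrides:
        flows = (6000.0,) + tuple(DEFAULT_FLOWS_SCC[1:])
        design = replace(design, total_flow_scc=flows)
    if overrides:
        design = replace(design, **overrides)
    return design
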