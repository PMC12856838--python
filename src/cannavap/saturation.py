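"""Vapor pressures from raw gas-saturation (DVME) measurement variables.

In a dynamic vapor microextraction (DVME) experiment a slow stream of
helium saturates with analyte vapor inside a heated vial and the analyte
is recovered from a cooled capillary trap.  The saturation vapor pressure
follows from Dalton's law applied to the saturated carrier stream:

    p_sat = p_saturator * y2 / x2
    p_saturator = p_ambient + p_overpressure
    y2 = (m2/M2) / (m1/M1 + m2/M2)
    x2 = 1 - x1 - x_impurities

where subscript 1 is the carrier gas (helium) and subscript 2 the analyte;
``m`` are masses, ``M`` molar masses, ``y2`` the analyte mole fraction in
the vapor, and ``x2`` the analyte mole fraction in the condensed phase
(a Raoult's-law purity correction).  The overpressure term accounts for the
viscous pressure drop across the trap capillary.  Helium solubility in the
condensed phase, ``x1``, is negligible for large organic liquids and
defaults to zero.

This module holds the measurement-domain value types and the closed-form
conversion operations, including internal-standard GC quantitation of the
trapped mass and area-percent purity.  All quantities are strict SI
internally: Pa, K, g, mol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.constants import R as R_SI  # 8.31446... J/(K mol), for gas metering

__all__ = [
    "STANDARD_TEMPERATURE",
    "STANDARD_PRESSURE",
    "CompoundSpec",
    "CarrierGasSpec",
    "HELIUM",
    "MeasurementRecord",
    "VaporPressurePoint",
    "CalibrationLine",
    "ChromatogramPeakSet",
    "carrier_mass_from_standard_volume",
    "vapor_mole_fraction",
    "condensed_purity",
    "purity_from_areas",
    "mass_from_internal_standard",
    "saturator_pressure",
    "vapor_pressure",
]

log = logging.getLogger(__name__)

#: Reference conditions defining "standard cubic centimeters" (scc).
#: Mass-flow-controller vendors differ; these are configurable per call.
STANDARD_TEMPERATURE = 273.15  # K
STANDARD_PRESSURE = 101_325.0  # Pa


@dataclass(frozen=True)
class CompoundSpec:
    """Identity and physical properties of an analyte.

    Parameters
    ----------
    name : str
        Compound label, e.g. ``"THC"``.
    molar_mass : float
        Molar mass M2 in g/mol.
    cp_gas : float, optional
        Ideal-gas heat capacity Cp(g) at 298.15 K in J/(K mol); feeds the
        Chickos estimate of the vaporization heat-capacity change.
    purity_mole_fraction : float
        Condensed-phase analyte mole fraction x2 in (0, 1].
    smiles : str, optional
        Structure line notation, metadata only.
    """

    name: str
    molar_mass: float
    cp_gas: Optional[float] = None
    purity_mole_fraction: float = 1.0
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")
        if not 0 < self.purity_mole_fraction <= 1:
            raise ValueError(
                f"purity_mole_fraction must be in (0, 1], got {self.purity_mole_fraction}"
            )
        if self.cp_gas is not None and self.cp_gas <= 0:
            raise ValueError(f"cp_gas must be > 0 when supplied, got {self.cp_gas}")


@dataclass(frozen=True)
class CarrierGasSpec:
    """Carrier-gas properties: molar mass M1 and condensed-phase solubility x1."""

    molar_mass: float = 4.0026  # helium, g/mol
    solubility: float = 0.0  # mole fraction x1 dissolved in the analyte

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")
        if not 0 <= self.solubility < 1:
            raise ValueError(f"solubility must be in [0, 1), got {self.solubility}")


#: Default carrier gas: helium with negligible solubility in the analyte.
HELIUM = CarrierGasSpec()


@dataclass(frozen=True)
class MeasurementRecord:
    """One saturation run: everything needed to compute a single p_sat.

    ``flow_rate`` (sccm) and ``duration`` (min) are metadata and do not
    enter the pressure calculation.
    """

    compound: str
    temperature: float  # K (nominal setpoint)
    carrier_mass: float  # g of carrier gas through the saturator, m1
    trapped_mass: float  # g of analyte recovered from the trap, m2
    p_ambient: float  # Pa
    p_overpressure: float = 0.0  # Pa
    series_id: str = ""
    flow_rate: Optional[float] = None  # sccm
    duration: Optional[float] = None  # min

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.carrier_mass <= 0:
            raise ValueError(f"carrier_mass must be > 0, got {self.carrier_mass}")
        if self.trapped_mass < 0:
            raise ValueError(f"trapped_mass must be >= 0, got {self.trapped_mass}")
        if self.p_ambient <= 0:
            raise ValueError(f"p_ambient must be > 0, got {self.p_ambient}")
        if self.p_overpressure < 0:
            raise ValueError(f"p_overpressure must be >= 0, got {self.p_overpressure}")


@dataclass(frozen=True)
class VaporPressurePoint:
    """A derived (T, p_sat, u_c) triple; the correlation fit's input."""

    temperature: float  # K
    p_sat: float  # Pa
    u_c: Optional[float] = None  # combined standard uncertainty (k=1), Pa
    compound: str = ""
    series_id: str = ""

    def __post_init__(self) -> None:
        if self.p_sat < 0:
            raise ValueError(f"p_sat must be >= 0, got {self.p_sat}")
        if self.u_c is not None and self.u_c < 0:
            raise ValueError(f"u_c must be >= 0, got {self.u_c}")


@dataclass(frozen=True)
class CalibrationLine:
    """Internal-standard calibration: mass ratio = slope * area ratio + intercept."""

    slope: float
    intercept: float = 0.0
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


@dataclass(frozen=True)
class ChromatogramPeakSet:
    """GC-FID peak areas for one injection, plus the internal-standard mass."""

    analyte_area: float
    internal_standard_area: float = 0.0
    internal_standard_mass: float = 0.0  # g
    impurity_areas: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.analyte_area < 0:
            raise ValueError("analyte_area must be >= 0")
        if self.internal_standard_area < 0:
            raise ValueError("internal_standard_area must be >= 0")
        if any(a < 0 for a in self.impurity_areas):
            raise ValueError("impurity areas must be >= 0")


def carrier_mass_from_standard_volume(
    volume: float,
    std_temperature: float = STANDARD_TEMPERATURE,
    std_pressure: float = STANDARD_PRESSURE,
    gas: CarrierGasSpec = HELIUM,
) -> float:
    """Convert a standard-volume flow total (scc) to grams of carrier gas.

    Ideal gas at the stated standard conditions: m1 = M1 * p V / (R T).
    """
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    if std_temperature <= 0 or std_pressure <= 0:
        raise ValueError("standard temperature and pressure must be positive")
    moles = std_pressure * (volume * 1e-6) / (R_SI * std_temperature)
    return gas.molar_mass * moles


def vapor_mole_fraction(
    m1: float,
    m2: float,
    gas: CarrierGasSpec = HELIUM,
    compound: CompoundSpec | None = None,
    molar_mass: float | None = None,
) -> float:
    """Analyte mole fraction y2 in the saturated carrier stream.

    y2 = (m2/M2) / (m1/M1 + m2/M2).  Pass either a ``CompoundSpec`` or an
    explicit analyte ``molar_mass`` in g/mol.
    """
    if m1 <= 0:
        raise ValueError(f"carrier mass m1 must be > 0, got {m1}")
    if m2 < 0:
        raise ValueError(f"trapped mass m2 must be >= 0, got {m2}")
    if compound is not None:
        m_analyte = compound.molar_mass
    elif molar_mass is not None:
        m_analyte = molar_mass
    else:
        raise ValueError("provide a compound or an explicit molar_mass")
    n2 = m2 / m_analyte
    n1 = m1 / gas.molar_mass
    return n2 / (n1 + n2)


def condensed_purity(x_impurities: float, gas: CarrierGasSpec = HELIUM) -> float:
    """Condensed-phase analyte mole fraction x2 = 1 - x1 - x_impurities."""
    if x_impurities < 0:
        raise ValueError(f"x_impurities must be >= 0, got {x_impurities}")
    x2 = 1.0 - gas.solubility - x_impurities
    if x2 <= 0:
        raise ValueError(
            f"x1 + x_impurities = {gas.solubility + x_impurities} >= 1: no analyte left"
        )
    return x2


def purity_from_areas(peaks: ChromatogramPeakSet) -> float:
    """Area-percent purity as a fraction: analyte / (analyte + impurities).

    GC-FID area percent is mapped directly to mole fraction, assuming equal
    response factors and similar impurity molar masses (an approximation).
    """
    total_impurity = math.fsum(peaks.impurity_areas)
    denom = peaks.analyte_area + total_impurity
    if denom <= 0:
        raise ValueError("all peak areas are zero; purity undefined")
    return peaks.analyte_area / denom


def mass_from_internal_standard(
    peaks: ChromatogramPeakSet, cal: CalibrationLine
) -> float:
    """Trapped analyte mass from internal-standard GC quantitation.

    m2 = m_IS * (slope * A_analyte / A_IS + intercept).  A calibration
    intercept can drive small peaks negative; the mass is clipped at zero
    with a warning rather than raising.
    """
    if peaks.internal_standard_area <= 0:
        raise ValueError("internal_standard_area must be > 0 to quantitate")
    if peaks.internal_standard_mass <= 0:
        raise ValueError("internal_standard_mass must be > 0 to quantitate")
    ratio = peaks.analyte_area / peaks.internal_standard_area
    mass = peaks.internal_standard_mass * (cal.slope * ratio + cal.intercept)
    if mass < 0:
        log.warning(
            "calibration intercept drove quantitated mass negative (%g g); clipping to 0",
            mass,
        )
        return 0.0
    return mass


def saturator_pressure(p_ambient: float, p_overpressure: float = 0.0) -> float:
    """Total pressure in the saturation vial: ambient plus trap overpressure."""
    if p_ambient <= 0:
        raise ValueError(f"p_ambient must be > 0, got {p_ambient}")
    if p_overpressure < 0:
        raise ValueError(f"p_overpressure must be >= 0, got {p_overpressure}")
    return p_ambient + p_overpressure


def vapor_pressure(
    record: MeasurementRecord,
    compound: CompoundSpec,
    gas: CarrierGasSpec = HELIUM,
) -> VaporPressurePoint:
    """Saturation vapor pressure for one run: p_sat = p_saturator * y2 / x2.

    The combined standard uncertainty ``u_c`` is left unset here; the
    :mod:`cannavap.uncertainty` module fills it from an input-uncertainty
    budget.
    """
    y2 = vapor_mole_fraction(record.carrier_mass, record.trapped_mass, gas, compound)
    p_vial = saturator_pressure(record.p_ambient, record.p_overpressure)
    p_sat = p_vial * y2 / compound.purity_mole_fraction
    return VaporPressurePoint(
        temperature=record.temperature,
        p_sat=p_sat,
        u_c=None,
        compound=record.compound,
        series_id=record.series_id,
    )
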