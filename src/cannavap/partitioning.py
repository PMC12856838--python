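"""Vapor-aerosol partitioning at breath conditions.

The absorptive-partitioning (volatility basis set) framework maps a vapor
pressure onto an effective saturation concentration

    C* = M * 1e6 * zeta * p / (R * T)    [ug m^-3]

the organic-aerosol mass concentration at which the compound splits
equally between vapor and aerosol.  Against an actual aerosol loading
C_OA, the equilibrium aerosol-phase mass fraction is

    F_OA = (1 + C*/C_OA)^-1.

Compounds are binned by C* into the standard volatility classes; the
semi-volatile (SVOC) band spans 0.3-300 ug m^-3, the range in which both
phases carry substantial fractions at ambient-like loadings.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

from .clarke_glew import R
from .saturation import CompoundSpec

__all__ = [
    "PartitioningScenario",
    "PartitioningResult",
    "DEFAULT_VOLATILITY_BANDS",
    "SCENARIO_PRESETS",
    "effective_saturation_concentration",
    "aerosol_fraction",
    "classify_volatility",
    "partition",
]


@dataclass(frozen=True)
class PartitioningScenario:
    """Conditions of a partitioning calculation.

    ``aerosol_concentration`` is the total organic-aerosol loading C_OA in
    ug m^-3 (breath plus ambient); ``activity_coefficient`` is the
    molality-based activity coefficient zeta of the analyte in the aerosol
    (1 for an ideal mixture, the usual assumption).
    """

    temperature: float = 307.15  # K
    aerosol_concentration: float = 1.7  # ug m^-3
    activity_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.aerosol_concentration <= 0:
            raise ValueError(
                f"aerosol_concentration must be > 0, got {self.aerosol_concentration}"
            )
        if self.activity_coefficient <= 0:
            raise ValueError(
                f"activity_coefficient must be > 0, got {self.activity_coefficient}"
            )


#: Named scenarios: clean filtered air (breath aerosol only) vs untreated
#: ambient air an order of magnitude higher, both at breath temperature.
SCENARIO_PRESETS: dict[str, PartitioningScenario] = {
    "breath-clean": PartitioningScenario(307.15, 1.7, 1.0),
    "breath-ambient": PartitioningScenario(307.15, 17.0, 1.0),
}

#: Volatility classes as (label, lower C* edge in ug m^-3); half-open
#: lower-edge-inclusive bands on the standard decade grid.  Only the SVOC
#: span (0.3-300) is anchored to measurement practice; edges are settable.
DEFAULT_VOLATILITY_BANDS: tuple[tuple[str, float], ...] = (
    ("ELVOC", 0.0),
    ("LVOC", 3.0e-4),
    ("SVOC", 0.3),
    ("IVOC", 300.0),
    ("VOC", 3.0e6),
)


@dataclass(frozen=True)
class PartitioningResult:
    """C*, phase fractions, and volatility class for one scenario."""

    c_star: float  # ug m^-3
    f_oa: float  # aerosol-phase mass fraction
    f_vapor: float  # = 1 - f_oa
    volatility_class: str
    compound: str = ""
    scenario: Optional[PartitioningScenario] = None

    def __post_init__(self) -> None:
        if self.c_star < 0:
            raise ValueError(f"c_star must be >= 0, got {self.c_star}")
        if not 0 <= self.f_oa <= 1:
            raise ValueError(f"f_oa must be in [0, 1], got {self.f_oa}")


def effective_saturation_concentration(
    compound: CompoundSpec,
    p_corr: float,
    scenario: PartitioningScenario,
) -> float:
    """C* = M * 1e6 * zeta * p_corr / (R T) in ug m^-3.

    ``p_corr`` is the (supercooled-liquid) vapor pressure in Pa at the
    scenario temperature; M is the molar mass in g/mol.
    """
    if p_corr < 0:
        raise ValueError(f"p_corr must be >= 0, got {p_corr}")
    return (
        compound.molar_mass
        * 1.0e6
        * scenario.activity_coefficient
        * p_corr
        / (R * scenario.temperature)
    )


def aerosol_fraction(c_star: float, c_oa: float) -> float:
    """Equilibrium aerosol-phase mass fraction F_OA = (1 + C*/C_OA)^-1."""
    if c_oa <= 0:
        raise ValueError(f"C_OA must be > 0, got {c_oa}")
    if c_star < 0:
        raise ValueError(f"c_star must be >= 0, got {c_star}")
    return 1.0 / (1.0 + c_star / c_oa)


def classify_volatility(
    c_star: float,
    bands: Sequence[tuple[str, float]] = DEFAULT_VOLATILITY_BANDS,
) -> str:
    """Volatility class label for a C* value under half-open [lower, next) bands."""
    if c_star < 0:
        raise ValueError(f"c_star must be >= 0, got {c_star}")
    edges = [lower for _, lower in bands]
    if edges != sorted(edges):
        raise ValueError("band lower edges must be ascending")
    idx = bisect_right(edges, c_star) - 1
    if idx < 0:
        idx = 0
    return bands[idx][0]


def partition(
    compound: CompoundSpec,
    p_corr: float,
    scenario: PartitioningScenario,
    bands: Sequence[tuple[str, float]] = DEFAULT_VOLATILITY_BANDS,
) -> PartitioningResult:
    """Full partitioning calculation for one compound and scenario."""
    c_star = effective_saturation_concentration(compound, p_corr, scenario)
    f_oa = aerosol_fraction(c_star, scenario.aerosol_concentration)
    return PartitioningResult(
        c_star=c_star,
        f_oa=f_oa,
        f_vapor=1.0 - f_oa,
        volatility_class=classify_volatility(c_star, bands),
        compound=compound.name,
        scenario=scenario,
    )
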