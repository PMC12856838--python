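"""Built-in compound registry and published reference correlations.

Three cannabinoids are shipped with the package: Δ9-tetrahydrocannabinol
(THC), cannabidiol (CBD, a structural isomer of THC), and cannabinol (CBN).
For each, the registry holds molar mass, ideal-gas heat capacity at
298.15 K, and GC-FID area-percent purity of the measured material, plus the
published Clarke-Glew correlation parameters (theta = 307.15 K,
p0 = 0.1 MPa) fitted to gas-saturation measurements over 364-424 K.  The
correlations serve as ground truth for the synthetic generator and as the
default parameter source for partitioning calculations.
"""

from __future__ import annotations

from .clarke_glew import ClarkeGlewParams
from .saturation import CarrierGasSpec, CompoundSpec, HELIUM

__all__ = [
    "COMPOUNDS",
    "REFERENCE_CORRELATIONS",
    "HELIUM",
    "get_compound",
    "get_reference_correlation",
]

COMPOUNDS: dict[str, CompoundSpec] = {
    "THC": CompoundSpec(
        name="THC",
        molar_mass=314.47,
        cp_gas=407.3,
        purity_mole_fraction=0.960,  # after helium-flow pretreatment
    ),
    "CBD": CompoundSpec(
        name="CBD",
        molar_mass=314.47,
        cp_gas=422.3,
        purity_mole_fraction=0.977,
    ),
    "CBN": CompoundSpec(
        name="CBN",
        molar_mass=310.47,
        cp_gas=387.8,
        purity_mole_fraction=0.991,
    ),
}

#: Published correlation parameters: dvap_g/dvap_h in kJ/mol at theta,
#: dvap_cp in J/(K mol) from the Chickos correlation (rounded as published).
REFERENCE_CORRELATIONS: dict[str, ClarkeGlewParams] = {
    "THC": ClarkeGlewParams(theta=307.15, p0=1e5, dvap_g=54.75, dvap_h=119.00, dvap_cp=-157.0),
    "CBD": ClarkeGlewParams(theta=307.15, p0=1e5, dvap_g=52.84, dvap_h=117.16, dvap_cp=-162.0),
    "CBN": ClarkeGlewParams(theta=307.15, p0=1e5, dvap_g=56.73, dvap_h=123.12, dvap_cp=-150.0),
}


def get_compound(name: str) -> CompoundSpec:
    """Look up a registered compound (case-insensitive)."""
    try:
        return COMPOUNDS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown compound {name!r}; registered: {sorted(COMPOUNDS)}"
        ) from None


def get_reference_correlation(name: str) -> ClarkeGlewParams:
    """Published Clarke-Glew parameters for a registered compound."""
    try:
        return REFERENCE_CORRELATIONS[name.upper()]
    except KeyError:
        raise KeyError(
            f"no reference correlation for {name!r}; available: "
            f"{sorted(REFERENCE_CORRELATIONS)}"
        ) from None
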