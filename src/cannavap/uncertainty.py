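"""Propagation of measurement uncertainty to the vapor pressure.

Two routes to the combined standard uncertainty u_c(p_sat), k = 1:

* :func:`first_order_budget` -- GUM-style first-order propagation with
  analytic partial derivatives of p_sat = (p_ambient + p_overpressure) *
  y2 / x2 with respect to each input variable.  Temperature does not enter
  that expression explicitly; its contribution comes through the steepness
  of the vapor-pressure curve, u_T * p_sat * dlnp/dT, with the logarithmic
  slope supplied from the correlation (DvapH/(R T^2)) or a finite
  difference.
* :func:`monte_carlo_budget` -- independent Gaussian draws of every input,
  full recomputation of p_sat per draw (temperature applied as the
  multiplicative factor exp(dlnp/dT * dT)).  Serves as the oracle for the
  first-order result; for small relative inputs the two agree, for large
  ones the Monte-Carlo total exceeds first order because the multiplicative
  terms are log-normally skewed.

All inputs are treated as independent.  Input-uncertainty profiles are
shipped as illustrative presets; the true per-variable values of any given
apparatus must come from its own calibration records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .saturation import (
    HELIUM,
    CarrierGasSpec,
    CompoundSpec,
    MeasurementRecord,
    vapor_mole_fraction,
)

__all__ = [
    "InputUncertainties",
    "UncertaintyBudget",
    "UNCERTAINTY_PROFILES",
    "first_order_budget",
    "monte_carlo_budget",
    "resolve_profile",
    "load_profile",
]

_VARIABLES = ("m1", "m2", "p_ambient", "p_overpressure", "x2", "T")


@dataclass(frozen=True)
class InputUncertainties:
    """Absolute standard uncertainties (k = 1) of the input variables."""

    u_m1: float = 0.0  # g
    u_m2: float = 0.0  # g
    u_p_ambient: float = 0.0  # Pa
    u_p_overpressure: float = 0.0  # Pa
    u_x2: float = 0.0  # mole fraction
    u_T: float = 0.0  # K

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Combined standard uncertainty and its per-variable decomposition."""

    total: float  # u_c(p_sat), Pa
    contributions: dict[str, float] = field(default_factory=dict)  # Pa, by variable
    relative: float = 0.0  # total / p_sat
    n_rejected: int = 0  # Monte-Carlo draws discarded as unphysical


#: Illustrative presets.  "standard" mirrors a run with a long thermal
#: equilibration period; "short-equilibration" a shortened one, which
#: mainly inflates the temperature uncertainty (and hence u_c at the
#: steep, high-T end of the curve).
UNCERTAINTY_PROFILES: dict[str, dict[str, dict[str, float]]] = {
    "standard": {
        "m1": {"relative": 0.005},
        "m2": {"relative": 0.025},
        "p_ambient": {"absolute": 50.0},
        "p_overpressure": {"absolute": 30.0},
        "x2": {"absolute": 0.003},
        "T": {"absolute": 0.25},
    },
    "short-equilibration": {
        "m1": {"relative": 0.005},
        "m2": {"relative": 0.04},
        "p_ambient": {"absolute": 50.0},
        "p_overpressure": {"absolute": 30.0},
        "x2": {"absolute": 0.004},
        "T": {"absolute": 0.6},
    },
}

ProfileLike = Union[str, Mapping[str, Mapping[str, float]]]


def resolve_profile(
    profile: ProfileLike,
    record: MeasurementRecord,
    compound: CompoundSpec,
) -> InputUncertainties:
    """Turn a profile (preset name or mapping) into absolute uncertainties.

    Each variable maps to ``{"absolute": u}`` or ``{"relative": r}``;
    relative entries are scaled by the record's value of that variable.
    """
    if isinstance(profile, str):
        try:
            profile = UNCERTAINTY_PROFILES[profile]
        except KeyError:
            raise KeyError(
                f"unknown uncertainty profile {profile!r}; "
                f"presets: {sorted(UNCERTAINTY_PROFILES)}"
            ) from None
    base = {
        "m1": record.carrier_mass,
        "m2": record.trapped_mass,
        "p_ambient": record.p_ambient,
        "p_overpressure": record.p_overpressure,
        "x2": compound.purity_mole_fraction,
        "T": record.temperature,
    }
    resolved: dict[str, float] = {}
    for var, spec in profile.items():
        if var not in _VARIABLES:
            raise ValueError(f"unknown variable {var!r}; expected one of {_VARIABLES}")
        if "absolute" in spec:
            resolved[var] = float(spec["absolute"])
        elif "relative" in spec:
            resolved[var] = float(spec["relative"]) * base[var]
        else:
            raise ValueError(f"profile entry for {var!r} needs 'absolute' or 'relative'")
    return InputUncertainties(
        u_m1=resolved.get("m1", 0.0),
        u_m2=resolved.get("m2", 0.0),
        u_p_ambient=resolved.get("p_ambient", 0.0),
        u_p_overpressure=resolved.get("p_overpressure", 0.0),
        u_x2=resolved.get("x2", 0.0),
        u_T=resolved.get("T", 0.0),
    )


def load_profile(path: str | Path) -> dict:
    """Read a JSON uncertainty profile (variable -> absolute/relative spec)."""
    with open(path) as fh:
        return json.load(fh)


def _nominal(record: MeasurementRecord, compound: CompoundSpec, gas: CarrierGasSpec):
    x2 = compound.purity_mole_fraction
    y2 = vapor_mole_fraction(record.carrier_mass, record.trapped_mass, gas, compound)
    p_vial = record.p_ambient + record.p_overpressure
    return p_vial * y2 / x2, y2, p_vial, x2


def first_order_budget(
    record: MeasurementRecord,
    compound: CompoundSpec,
    gas: CarrierGasSpec = HELIUM,
    u: InputUncertainties = InputUncertainties(),
    dlnp_dT: float = 0.0,
) -> UncertaintyBudget:
    """First-order (GUM) uncertainty budget for one measurement.

    u_c^2 = sum_v (dp/dv)^2 u(v)^2 over v in {m1, m2, p_ambient,
    p_overpressure, x2, T}; the temperature term is (p * dlnp/dT * u_T)^2.
    """
    if dlnp_dT is None or dlnp_dT < 0 or not np.isfinite(dlnp_dT):
        raise ValueError(f"dlnp_dT must be a finite value >= 0, got {dlnp_dT}")
    p, y2, p_vial, x2 = _nominal(record, compound, gas)

    a = record.trapped_mass / compound.molar_mass  # analyte moles
    b = record.carrier_mass / gas.molar_mass  # carrier moles
    dy2_dm2 = (1.0 / compound.molar_mass) * b / (a + b) ** 2
    dy2_dm1 = -(a / gas.molar_mass) / (a + b) ** 2

    contrib = {
        "m1": abs(p_vial / x2 * dy2_dm1) * u.u_m1,
        "m2": abs(p_vial / x2 * dy2_dm2) * u.u_m2,
        "p_ambient": (y2 / x2) * u.u_p_ambient,
        "p_overpressure": (y2 / x2) * u.u_p_overpressure,
        "x2": (p / x2) * u.u_x2,
        "T": p * dlnp_dT * u.u_T,
    }
    total = float(np.sqrt(np.sum([c**2 for c in contrib.values()])))
    return UncertaintyBudget(
        total=total,
        contributions=contrib,
        relative=total / p if p > 0 else 0.0,
    )


def _mc_pressures(
    record: MeasurementRecord,
    compound: CompoundSpec,
    gas: CarrierGasSpec,
    u: InputUncertainties,
    dlnp_dT: float,
    n_draws: int,
    rng: np.random.Generator,
    active: set[str],
) -> tuple[np.ndarray, int]:
    def draw(center: float, scale: float, name: str) -> np.ndarray:
        if name in active and scale > 0:
            return center + rng.normal(0.0, scale, n_draws)
        return np.full(n_draws, center)

    m1 = draw(record.carrier_mass, u.u_m1, "m1")
    m2 = draw(record.trapped_mass, u.u_m2, "m2")
    pa = draw(record.p_ambient, u.u_p_ambient, "p_ambient")
    po = draw(record.p_overpressure, u.u_p_overpressure, "p_overpressure")
    x2 = draw(compound.purity_mole_fraction, u.u_x2, "x2")
    if "T" in active and u.u_T > 0:
        t_factor = np.exp(dlnp_dT * rng.normal(0.0, u.u_T, n_draws))
    else:
        t_factor = np.ones(n_draws)

    valid = (m1 > 0) & (m2 >= 0) & (x2 > 0) & (x2 <= 1) & (pa + po > 0)
    n_rejected = int((~valid).sum())
    m1, m2, pa, po, x2, t_factor = (
        arr[valid] for arr in (m1, m2, pa, po, x2, t_factor)
    )
    n2 = m2 / compound.molar_mass
    n1 = m1 / gas.molar_mass
    y2 = n2 / (n1 + n2)
    p = (pa + po) * y2 / x2 * t_factor
    return p, n_rejected


def monte_carlo_budget(
    record: MeasurementRecord,
    compound: CompoundSpec,
    gas: CarrierGasSpec = HELIUM,
    u: InputUncertainties = InputUncertainties(),
    dlnp_dT: float = 0.0,
    n_draws: int = 100_000,
    seed: int = 0,
) -> UncertaintyBudget:
    """Monte-Carlo uncertainty budget: u_c as the sample standard deviation.

    Every input is drawn as an independent Gaussian and p_sat recomputed
    per draw.  Draws producing unphysical records (m1 <= 0, m2 < 0, x2
    outside (0, 1], non-positive saturator pressure) are rejected and
    counted; more than 1 % rejections triggers a warning.  Per-variable
    contributions are measured by one-at-a-time re-runs with independent
    substreams; for a fixed seed the whole budget is reproducible.
    """
    if n_draws < 1000:
        raise ValueError(f"n_draws must be >= 1000, got {n_draws}")
    if dlnp_dT is None or dlnp_dT < 0 or not np.isfinite(dlnp_dT):
        raise ValueError(f"dlnp_dT must be a finite value >= 0, got {dlnp_dT}")

    p_nom, _, _, _ = _nominal(record, compound, gas)
    streams = np.random.default_rng(seed).spawn(len(_VARIABLES) + 1)
    scales = {
        "m1": u.u_m1, "m2": u.u_m2, "p_ambient": u.u_p_ambient,
        "p_overpressure": u.u_p_overpressure, "x2": u.u_x2, "T": u.u_T,
    }

    contrib: dict[str, float] = {}
    for var, rng in zip(_VARIABLES, streams):
        if scales[var] == 0:  # nothing varies: contribution is exactly zero
            contrib[var] = 0.0
            continue
        p, _ = _mc_pressures(record, compound, gas, u, dlnp_dT, n_draws, rng, {var})
        contrib[var] = float(np.std(p, ddof=1)) if p.size > 1 else 0.0

    if all(s == 0 for s in scales.values()):
        return UncertaintyBudget(total=0.0, contributions=contrib, relative=0.0)
    p_all, n_rejected = _mc_pressures(
        record, compound, gas, u, dlnp_dT, n_draws, streams[-1], set(_VARIABLES)
    )
    if n_rejected > 0.01 * n_draws:
        warnings.warn(
            f"{n_rejected}/{n_draws} Monte-Carlo draws rejected as unphysical; "
            "input uncertainties may be too large for Gaussian modelling",
            stacklevel=2,
        )
    total = float(np.std(p_all, ddof=1)) if p_all.size > 1 else 0.0
    return UncertaintyBudget(
        total=total,
        contributions=contrib,
        relative=total / p_nom if p_nom > 0 else 0.0,
        n_rejected=n_rejected,
    )
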