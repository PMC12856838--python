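"""Clarke-Glew vapor-pressure correlation: fit, evaluate, differentiate.

The correlation, truncated at the heat-capacity term, relates the
saturation pressure of a (possibly supercooled) liquid to temperature
through thermodynamic quantities at a reference temperature theta:

    R ln(p/p0) = -DvapG(theta)/theta
                 + DvapH(theta) * (1/theta - 1/T)
                 + DvapCp * (theta/T - 1 + ln(T/theta))

with p0 = 0.1 MPa.  DvapCp (gas minus liquid heat capacity) is treated as
temperature independent and, when not measured, estimated from the
ideal-gas heat capacity with the Chickos group correlation

    DvapCp / (J K^-1 mol^-1) = -14.30 - 0.35 * Cp_gas(298.15 K).

Holding DvapCp fixed makes the model linear in (DvapG, DvapH), so the
unweighted least-squares fit in R ln(p/p0) space has a closed form.  The
enthalpy of vaporization at any temperature follows from Kirchhoff's law:
DvapH(T) = DvapH(theta) + DvapCp * (T - theta).

The fit is exposed as :class:`ClarkeGlewRegressor`, a scikit-learn style
estimator (temperatures in, pressures out), with thin functional wrappers
for one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .saturation import VaporPressurePoint

__all__ = [
    "R",
    "ClarkeGlewParams",
    "FitResult",
    "FitError",
    "chickos_heat_capacity",
    "chickos_expanded_uncertainty",
    "clarke_glew_pressure",
    "vaporization_enthalpy",
    "log_pressure_slope",
    "ClarkeGlewRegressor",
    "fit_clarke_glew",
    "extrapolate",
]

#: Gas constant as used throughout the correlation, J/(K mol).
R = 8.314

#: Reference pressure p0 of the correlation, Pa (0.1 MPa).
P0_DEFAULT = 1.0e5

#: Default reference temperature theta, K (exhaled-breath temperature).
THETA_DEFAULT = 307.15


class FitError(ValueError):
    """Raised when a correlation fit cannot be performed."""


def chickos_heat_capacity(cp_gas: float) -> float:
    """Heat-capacity change of vaporization from the Chickos correlation.

    DvapCp = -14.30 - 0.35 * Cp_gas, all in J/(K mol), with Cp_gas the
    ideal-gas heat capacity at 298.15 K.  The result is negative: the gas
    has a smaller heat capacity than the liquid.
    """
    if not np.isfinite(cp_gas):
        raise ValueError(f"cp_gas must be finite, got {cp_gas}")
    return -14.30 - 0.35 * cp_gas


def chickos_expanded_uncertainty(dvap_cp: float) -> float:
    """Expanded uncertainty conventionally attached to a Chickos estimate: 0.2|DvapCp|."""
    return 0.2 * abs(dvap_cp)


@dataclass(frozen=True)
class ClarkeGlewParams:
    """Parameter set of one correlation.

    Energies are kJ/mol at this boundary (converted to J/mol internally);
    ``dvap_cp`` is J/(K mol) and negative for liquids of this kind.
    """

    theta: float = THETA_DEFAULT  # K
    p0: float = P0_DEFAULT  # Pa
    dvap_g: float = 0.0  # kJ/mol, Gibbs energy of vaporization at theta
    dvap_h: float = 0.0  # kJ/mol, enthalpy of vaporization at theta
    dvap_cp: float = -1.0  # J/(K mol)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0 K, got {self.theta}")
        if self.p0 <= 0:
            raise ValueError(f"p0 must be > 0 Pa, got {self.p0}")
        if self.dvap_h <= 0:
            raise ValueError(f"dvap_h must be > 0 kJ/mol, got {self.dvap_h}")
        if self.dvap_cp >= 0:
            raise ValueError(f"dvap_cp must be < 0 J/(K mol), got {self.dvap_cp}")


def _shape_term(T: np.ndarray, theta: float) -> np.ndarray:
    # theta/T - 1 + ln(T/theta): the heat-capacity basis function; zero at T=theta
    return theta / T - 1.0 + np.log(T / theta)


def _as_temperatures(T) -> tuple[np.ndarray, bool]:
    arr = np.asarray(T, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if arr.ndim == 2 and arr.shape[1] == 1:  # sklearn-style column vector
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"temperatures must be scalar, 1-d, or (n, 1); got shape {np.shape(T)}")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("temperatures must be finite and > 0 K")
    return arr, scalar


def clarke_glew_pressure(params: ClarkeGlewParams, T):
    """Correlated saturation pressure p(T) in Pa; T scalar or array-like in K."""
    t, scalar = _as_temperatures(T)
    g = params.dvap_g * 1e3
    h = params.dvap_h * 1e3
    bracket = (
        -g / params.theta
        + h * (1.0 / params.theta - 1.0 / t)
        + params.dvap_cp * _shape_term(t, params.theta)
    )
    p = params.p0 * np.exp(bracket / R)
    return float(p[0]) if scalar else p


def vaporization_enthalpy(params: ClarkeGlewParams, T):
    """Enthalpy of vaporization DvapH(T) in kJ/mol (Kirchhoff, constant DvapCp)."""
    t, scalar = _as_temperatures(T)
    h = params.dvap_h + params.dvap_cp * (t - params.theta) / 1e3
    return float(h[0]) if scalar else h


def log_pressure_slope(params: ClarkeGlewParams, T):
    """d ln p / dT = DvapH(T) / (R T^2), in 1/K (Clausius-Clapeyron form)."""
    t, scalar = _as_temperatures(T)
    h_joule = vaporization_enthalpy(params, t) * 1e3
    s = h_joule / (R * t**2)
    return float(s[0]) if scalar else s


@dataclass(frozen=True)
class FitResult:
    """Outcome of a correlation fit.

    ``covariance`` is the 2x2 covariance of (DvapG, DvapH) in (kJ/mol)^2;
    ``residuals`` are in the fit's R ln(p/p0) space, J/(K mol).
    """

    params: ClarkeGlewParams
    n_used: int
    n_excluded: int
    mean_fit_temperature: float  # K
    residuals: np.ndarray
    covariance: np.ndarray
    stderr_dvap_g: float  # kJ/mol
    stderr_dvap_h: float  # kJ/mol
    temperature_range: tuple[float, float]  # span of the fitted points, K


class ClarkeGlewRegressor(RegressorMixin, BaseEstimator):
    """Fit the Clarke-Glew correlation to (temperature, pressure) data.

    With the heat-capacity change held fixed, the correlation is linear in
    the two free parameters, so ``fit`` solves an ordinary (unweighted)
    least-squares problem in R ln(p/p0) space in closed form.  Points at or
    below ``exclusion_threshold`` are dropped before fitting: very low
    pressures carry relative errors far beyond their nominal uncertainty
    and would otherwise bias the fit.

    Parameters
    ----------
    theta : float, default 307.15
        Reference temperature in K.
    p0 : float, default 1e5
        Reference pressure in Pa.
    dvap_cp : float, optional
        Heat-capacity change of vaporization, J/(K mol).  Fixed during
        fitting.  If omitted, estimated from ``cp_gas`` with the Chickos
        correlation.
    cp_gas : float, optional
        Ideal-gas heat capacity at 298.15 K, J/(K mol); used only when
        ``dvap_cp`` is not given.
    exclusion_threshold : float, default 0.1
        Pressure floor in Pa; only points with p > threshold are fitted.

    Attributes
    ----------
    dvap_g_, dvap_h_ : float
        Fitted Gibbs energy and enthalpy of vaporization at theta, kJ/mol.
    dvap_cp_ : float
        The heat-capacity change actually used, J/(K mol).
    n_used_, n_excluded_ : int
        Point counts after/under the exclusion filter.
    mean_fit_temperature_ : float
        Mean temperature of the fitted points, K.
    covariance_ : ndarray, shape (2, 2)
        Covariance of (dvap_g_, dvap_h_) in (kJ/mol)^2.
    residuals_ : ndarray
        Per-point residuals in R ln(p/p0) space, J/(K mol).
    temperature_range_ : tuple of float
        (min, max) of fitted temperatures; predictions outside are
        extrapolations.

    Examples
    --------
    >>> reg = ClarkeGlewRegressor(dvap_cp=-157.0)
    >>> T = [374., 384., 394., 404., 414., 424.]
    >>> p = clarke_glew_pressure(ClarkeGlewParams(dvap_g=54.75, dvap_h=119.0,
    ...                                           dvap_cp=-157.0), T)
    >>> reg.fit(T, p).dvap_h_  # doctest: +ELLIPSIS
    119.0...
    """

    def __init__(
        self,
        theta: float = THETA_DEFAULT,
        p0: float = P0_DEFAULT,
        dvap_cp: Optional[float] = None,
        cp_gas: Optional[float] = None,
        exclusion_threshold: float = 0.1,
    ) -> None:
        self.theta = theta
        self.p0 = p0
        self.dvap_cp = dvap_cp
        self.cp_gas = cp_gas
        self.exclusion_threshold = exclusion_threshold

    def _resolve_dvap_cp(self) -> float:
        if self.dvap_cp is not None:
            return float(self.dvap_cp)
        if self.cp_gas is not None:
            return chickos_heat_capacity(self.cp_gas)
        raise FitError("either dvap_cp or cp_gas must be set to fix the curvature term")

    def fit(self, X, y, sample_weight=None):
        """Fit to temperatures ``X`` (K) and pressures ``y`` (Pa).

        ``sample_weight`` is accepted for API compatibility but rejected if
        non-uniform: the fit is unweighted by construction.
        """
        if self.theta <= 0 or self.p0 <= 0:
            raise ValueError("theta and p0 must be positive")
        if sample_weight is not None and len(np.unique(sample_weight)) > 1:
            raise ValueError("the Clarke-Glew fit is unweighted; sample_weight unsupported")
        t, _ = _as_temperatures(X)
        p = np.asarray(y, dtype=float).ravel()
        if p.shape != t.shape:
            raise ValueError(f"X and y lengths differ: {t.shape} vs {p.shape}")
        if np.any(~np.isfinite(p)) or np.any(p < 0):
            raise ValueError("pressures must be finite and >= 0 Pa")

        dvap_cp = self._resolve_dvap_cp()
        mask = p > self.exclusion_threshold
        tu, pu = t[mask], p[mask]
        n_used = int(mask.sum())
        if n_used < 2:
            raise FitError(
                f"need >= 2 points above {self.exclusion_threshold} Pa, have {n_used}"
            )
        if np.ptp(tu) == 0:
            raise FitError("fitted temperatures are all equal; slope undetermined")

        # Linear model: y = a + b x with x = 1/theta - 1/T,
        # a = -DvapG/theta, b = DvapH (J/mol units internally).
        x = 1.0 / self.theta - 1.0 / tu
        yy = R * np.log(pu / self.p0) - dvap_cp * _shape_term(tu, self.theta)
        design = np.column_stack([np.ones_like(x), x])
        beta, _, _, _ = np.linalg.lstsq(design, yy, rcond=None)
        a, b = beta
        resid = yy - design @ beta
        if n_used > 2:
            s2 = float(resid @ resid) / (n_used - 2)
            cov_ab = s2 * np.linalg.inv(design.T @ design)
        else:
            cov_ab = np.zeros((2, 2))
        # (a, b) -> (G, H): G = -theta * a, H = b; then J -> kJ.
        jac = np.array([[-self.theta, 0.0], [0.0, 1.0]])
        cov_gh = jac @ cov_ab @ jac.T / 1e6

        self.dvap_cp_ = dvap_cp
        self.dvap_g_ = float(-self.theta * a / 1e3)
        self.dvap_h_ = float(b / 1e3)
        self.covariance_ = cov_gh
        self.stderr_dvap_g_ = float(np.sqrt(cov_gh[0, 0]))
        self.stderr_dvap_h_ = float(np.sqrt(cov_gh[1, 1]))
        self.residuals_ = resid
        self.n_used_ = n_used
        self.n_excluded_ = int((~mask).sum())
        self.mean_fit_temperature_ = float(tu.mean())
        self.temperature_range_ = (float(tu.min()), float(tu.max()))
        self.n_features_in_ = 1
        return self

    @property
    def params_(self) -> ClarkeGlewParams:
        """Fitted parameters as a :class:`ClarkeGlewParams` value object."""
        check_is_fitted(self, "dvap_h_")
        return ClarkeGlewParams(
            theta=self.theta,
            p0=self.p0,
            dvap_g=self.dvap_g_,
            dvap_h=self.dvap_h_,
            dvap_cp=self.dvap_cp_,
        )

    def predict(self, X):
        """Correlated pressures p_corr(T) in Pa for temperatures ``X`` in K."""
        check_is_fitted(self, "dvap_h_")
        t, scalar = _as_temperatures(X)
        p = clarke_glew_pressure(self.params_, t)
        return np.atleast_1d(p) if not scalar else np.atleast_1d(p)

    def enthalpy(self, T):
        """DvapH(T) in kJ/mol at the fitted parameters."""
        return vaporization_enthalpy(self.params_, T)

    def fit_result(self) -> FitResult:
        """Package the fitted state as an immutable :class:`FitResult`."""
        check_is_fitted(self, "dvap_h_")
        return FitResult(
            params=self.params_,
            n_used=self.n_used_,
            n_excluded=self.n_excluded_,
            mean_fit_temperature=self.mean_fit_temperature_,
            residuals=self.residuals_,
            covariance=self.covariance_,
            stderr_dvap_g=self.stderr_dvap_g_,
            stderr_dvap_h=self.stderr_dvap_h_,
            temperature_range=self.temperature_range_,
        )


def _split_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return points["T_K"].to_numpy(float), points["p_sat_Pa"].to_numpy(float)
    pts = list(points)
    if pts and isinstance(pts[0], VaporPressurePoint):
        return (
            np.array([q.temperature for q in pts]),
            np.array([q.p_sat for q in pts]),
        )
    arr = np.asarray(pts, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_clarke_glew(
    points: Iterable[VaporPressurePoint] | pd.DataFrame | Sequence,
    theta: float = THETA_DEFAULT,
    dvap_cp: Optional[float] = None,
    cp_gas: Optional[float] = None,
    exclusion_threshold: float = 0.1,
    p0: float = P0_DEFAULT,
) -> FitResult:
    """One-shot wrapper around :class:`ClarkeGlewRegressor`.

    ``points`` may be VaporPressurePoint objects, (T, p) pairs, or a frame
    with ``T_K``/``p_sat_Pa`` columns.
    """
    t, p = _split_points(points)
    reg = ClarkeGlewRegressor(
        theta=theta,
        p0=p0,
        dvap_cp=dvap_cp,
        cp_gas=cp_gas,
        exclusion_threshold=exclusion_threshold,
    )
    return reg.fit(t, p).fit_result()


def extrapolate(
    params: ClarkeGlewParams,
    temperatures: Sequence[float],
    fitted_range: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Evaluate p_corr at each temperature, flagging extrapolations.

    Returns a frame with columns ``T_K``, ``p_corr_Pa``, ``extrapolated``;
    a point is an extrapolation when it falls outside ``fitted_range``
    (when no range is given every point is flagged).
    """
    temps = np.asarray(list(temperatures), dtype=float)
    if temps.size == 0:
        return pd.DataFrame(columns=["T_K", "p_corr_Pa", "extrapolated"])
    p = clarke_glew_pressure(params, temps)
    if fitted_range is None:
        flagged = np.ones(temps.shape, dtype=bool)
    else:
        lo, hi = fitted_range
        flagged = (temps < lo) | (temps > hi)
    return pd.DataFrame(
        {"T_K": temps, "p_corr_Pa": np.atleast_1d(p), "extrapolated": flagged}
    )
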