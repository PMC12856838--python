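"""Clarke-Glew correlation: evaluation, Kirchhoff enthalpies, closed-form fit."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from cannavap._format import round_sig
from cannavap.clarke_glew import (
    R,
    ClarkeGlewParams,
    ClarkeGlewRegressor,
    FitError,
    chickos_expanded_uncertainty,
    chickos_heat_capacity,
    clarke_glew_pressure,
    extrapolate,
    fit_clarke_glew,
    vaporization_enthalpy,
)
from cannavap.data import REFERENCE_CORRELATIONS

THC = REFERENCE_CORRELATIONS["THC"]
CBD = REFERENCE_CORRELATIONS["CBD"]
CBN = REFERENCE_CORRELATIONS["CBN"]


class TestChickos:
    def test_intercept(self):
        assert chickos_heat_capacity(0.0) == pytest.approx(-14.30)

    @pytest.mark.parametrize(
        "cp_gas, published",
        [(407.3, -157), (422.3, -162), (387.8, -150)],
    )
    def test_published_roundings(self, cp_gas, published):
        assert round(chickos_heat_capacity(cp_gas)) == published

    def test_expanded_uncertainty_convention(self):
        assert chickos_expanded_uncertainty(-157.0) == pytest.approx(31.4)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            chickos_heat_capacity(float("nan"))


class TestPressure:
    def test_reference_temperature_identity(self):
        # at T = theta the H and Cp terms vanish
        p = clarke_glew_pressure(THC, THC.theta)
        assert p == pytest.approx(THC.p0 * math.exp(-THC.dvap_g * 1e3 / (R * THC.theta)))

    @pytest.mark.parametrize(
        "params, T, published",
        [
            (THC, 307.15, 4.9e-5),
            (THC, 310.15, 7.7e-5),
            (CBD, 307.15, 1.0e-4),
            (CBD, 310.15, 1.6e-4),
            (CBN, 310.15, 3.6e-5),
        ],
    )
    def test_breath_and_body_temperature_values(self, params, T, published):
        assert round_sig(clarke_glew_pressure(params, T), 2) == pytest.approx(published)

    @pytest.mark.parametrize("params", [THC, CBD, CBN], ids=["THC", "CBD", "CBN"])
    def test_strictly_increasing_in_temperature(self, params):
        T = np.linspace(280.0, 430.0, 301)
        p = clarke_glew_pressure(params, T)
        assert np.all(np.diff(p) > 0)

    def test_rejects_non_positive_temperature(self):
        with pytest.raises(ValueError):
            clarke_glew_pressure(THC, 0.0)


class TestEnthalpy:
    def test_reference_identity(self):
        assert vaporization_enthalpy(THC, THC.theta) == pytest.approx(119.00)

    @pytest.mark.parametrize(
        "T, published", [(298.15, 120.4), (398.8, 104.6)], ids=["298K", "meanT"]
    )
    def test_published_kirchhoff_values(self, T, published):
        assert round(vaporization_enthalpy(THC, T), 1) == pytest.approx(published)

    def test_linear_in_temperature_with_cp_slope(self):
        h1 = vaporization_enthalpy(THC, 350.0)
        h2 = vaporization_enthalpy(THC, 351.0)
        assert (h2 - h1) * 1e3 == pytest.approx(THC.dvap_cp, rel=1e-9)


def _synthetic_points(params, temperatures, scale=1.0):
    T = np.asarray(temperatures, float)
    return T, clarke_glew_pressure(params, T) * scale


class TestFit:
    def test_noiseless_recovery_exact(self):
        T, p = _synthetic_points(THC, [374, 384, 394, 404, 414, 424, 420])
        fr = fit_clarke_glew(list(zip(T, p)), dvap_cp=THC.dvap_cp)
        assert fr.params.dvap_g == pytest.approx(THC.dvap_g, rel=1e-9)
        assert fr.params.dvap_h == pytest.approx(THC.dvap_h, rel=1e-9)

    def test_two_points_interpolate_with_zero_residuals(self):
        T, p = _synthetic_points(THC, [380.0, 420.0])
        fr = fit_clarke_glew(list(zip(T, p)), dvap_cp=THC.dvap_cp)
        assert fr.n_used == 2
        assert np.allclose(fr.residuals, 0.0, atol=1e-9)
        assert np.allclose(fr.covariance, 0.0)

    def test_exclusion_filter_counts(self):
        # 14 points, 4 of them pushed below the 0.1 Pa floor
        T_hi, p_hi = _synthetic_points(THC, np.linspace(380, 424, 10))
        T_lo = np.array([350.0, 352.0, 354.0, 356.0])
        p_lo = np.full(4, 0.05)
        T = np.concatenate([T_hi, T_lo])
        p = np.concatenate([p_hi, p_lo])
        fr = fit_clarke_glew(list(zip(T, p)), dvap_cp=THC.dvap_cp)
        assert (fr.n_used, fr.n_excluded) == (10, 4)
        lo, hi = fr.temperature_range
        assert lo <= fr.mean_fit_temperature <= hi

    def test_uniform_pressure_rescaling_shifts_only_gibbs_energy(self):
        c = 3.7
        T, p = _synthetic_points(THC, np.linspace(374, 424, 12))
        base = fit_clarke_glew(list(zip(T, p)), dvap_cp=THC.dvap_cp)
        scaled = fit_clarke_glew(list(zip(T, c * p)), dvap_cp=THC.dvap_cp)
        assert scaled.params.dvap_h == pytest.approx(base.params.dvap_h, rel=1e-9)
        expected_shift = -R * THC.theta * math.log(c) / 1e3  # kJ/mol
        assert scaled.params.dvap_g - base.params.dvap_g == pytest.approx(
            expected_shift, rel=1e-9
        )

    def test_too_few_usable_points_raise(self):
        with pytest.raises(FitError):
            fit_clarke_glew([(400.0, 1.0)], dvap_cp=-157.0)
        with pytest.raises(FitError):
            fit_clarke_glew([(400.0, 0.01), (410.0, 0.02), (420.0, 1.0)], dvap_cp=-157.0)

    def test_equal_temperatures_raise(self):
        with pytest.raises(FitError):
            fit_clarke_glew([(400.0, 1.0), (400.0, 1.1)], dvap_cp=-157.0)

    def test_parameter_recovery_within_three_stderr(self):
        """With 2% multiplicative pressure noise the estimated standard error
        covers the truth at the Gaussian 3-sigma rate (>=99% of seeded trials)."""
        rng = np.random.default_rng(20260919)
        T = np.tile([364, 374, 384, 394, 404, 414, 424.0], 6)
        p_true = clarke_glew_pressure(THC, T)
        hits = 0
        n_trials = 500
        for _ in range(n_trials):
            p = p_true * (1.0 + rng.normal(0.0, 0.02, T.size))
            fr = fit_clarke_glew(list(zip(T, np.clip(p, 1e-12, None))), dvap_cp=THC.dvap_cp)
            if abs(fr.params.dvap_h - THC.dvap_h) <= 3 * fr.stderr_dvap_h:
                hits += 1
        assert hits / n_trials >= 0.99


class TestRegressorAPI:
    def test_sklearn_clone_and_params_roundtrip(self):
        reg = ClarkeGlewRegressor(dvap_cp=-157.0, exclusion_threshold=0.05)
        cloned = clone(reg)
        assert cloned.get_params() == reg.get_params()
        cloned.set_params(exclusion_threshold=0.2)
        assert cloned.exclusion_threshold == 0.2

    def test_fit_predict_column_vector(self):
        T, p = _synthetic_points(THC, [374, 384, 394, 404, 414, 424])
        reg = ClarkeGlewRegressor(dvap_cp=THC.dvap_cp).fit(T.reshape(-1, 1), p)
        pred = reg.predict(np.array([[390.0], [410.0]]))
        assert pred.shape == (2,)
        assert np.allclose(pred, clarke_glew_pressure(THC, [390.0, 410.0]), rtol=1e-9)

    def test_cp_gas_feeds_chickos_when_dvap_cp_absent(self):
        T, p = _synthetic_points(THC, [374, 394, 414])
        reg = ClarkeGlewRegressor(cp_gas=407.3).fit(T, p)
        assert reg.dvap_cp_ == pytest.approx(chickos_heat_capacity(407.3))

    def test_missing_curvature_term_raises(self):
        with pytest.raises(FitError):
            ClarkeGlewRegressor().fit([374.0, 394.0], [1.0, 2.0])


class TestExtrapolate:
    def test_empty_temperature_list(self):
        table = extrapolate(THC, [])
        assert table.empty

    def test_flags_points_outside_fitted_range(self):
        table = extrapolate(THC, [307.15, 400.0], fitted_range=(374.0, 424.0))
        assert table["extrapolated"].tolist() == [True, False]
        assert table["p_corr_Pa"].iloc[0] == pytest.approx(
            clarke_glew_pressure(THC, 307.15)
        )
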