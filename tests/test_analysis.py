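"""Model analyses: control coefficients, EC50 extraction, Hill fits,
regressions."""

import numpy as np
import pandas as pd
import pytest

from hepg1s.analysis import (
    cdk2_cdk4_fold_excess,
    dose_response,
    finite_difference_control,
    fit_hill4,
    half_maximum_dose,
    rank_sensitivities,
    regress_components_vs_proliferation,
    response_surface,
)
from hepg1s.parameters import ParameterSet
from hepg1s.synth import HillSpec


class TestAbundanceArithmetic:
    def test_cdk2_excess_over_cdk4_rounds_to_seven(self):
        assert round(cdk2_cdk4_fold_excess()) == 7

    def test_custom_concentrations(self):
        assert cdk2_cdk4_fold_excess(10.0, 2.0) == pytest.approx(5.0)


PSET = ParameterSet(values={"a": 2.0, "b": 3.0}, free=("a", "b"))


class TestControlCoefficients:
    def test_inert_parameter_has_zero_control(self):
        assert finite_difference_control(lambda p: 7.0, PSET, "a", 1.1) == 0.0

    def test_multiplicative_parameter_has_unit_control(self):
        for f in (0.9, 1.1, 1.5):
            c = finite_difference_control(lambda p: 4.2 * p["a"], PSET, "a", f)
            assert c == pytest.approx(1.0)

    def test_quadratic_parameter_at_ten_percent_increase(self):
        c = finite_difference_control(lambda p: 0.3 * p["a"] ** 2, PSET, "a", 1.1)
        assert c == pytest.approx(2.1)

    def test_zero_reference_response_rejected(self):
        with pytest.raises(ZeroDivisionError):
            finite_difference_control(lambda p: 0.0, PSET, "a", 1.1)


class TestRanking:
    def _table(self, rows):
        return pd.DataFrame(
            [{"parameter": p, "member": m, "factor": 1.1, "coefficient": c}
             for p, m, c in rows]
        )

    def test_single_parameter_table_returns_itself(self):
        t = self._table([("a", 0, 0.5)])
        ranked = rank_sensitivities(t, "basal-increase")
        assert list(ranked["parameter"]) == ["a"]

    def test_hand_built_ordering(self):
        t = self._table([("a", 0, 0.2), ("b", 0, 0.9), ("c", 0, 0.5)])
        ranked = rank_sensitivities(t, "basal-increase")
        assert list(ranked["parameter"]) == ["b", "c", "a"]

    def test_sign_filter_excludes_wrong_direction(self):
        t = self._table([("up", 0, 0.4), ("down", 0, -0.8)])
        basal = rank_sensitivities(t, "basal-increase")
        stim = rank_sensitivities(t, "stimulated-decrease")
        assert list(basal["parameter"]) == ["up"]
        assert list(stim["parameter"]) == ["down"]


class TestHalfMaximumDose:
    def test_analytic_hill_self_consistency(self):
        doses = np.geomspace(0.01, 500, 400)
        hill = HillSpec(base=0.2, amp=1.0, k=5.0, n=2.0)
        ec = half_maximum_dose(doses, hill(doses))
        assert ec == pytest.approx(5.0, abs=1e-3)

    def test_interpolation_matches_dense_grid_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.uniform(1, 50)
            n = rng.uniform(0.8, 4)
            base = rng.uniform(0, 1)
            amp = rng.uniform(0.5, 3)
            hill = HillSpec(base=base, amp=amp, k=k, n=n)
            coarse = np.geomspace(0.05, 400, 15)
            dense = np.geomspace(0.05, 400, 20000)
            ec_coarse = half_maximum_dose(coarse, hill(coarse))
            y = hill(dense)
            half = y.min() + 0.5 * (y.max() - y.min())
            ec_dense = dense[np.argmax(y >= half)]
            # agreement within one coarse grid step (log spacing ratio)
            step = (400 / 0.05) ** (1 / 14)
            assert ec_dense / step <= ec_coarse <= ec_dense * step

    def test_flat_curve_undefined(self):
        doses = np.geomspace(0.1, 100, 10)
        assert np.isnan(half_maximum_dose(doses, np.full(10, 3.0)))

    def test_invariant_under_response_rescaling(self):
        doses = np.geomspace(0.1, 300, 30)
        hill = HillSpec(base=0.1, amp=2.0, k=12.0, n=1.5)
        y = hill(doses)
        assert half_maximum_dose(doses, y) == pytest.approx(
            half_maximum_dose(doses, 37.0 * y)
        )


class TestDoseResponseConsistency:
    def test_at72h_response_equals_surface_along_dose_path(self, network, truth):
        """The two-input activity surface evaluated on the HGF dose path
        must reproduce the one-dimensional dose response at 72 h."""
        doses = np.array([0.0, 4.0, 40.0])
        dr = dose_response(network, [truth], doses, ["pcdk2_t160"],
                           response_def="at-72h")
        from hepg1s.inputs import evaluate_inputs
        from hepg1s.analysis import _simulate_clamped
        from hepg1s.simulate import ExperimentProtocol, compute_observables

        ip = truth.input_params()
        proto = ExperimentProtocol(hgf_dose=0.0, t_end=72.0)
        for j, d in enumerate(doses):
            s = evaluate_inputs(float(d), ip)
            tr = _simulate_clamped(network, truth, proto,
                                   {"erk": s.erk, "akt": s.akt}, np.array([72.0]))
            val = compute_observables(tr, network, truth)["pcdk2_t160"][0]
            assert val == pytest.approx(dr["pcdk2_t160"].responses[0, j], rel=1e-5)

    def test_surface_validates_axes_and_grid(self, network, truth):
        with pytest.raises(ValueError):
            response_surface(network, truth, "erk", "nonsense", np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            response_surface(network, truth, "erk", "akt", np.array([0.0, 1.5]))


class TestHillFit:
    def test_noiseless_recovery(self):
        x = np.geomspace(0.5, 512, 12)
        y = HillSpec(base=1.0, amp=1.0, k=32.0, n=6.0)(x)
        fit = fit_hill4(x, y)
        assert fit.k == pytest.approx(32.0, rel=1e-3)

    def test_constant_data_flagged_flat(self):
        x = np.geomspace(1, 100, 8)
        fit = fit_hill4(x, np.full(8, 2.0))
        assert fit.flat
        assert np.isnan(fit.k)

    def test_decreasing_curve_negative_amplitude(self):
        x = np.geomspace(0.5, 100, 15)
        y = 2.0 - 1.5 * x**2 / (10.0**2 + x**2)
        fit = fit_hill4(x, y)
        assert fit.amp < 0
        assert fit.k == pytest.approx(10.0, rel=1e-3)

    def test_noisy_recovery_median_error_below_five_percent(self):
        """100 noisy curves (10% proportional noise): median relative
        inflection error stays below 5%."""
        rng = np.random.default_rng(3)
        x = np.geomspace(0.5, 512, 97)
        truth_curve = HillSpec(base=1.0, amp=1.0, k=32.0, n=6.0)(x)
        errs = []
        for i in range(100):
            y = truth_curve * (1 + 0.1 * rng.standard_normal(x.size))
            fit = fit_hill4(x, y, seed=i)
            errs.append(abs(fit.k - 32.0) / 32.0)
        assert np.median(errs) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill4(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))


class TestRegression:
    def test_collinear_data_unit_r_squared(self):
        comp = {"x": np.array([1.0, 2.0, 3.0, 4.0])}
        out = regress_components_vs_proliferation(comp, 3 * comp["x"] - 1)
        assert out["r_squared"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(4)
        x = rng.random(20)
        y = x + rng.normal(0, 0.2, 20)
        single = regress_components_vs_proliferation({"x": x}, y, m_tests=1)
        nine = regress_components_vs_proliferation({"x": x}, y, m_tests=9)
        p = single["p_value"].iloc[0]
        assert nine["p_adjusted"].iloc[0] == pytest.approx(min(1.0, 9 * p))

    def test_ols_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.random(30)
        y = rng.random(30)
        out = regress_components_vs_proliferation({"x": x}, y)
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert out["intercept"].iloc[0] == pytest.approx(beta[0], abs=1e-10)
        assert out["slope"].iloc[0] == pytest.approx(beta[1], abs=1e-10)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            regress_components_vs_proliferation(
                {"x": np.array([1.0, 2.0])}, np.array([1.0, 2.0, 3.0])
            )
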