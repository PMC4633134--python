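"""Growth-curve forms: evaluation identities, fitting, model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cottonlai import (
    MODEL_FORMS,
    RLAIGrowthModel,
    ValidationError,
    compare,
    datasets,
    evaluate,
    fit_form,
    universal_lai,
)

REF_PARAMS = datasets.growth_curve_parameters()


class TestEvaluate:
    def test_peak_values_of_reference_fits(self):
        mg = REF_PARAMS["modified_gaussian"]
        assert evaluate("modified_gaussian", mg, mg["a"]) == pytest.approx(0.9968)
        ln = REF_PARAMS["log_normal"]
        assert evaluate("log_normal", ln, ln["a"]) == pytest.approx(1.0298)

    def test_modified_logistic_near_unity_at_observed_peak(self):
        ml = REF_PARAMS["modified_logistic"]
        assert evaluate("modified_logistic", ml, 1639.0) == pytest.approx(1.0, abs=0.02)

    def test_log_normal_rejects_nonpositive_gdd(self):
        with pytest.raises(ValidationError):
            evaluate("log_normal", REF_PARAMS["log_normal"], 0.0)

    def test_unknown_form(self):
        with pytest.raises(ValidationError):
            evaluate("gompertz", {}, 1.0)

    @given(
        st.floats(0.6, 1.4),
        st.floats(800, 2400),
        st.floats(100, 2000),
        st.floats(0.6, 8.0),
        st.floats(1, 1000),
    )
    def test_peak_identity_and_symmetry(self, amp, a, b, c, delta):
        """Peak forms attain exactly their amplitude at gdd = a; the
        Gaussian family is symmetric about the peak."""
        mg = {"amplitude": amp, "a": a, "b": b, "c": c}
        assert evaluate("modified_gaussian", mg, a) == amp
        g = {"amplitude": amp, "a": a, "b": b}
        assert evaluate("gaussian", g, a) == amp
        if a - delta > 0:
            for form, p in (("gaussian", g), ("modified_gaussian", mg)):
                assert evaluate(form, p, a + delta) == pytest.approx(
                    evaluate(form, p, a - delta), rel=1e-9
                )

    @given(st.floats(0.6, 1.4), st.floats(800, 2400), st.floats(100, 2000))
    def test_modified_gaussian_c2_equals_gaussian(self, amp, a, b):
        grid = np.linspace(100, 3000, 23)
        mg = evaluate("modified_gaussian", {"amplitude": amp, "a": a, "b": b, "c": 2.0}, grid)
        ga = evaluate("gaussian", {"amplitude": amp, "a": a, "b": b}, grid)
        np.testing.assert_allclose(mg, ga, rtol=1e-12)


class TestFit:
    def test_generate_and_refit_modified_gaussian(self, mean_curve):
        """Noiseless data from a known curve is recovered to 0.1%."""
        g, _ = mean_curve
        truth = {"amplitude": 0.9968, "a": 1772.978, "b": 928.9753, "c": 4.4947}
        y = evaluate("modified_gaussian", truth, g)
        fit = fit_form("modified_gaussian", g, y, random_state=0)
        for name, true in truth.items():
            assert fit.params_[name] == pytest.approx(true, rel=1e-3)
        assert fit.metrics_.rmse < 1e-6

    def test_fit_on_reference_means_beats_printed_parameterization(self, mean_curve):
        g, y = mean_curve
        fit = fit_form("modified_gaussian", g, y, random_state=0)
        assert fit.metrics_.rmse <= 0.010

    def test_cubic_is_exact_on_cubic_data(self):
        g = np.linspace(100, 2500, 9)
        truth = {"a0": -0.65, "a1": 2.1e-3, "a2": -7.7e-7, "a3": 6.8e-11}
        fit = fit_form("cubic_polynomial", g, evaluate("cubic_polynomial", truth, g))
        for name, true in truth.items():
            assert fit.params_[name] == pytest.approx(true, rel=1e-8)

    def test_underdetermined_fit_raises(self):
        with pytest.raises(ValidationError):
            fit_form("modified_gaussian", [1, 2, 3], [0.1, 0.5, 1.0])

    def test_fit_is_deterministic_per_seed(self, mean_curve):
        g, y = mean_curve
        a = fit_form("log_normal", g, y, random_state=3)
        b = fit_form("log_normal", g, y, random_state=3)
        assert a.params_ == b.params_

    def test_refit_of_own_predictions_is_idempotent(self, mean_curve):
        g, y = mean_curve
        first = fit_form("log_normal", g, y, random_state=0)
        second = fit_form("log_normal", g, first.predict(g), random_state=0)
        for name in first.params_:
            assert second.params_[name] == pytest.approx(first.params_[name], rel=1e-4)


class TestCompare:
    def test_printed_parameterizations_rank_gaussian_last(self, mean_curve):
        g, y = mean_curve
        fits = [RLAIGrowthModel.from_parameters(f, p) for f, p in REF_PARAMS.items()]
        table = compare(fits, observed_gdd=g, observed_rlai=y)
        assert table["form"].iloc[-1] == "gaussian"
        assert table["rmse"].iloc[-1] == pytest.approx(0.1113, abs=0.01)

    def test_single_fit_and_tie_break(self, mean_curve):
        g, y = mean_curve
        fit = fit_form("gaussian", g, y)
        assert len(compare([fit])) == 1
        twins = compare([fit, fit])
        assert twins["form"].tolist() == ["gaussian", "gaussian"]
        assert twins["rank"].tolist() == [1, 2]  # tie kept in input order

    def test_refit_ranking_matches_published_ordering(self, mean_curve):
        g, y = mean_curve
        fits = [fit_form(f, g, y, random_state=0) for f in MODEL_FORMS]
        ranked = compare(fits)["form"].tolist()
        assert set(ranked[:2]) == {"modified_gaussian", "modified_logistic"}
        assert ranked[2:] == ["log_normal", "cubic_polynomial", "gaussian"]


class TestUniversalLAI:
    def test_is_scaled_relative_curve(self):
        fit = RLAIGrowthModel.from_parameters("modified_gaussian", REF_PARAMS["modified_gaussian"])
        peak_gdd, amp = fit.peak()
        assert universal_lai(fit, 2.70, peak_gdd) == pytest.approx(2.70 * amp)

    def test_reference_logistic_curve_scales_to_lai_m(self):
        fit = RLAIGrowthModel.from_parameters(
            "modified_logistic", REF_PARAMS["modified_logistic"]
        )
        value = universal_lai(fit, 2.47, 1639.0)
        assert value == pytest.approx(2.47 * 1.0, rel=0.02)

    def test_nonpositive_lai_m_raises(self):
        fit = RLAIGrowthModel.from_parameters("gaussian", REF_PARAMS["gaussian"])
        with pytest.raises(ValidationError):
            universal_lai(fit, 0.0, 1000.0)
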