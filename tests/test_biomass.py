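"""Saturating LAI-dry-matter link, harvest index, yield prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cottonlai import (
    MichaelisMentenRelation,
    ValidationError,
    YieldModel,
    datasets,
    fit_mm,
    harvest_index,
    mean_hi,
)

P_REF, Q_REF = datasets.mm_parameters()
REF_MM = MichaelisMentenRelation.from_parameters(P_REF, Q_REF)


def _exact_points(p, q, masses):
    return [(m, p * m / (1 + q * m)) for m in masses]


class TestMMFit:
    @pytest.mark.parametrize("p, q", [(2.0, 0.5), (P_REF, Q_REF)])
    def test_generate_and_refit(self, p, q):
        mm = fit_mm(_exact_points(p, q, [0.1, 0.2, 0.4, 0.8]))
        assert mm.p_ == pytest.approx(p, rel=1e-10)
        assert mm.q_ == pytest.approx(q, rel=1e-10)

    def test_two_points_interpolate(self):
        mm = fit_mm(_exact_points(3.0, 1.0, [0.2, 0.5]))
        assert mm.p_ == pytest.approx(3.0, rel=1e-9)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValidationError):
            fit_mm([(0.0, 1.0), (0.2, 1.5)])

    def test_nonlinear_method_agrees_on_exact_data(self):
        mm = fit_mm(_exact_points(P_REF, Q_REF, [0.1, 0.25, 0.4]), method="nonlinear")
        assert mm.p_ == pytest.approx(P_REF, rel=1e-6)
        assert mm.q_ == pytest.approx(Q_REF, rel=1e-6)


class TestMMEvaluation:
    def test_origin_and_asymptote(self):
        assert REF_MM.predict(0.0) == 0.0
        assert REF_MM.predict(1e9) == pytest.approx(P_REF / Q_REF, rel=1e-6)
        assert REF_MM.asymptote_ == pytest.approx(6.211, abs=0.01)

    @pytest.mark.parametrize("lai_m, expected", [(2.28, 0.355), (2.29, 0.358), (0.0, 0.0)])
    def test_dry_matter_inversion(self, lai_m, expected):
        assert REF_MM.dry_matter(lai_m) == pytest.approx(expected, abs=1e-3)

    def test_beyond_asymptote_raises(self):
        with pytest.raises(ValidationError):
            REF_MM.dry_matter(REF_MM.asymptote_)

    @given(st.floats(0.0, 6.2))
    def test_round_trip_identity(self, lai_m):
        """predict(dry_matter(x)) == x to 1e-10 below the asymptote."""
        if lai_m < REF_MM.asymptote_:
            assert REF_MM.predict(REF_MM.dry_matter(lai_m)) == pytest.approx(
                lai_m, abs=1e-10
            )


class TestHarvestIndex:
    def test_reference_row_and_closed_forms(self):
        assert harvest_index(0.4440, 0.8480) == pytest.approx(0.5236, abs=1e-4)
        assert harvest_index(1, 2) == 0.5
        with pytest.raises(ValidationError):
            harvest_index(2, 2)

    def test_mean_hi_reference_table(self, biomass_table):
        mean, sd = mean_hi(biomass_table["harvest_index"])
        assert round(mean, 4) == 0.5148
        assert round(sd, 4) == 0.0115

    def test_mean_hi_closed_form(self):
        mean, sd = mean_hi([0.5, 0.6])
        assert mean == pytest.approx(0.55)
        assert sd == pytest.approx(0.0707, abs=1e-4)
        assert mean_hi([0.5, 0.5, 0.5])[1] == 0.0

    def test_reference_table_identities(self, biomass_table):
        """Total biomass and HI columns are internally consistent."""
        np.testing.assert_allclose(
            biomass_table["total_biomass"],
            biomass_table["dry_biomass"] + biomass_table["yield_"],
            atol=1e-4,
        )
        np.testing.assert_allclose(
            biomass_table["harvest_index"],
            biomass_table["yield_"] / biomass_table["total_biomass"],
            atol=1e-4,
        )


class TestYieldModel:
    def test_half_hi_equals_dry_matter(self):
        model = YieldModel(0.5, REF_MM)
        assert model.predict(2.0) == pytest.approx(REF_MM.dry_matter(2.0))

    def test_reference_yield_predictions(self):
        model = YieldModel(datasets.reference_harvest_index(), REF_MM)
        assert model.predict(2.29) == pytest.approx(0.380, abs=0.004)
        assert model.predict(1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_matches_display_closed_form(self):
        """The folded-constant display form 0.5148*L/(4.9159-0.7915*L)
        agrees with the two-step model within 0.5% over the working range."""
        model = YieldModel(0.5148, REF_MM)
        for lai_m in np.linspace(1.0, 3.0, 21):
            display = 0.5148 * lai_m / (4.9159 - 0.7915 * lai_m)
            assert model.predict(lai_m) == pytest.approx(display, rel=5e-3)

    def test_strictly_increasing_in_lai_m(self):
        model = YieldModel(0.5148, REF_MM)
        grid = np.linspace(0.1, 6.0, 60)
        values = [model.predict(l) for l in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_hi(self):
        with pytest.raises(ValidationError):
            YieldModel(1.0, REF_MM)
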