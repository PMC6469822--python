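"""Unit-dose spray simulator: exact degenerate cases, route ordering,
dose linearity, pass/distance structure, 2D (uncertainty) variant."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from aggexpo.config import ConfigurationError, ScenarioSettings
from aggexpo.spray import (
    product_dose_rate,
    rescale_standard_dose,
    simulate_unit_dose,
    simulate_unit_dose_with_uncertainty,
)


def degenerate_settings(**overrides):
    base = dict(
        scenario_class="arable",
        n_passes=1,
        distance_range_m=(10.0, 10.0),
        drift_coefficient=1.0,
        drift_exponent=1.0,
        route_fractions=(0.9, 0.05, 0.001),  # dermal, inhalation, oral
        wind_speed_cv=0.0,
        averaging_days=90,
    )
    base.update(overrides)
    return ScenarioSettings(**base)


class TestDoseArithmetic:
    def test_unit_dose_from_product(self):
        assert product_dose_rate(250, 4) == 1.0

    def test_standard_bream_dose(self):
        assert product_dose_rate(1, 200) == pytest.approx(0.2)


class TestSimulateUnitDose:
    def test_degenerate_exact_triple(self):
        """Point-mass distance and wind give the closed-form triple
        route_fractions / (distance x averaging_days) for unit drift."""
        triples = simulate_unit_dose(degenerate_settings(), n=50, seed=0)
        np.testing.assert_allclose(triples["dermal"], 0.9 / (10 * 90), rtol=1e-12)
        np.testing.assert_allclose(triples["inhalation"], 0.05 / (10 * 90), rtol=1e-12)
        np.testing.assert_allclose(triples["oral"], 0.001 / (10 * 90), rtol=1e-12)

    def test_route_ordering_over_draws(self):
        """Dermal contributes most, inhalation less, oral least."""
        triples = simulate_unit_dose(ScenarioSettings(), n=10_000, seed=1)
        assert triples["dermal"].mean() > triples["inhalation"].mean() > triples["oral"].mean()

    def test_later_passes_contribute_less(self):
        """Pass p=1 sits 24 m further away, so its deposition is strictly
        smaller than pass p=0 for every draw."""
        one = simulate_unit_dose(
            dataclasses.replace(ScenarioSettings(), n_passes=1), n=500, seed=2
        )
        two = simulate_unit_dose(
            dataclasses.replace(ScenarioSettings(), n_passes=2), n=500, seed=2
        )
        second_pass = two["dermal"] - one["dermal"]
        assert (second_pass > 0).all()
        assert (second_pass < one["dermal"]).all()

    def test_all_nonnegative_and_correlated(self):
        triples = simulate_unit_dose(ScenarioSettings(), n=5000, seed=3)
        assert (triples[["dermal", "oral", "inhalation"]] >= 0).all().all()
        # routes share the distance/wind draw: perfectly rank-correlated
        corr = triples["dermal"].corr(triples["oral"], method="spearman")
        assert corr == pytest.approx(1.0)

    def test_monotone_in_distance(self):
        """Conditional on the same wind draw, closer residents dominate."""
        near = simulate_unit_dose(
            degenerate_settings(distance_range_m=(5.0, 5.0), wind_speed_cv=0.3),
            n=300, seed=4,
        )
        far = simulate_unit_dose(
            degenerate_settings(distance_range_m=(15.0, 15.0), wind_speed_cv=0.3),
            n=300, seed=4,
        )
        for col in ("dermal", "oral", "inhalation"):
            assert (near[col] > far[col]).all()

    def test_halving_averaging_days_doubles_exposure(self):
        a = simulate_unit_dose(degenerate_settings(averaging_days=90), 100, seed=5)
        b = simulate_unit_dose(degenerate_settings(averaging_days=45), 100, seed=5)
        np.testing.assert_allclose(b["dermal"], 2 * a["dermal"], rtol=1e-12)

    def test_three_vs_twelve_month_factor_four(self):
        a = simulate_unit_dose(degenerate_settings(averaging_days=90), 100, seed=5)
        b = simulate_unit_dose(degenerate_settings(averaging_days=360), 100, seed=5)
        np.testing.assert_allclose(a["dermal"], 4 * b["dermal"], rtol=1e-12)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            simulate_unit_dose(ScenarioSettings(), n=0, seed=0)


class TestRescale:
    def test_bream_to_browse_factor_five(self):
        t = simulate_unit_dose(ScenarioSettings(), 100, seed=6)
        out = rescale_standard_dose(t, standard_dose=0.2, target_dose=1.0)
        np.testing.assert_allclose(out["dermal"], 5 * t["dermal"], rtol=1e-12)

    def test_identity_and_ratio(self):
        t = simulate_unit_dose(ScenarioSettings(), 10, seed=6)
        pd.testing.assert_frame_equal(rescale_standard_dose(t, 1.0, 1.0), t)
        out = rescale_standard_dose(t, 0.5, 2.0)
        np.testing.assert_allclose(out["oral"], 4 * t["oral"], rtol=1e-12)

    def test_invalid_standard_dose(self):
        t = simulate_unit_dose(ScenarioSettings(), 10, seed=6)
        with pytest.raises(ValueError):
            rescale_standard_dose(t, 0.0, 1.0)

    def test_rescale_commutes_with_simulation(self):
        """Exposure is exactly linear in dose: rescaling unit-dose triples
        equals simulating with a proportionally larger drift source."""
        s = ScenarioSettings()
        t1 = rescale_standard_dose(simulate_unit_dose(s, 200, seed=7), 1.0, 3.0)
        s2 = dataclasses.replace(s, drift_coefficient=3 * s.drift_coefficient)
        t2 = simulate_unit_dose(s2, 200, seed=7)
        np.testing.assert_allclose(t1["dermal"], t2["dermal"], rtol=1e-12)


class TestUncertaintyVariant:
    def test_degenerate_collapses_to_plain(self):
        s = dataclasses.replace(
            ScenarioSettings(),
            drift_coefficient_uncertainty_cv=0.0,
            drift_exponent_uncertainty_cv=0.0,
        )
        two_d = simulate_unit_dose_with_uncertainty(s, n=100, n_uncertainty=1, seed=8)
        plain = simulate_unit_dose(s, n=100, seed=8)
        np.testing.assert_allclose(two_d["dermal"], plain["dermal"], rtol=1e-12)

    def test_dimensions(self):
        s = ScenarioSettings()
        out = simulate_unit_dose_with_uncertainty(s, n=1000, n_uncertainty=100, seed=9)
        assert len(out) == 100 * 1000
        assert out["uncertainty_id"].nunique() == 100

    def test_between_realisation_variance_positive(self):
        s = ScenarioSettings()  # non-degenerate uncertainty CVs by default
        out = simulate_unit_dose_with_uncertainty(s, n=200, n_uncertainty=20, seed=10)
        means = out.groupby("uncertainty_id")["dermal"].mean()
        assert means.var() > 0


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"route_fractions": (0.1, 0.5, 0.01)},   # inhalation > dermal
            {"route_fractions": (0.9, 0.01, 0.05)},  # oral > inhalation
            {"distance_range_m": (20.0, 2.0)},
            {"n_passes": 0},
            {"drift_coefficient": -1.0},
            {"wind_speed_cv": -0.1},
        ],
    )
    def test_invalid_settings(self, kw):
        with pytest.raises(ConfigurationError):
            ScenarioSettings(**kw)

    def test_orchard_preset_has_no_pass_structure(self):
        s = ScenarioSettings.orchard()
        assert s.n_passes == 1
        assert s.drift_coefficient > ScenarioSettings.arable().drift_coefficient
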