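"""RPFs, dietary OIM, probabilistic linking and aggregation arithmetic."""

import numpy as np
import pandas as pd
import pytest

from aggexpo.aggregate import (
    aggregate,
    compute_dietary_oim,
    compute_rpf,
    link_nondietary,
    population_percentiles,
    route_contributions,
)
from aggexpo.nondietary import NonDietarySurveySet


def compound_table(rows):
    return pd.DataFrame(rows, columns=[
        "compound", "noael_mg_kg_bw_day", "loael_mg_kg_bw_day", "is_reference"
    ])


def diary(rows):
    return pd.DataFrame(rows, columns=[
        "individual_id", "bodyweight_kg", "day", "food", "amount_g"
    ])


def conc(rows):
    return pd.DataFrame(rows, columns=[
        "sample_id", "food", "compound", "concentration_mg_kg", "nondetect"
    ])


def survey_set(records, weights):
    df = pd.DataFrame(records, columns=[
        "idIndividual", "idSurvey", "compound",
        "Dermal", "Oral", "Inhalation", "idUncertaintySet",
    ])
    return NonDietarySurveySet(
        df, {s: 1 - w for s, w in weights.items()}, dict(weights)
    )


class TestRPF:
    def test_reference_is_one_and_ratios(self):
        tab = compound_table([
            ("ref", 5.0, 15.0, 1),
            ("j", 50.0, np.nan, 0),
            ("k", np.nan, 30.0, 0),
        ])
        rpf = compute_rpf(tab, "ref")
        assert rpf.rpf["ref"] == 1.0
        assert rpf.rpf["j"] == pytest.approx(0.1)     # 5 / 50
        assert rpf.rpf["k"] == pytest.approx(0.5)     # 5 / (30/3)
        assert rpf.provenance == {"ref": "NOAEL", "j": "NOAEL", "k": "LOAEL3"}

    def test_common_scaling_invariance(self):
        tab = compound_table([("ref", 5.0, np.nan, 1), ("j", 50.0, np.nan, 0)])
        scaled = tab.copy()
        scaled["noael_mg_kg_bw_day"] *= 7.0
        assert compute_rpf(tab, "ref").rpf == compute_rpf(scaled, "ref").rpf

    def test_compound_without_limits_rejected(self):
        tab = compound_table([("ref", 5.0, np.nan, 1), ("bad", np.nan, np.nan, 0)])
        with pytest.raises(ValueError, match="bad"):
            compute_rpf(tab, "ref")

    def test_reference_needs_noael(self):
        tab = compound_table([("ref", np.nan, 15.0, 1)])
        with pytest.raises(ValueError, match="NOAEL"):
            compute_rpf(tab, "ref")


class TestDietaryOIM:
    def test_all_nondetect_gives_zero(self):
        d = diary([("i1", 60.0, 1, "apple", 100.0), ("i1", 60.0, 2, "apple", 50.0)])
        c = conc([("s1", "apple", "X", 0.0, 1), ("s2", "apple", "X", 0.0, 1)])
        expo = compute_dietary_oim(d, c)
        assert (expo.to_numpy() == 0).all()

    def test_unit_arithmetic(self):
        """100 g/day on both days at 0.5 mg/kg, 50 kg bodyweight ->
        1 ug/kg bw/day."""
        d = diary([("i1", 50.0, 1, "apple", 100.0), ("i1", 50.0, 2, "apple", 100.0)])
        c = conc([("s1", "apple", "X", 0.5, 0)])
        expo = compute_dietary_oim(d, c)
        assert expo.loc["i1", "X"] == pytest.approx(1.0)

    def test_doubling_bodyweight_halves_exposure(self):
        rows = [("i1", 50.0, 1, "apple", 100.0), ("i2", 100.0, 1, "apple", 100.0),
                ("i1", 50.0, 2, "apple", 100.0), ("i2", 100.0, 2, "apple", 100.0)]
        c = conc([("s1", "apple", "X", 0.5, 0)])
        expo = compute_dietary_oim(diary(rows), c)
        assert expo.loc["i2", "X"] == pytest.approx(expo.loc["i1", "X"] / 2)

    def test_uncovered_food_rejected(self):
        d = diary([("i1", 60.0, 1, "pear", 10.0), ("i1", 60.0, 2, "pear", 0.0)])
        c = conc([("s1", "apple", "X", 0.5, 0)])
        with pytest.raises(ValueError, match="pear"):
            compute_dietary_oim(d, c)

    def test_mean_over_all_survey_days(self):
        """A day without consumption still counts in the OIM denominator."""
        d = diary([("i1", 50.0, 1, "apple", 100.0), ("i1", 50.0, 2, "apple", 0.0)])
        c = conc([("s1", "apple", "X", 0.5, 0)])
        expo = compute_dietary_oim(d, c)
        assert expo.loc["i1", "X"] == pytest.approx(0.5)


class TestLinking:
    def base_diary(self, n):
        return diary([(f"i{k}", 60.0, 1, "apple", 10.0) for k in range(n)])

    def test_zero_weights_nobody_linked(self):
        ss = survey_set([("w1", "wheat", "X", 1, 0, 0, 0)], {"wheat": 0.0})
        link = link_nondietary(self.base_diary(50), ss, seed=0)
        assert link["survey_id"].isna().all()

    def test_determinism(self):
        ss = survey_set([("w1", "wheat", "X", 1, 0, 0, 0)], {"wheat": 0.5})
        a = link_nondietary(self.base_diary(100), ss, seed=3)
        b = link_nondietary(self.base_diary(100), ss, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_weights_above_one_rejected(self):
        ss = survey_set([("w1", "wheat", "X", 1, 0, 0, 0)], {"wheat": 1.2})
        with pytest.raises(ValueError, match="> 1"):
            link_nondietary(self.base_diary(10), ss, seed=0)

    def test_linked_fraction_binomial(self):
        """Over replicates, the linked count concentrates on n x p."""
        ss = survey_set(
            [("w1", "wheat", "X", 1, 0, 0, 0), ("w2", "wheat", "X", 2, 0, 0, 0)],
            {"wheat": 0.3},
        )
        d = self.base_diary(200)
        counts = [
            link_nondietary(d, ss, seed=s)["survey_id"].notna().sum()
            for s in range(40)
        ]
        se = np.sqrt(200 * 0.3 * 0.7)
        assert abs(np.mean(counts) - 60.0) < 3 * se / np.sqrt(40)


class TestAggregation:
    def setup_case(self, linked: bool, absorption=None):
        d = diary([("i1", 60.0, 1, "apple", 0.0), ("i1", 60.0, 2, "apple", 0.0)])
        c = conc([("s1", "apple", "ref", 0.5, 0)])
        expo = compute_dietary_oim(d, c)
        ss = survey_set([("w1", "wheat", "ref", 0.6, 0.0, 0.0, 0)], {"wheat": 1.0})
        link = pd.DataFrame(
            {"survey_id": ["wheat" if linked else None],
             "nd_individual": ["w1" if linked else None]},
            index=pd.Index(["i1"], name="individual_id"),
        )
        rpf = compute_rpf(compound_table([("ref", 5.0, np.nan, 1)]), "ref")
        bw = pd.Series({"i1": 60.0})
        return aggregate(expo, link, ss, rpf, bw, absorption)

    def test_unlinked_equals_dietary(self):
        res = self.setup_case(linked=False)
        assert res.totals["aggregate_total"].equals(res.totals["dietary_total"])

    def test_absorption_zero_equals_dietary(self):
        res = self.setup_case(
            linked=True, absorption={"Dermal": 0.0, "Oral": 0.0, "Inhalation": 0.0}
        )
        assert res.totals["aggregate_total"].equals(res.totals["dietary_total"])

    def test_unit_arithmetic(self):
        """0.6 mg/day dermal at 60 kg, zero diet -> 10 ug/kg bw/day."""
        res = self.setup_case(linked=True)
        assert res.totals["aggregate_total"].iloc[0] == pytest.approx(10.0)
        assert res.totals["dietary_total"].iloc[0] == 0.0

    def test_additivity_per_individual(self, small_survey_set, small_tables, small_config):
        surveys, _, _ = small_survey_set
        rpf = compute_rpf(small_tables["compound"], small_config.reference_compound)
        d = small_tables["dietary_survey"]
        expo = compute_dietary_oim(d, small_tables["concentration"])
        expo = expo.reindex(
            columns=sorted(set(expo.columns) | set(surveys.records["compound"])),
            fill_value=0.0,
        )
        link = link_nondietary(d, surveys, seed=5)
        bw = d.drop_duplicates("individual_id").set_index("individual_id")["bodyweight_kg"]
        res = aggregate(expo, link, surveys, rpf, bw)
        rpf_vec = rpf.series(res.dietary.columns)
        nd_total = sum(
            res.nondietary[r].mul(rpf_vec, axis=1).sum(axis=1)
            for r in ("Dermal", "Oral", "Inhalation")
        )
        np.testing.assert_allclose(
            res.totals["aggregate_total"],
            res.totals["dietary_total"] + nd_total,
            rtol=1e-12,
        )
        # unlinked individuals carry no non-dietary exposure
        unlinked = res.totals["survey_id"].isna()
        assert (nd_total[unlinked] == 0).all()

    def test_missing_bodyweight_rejected(self):
        d = diary([("i1", 60.0, 1, "apple", 0.0), ("i1", 60.0, 2, "apple", 0.0)])
        expo = compute_dietary_oim(d, conc([("s1", "apple", "ref", 0.5, 0)]))
        ss = survey_set([("w1", "wheat", "ref", 1, 0, 0, 0)], {"wheat": 0.0})
        link = link_nondietary(d, ss, 0)
        rpf = compute_rpf(compound_table([("ref", 5.0, np.nan, 1)]), "ref")
        with pytest.raises(ValueError, match="bodyweight"):
            aggregate(expo, link, ss, rpf, pd.Series(dtype=float))


class TestPopulationSummaries:
    def constant_result(self):
        d = diary([("i1", 50.0, 1, "apple", 100.0), ("i1", 50.0, 2, "apple", 100.0),
                   ("i2", 50.0, 1, "apple", 100.0), ("i2", 50.0, 2, "apple", 100.0)])
        c = conc([("s1", "apple", "ref", 0.5, 0)])
        expo = compute_dietary_oim(d, c)
        ss = survey_set([("w1", "wheat", "ref", 1, 0, 0, 0)], {"wheat": 0.0})
        link = link_nondietary(d, ss, 0)
        rpf = compute_rpf(compound_table([("ref", 5.0, np.nan, 1)]), "ref")
        bw = pd.Series({"i1": 50.0, "i2": 50.0})
        return aggregate(expo, link, ss, rpf, bw)

    def test_constant_totals_constant_percentiles(self):
        res = self.constant_result()
        pct = population_percentiles(res, probs=(50, 95, 99))
        np.testing.assert_allclose(pct["dietary"], 1.0)
        np.testing.assert_allclose(pct["aggregate"], 1.0)

    def test_aggregate_dominates_dietary(self, small_survey_set, small_tables, small_config):
        surveys, _, _ = small_survey_set
        rpf = compute_rpf(small_tables["compound"], small_config.reference_compound)
        d = small_tables["dietary_survey"]
        expo = compute_dietary_oim(d, small_tables["concentration"]).reindex(
            columns=sorted(
                set(small_tables["concentration"]["compound"])
                | set(surveys.records["compound"])
            ),
            fill_value=0.0,
        )
        link = link_nondietary(d, surveys, seed=5)
        bw = d.drop_duplicates("individual_id").set_index("individual_id")["bodyweight_kg"]
        res = aggregate(expo, link, surveys, rpf, bw)
        pct = population_percentiles(res)
        assert (pct["aggregate"] >= pct["dietary"]).all()

    def test_uniform_median_analytic(self):
        """P50 of a large uniform sample is 0.5 within 0.01."""
        rng = np.random.default_rng(0)
        vals = rng.random(1_000_000)
        d = pd.DataFrame({
            "bodyweight_kg": 60.0, "dietary_total": vals,
            "aggregate_total": vals, "survey_id": None,
        })
        from aggexpo.aggregate import AggregateResult, RPFMap

        res = AggregateResult(
            dietary=pd.DataFrame({"ref": vals}),
            nondietary={r: pd.DataFrame({"ref": np.zeros_like(vals)})
                        for r in ("Dermal", "Oral", "Inhalation")},
            totals=d,
            rpf=RPFMap("ref", {"ref": 1.0}, {"ref": "NOAEL"}),
        )
        pct = population_percentiles(res, probs=(50,))
        assert abs(pct["dietary"].iloc[0] - 0.5) < 0.01

    def test_empty_results_rejected(self):
        res = self.constant_result()
        res.totals = res.totals.iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            population_percentiles(res)

    def test_route_contributions_sum_to_100(self, small_survey_set, small_tables, small_config):
        surveys, _, _ = small_survey_set
        rpf = compute_rpf(small_tables["compound"], small_config.reference_compound)
        d = small_tables["dietary_survey"]
        expo = compute_dietary_oim(d, small_tables["concentration"]).reindex(
            columns=sorted(
                set(small_tables["concentration"]["compound"])
                | set(surveys.records["compound"])
            ),
            fill_value=0.0,
        )
        link = link_nondietary(d, surveys, seed=5)
        bw = d.drop_duplicates("individual_id").set_index("individual_id")["bodyweight_kg"]
        res = aggregate(expo, link, surveys, rpf, bw)
        table = route_contributions(res)
        assert table["contribution_pct"].sum() == pytest.approx(100.0)
        nd_routes = table[table["route"] != "Dietary"]
        linked = res.totals["survey_id"].notna().sum()
        assert (nd_routes["n_exposed"] <= linked).all()

    def test_dietary_only_contribution_100(self):
        res = self.constant_result()
        table = route_contributions(res)
        dietary = table[table["route"] == "Dietary"].iloc[0]
        assert dietary["contribution_pct"] == pytest.approx(100.0)
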