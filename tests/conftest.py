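import dataclasses

import pytest

from aggexpo.config import CropSpec, FoodSpec, SyntheticConfig


@pytest.fixture(scope="session")
def small_config():
    """A compact study configuration: two crops, few compounds/foods."""
    return SyntheticConfig(
        n_fields_per_crop=40,
        crops=(
            CropSpec("wheat", "arable", resident_count_mean=25.0),
            CropSpec("dessert_apples", "orchard", resident_count_mean=3.0),
        ),
        compounds_per_field_range=(1, 4),
        n_dietary_individuals=150,
        n_survey_days=3,
        foods=tuple(FoodSpec(code=f"F{k:03d}") for k in range(1, 6)),
        n_residue_samples=10,
        n_compounds=8,
        reference_compound="C001",
        seed=42,
    )


@pytest.fixture(scope="session")
def small_tables(small_config):
    from aggexpo.synthetic import generate_all

    return generate_all(small_config)


@pytest.fixture(scope="session")
def small_survey_set(small_config, small_tables):
    """Survey set + processed fields built from the small config."""
    from aggexpo.config import scenario_for
    from aggexpo.nondietary import build_crop_survey, combine_surveys
    from aggexpo.spray import simulate_unit_dose
    from aggexpo.usage import (
        add_dose_rates,
        estimate_resident_proportions,
        impute_missing_residents,
    )

    fields = add_dose_rates(small_tables["field_survey"])
    fields = impute_missing_residents(fields, small_config.seed)
    props = estimate_resident_proportions(fields, 63.2e6, 0.824)
    per_crop = []
    for ci, (crop, grp) in enumerate(fields.groupby("crop", sort=True)):
        settings = scenario_for(grp["scenario_class"].iloc[0])
        triples = simulate_unit_dose(settings, 2000, seed=small_config.seed + ci)
        per_crop.append(
            build_crop_survey(grp, triples, I=200, seed=small_config.seed, crop_key=ci)
        )
    return combine_surveys(per_crop, props), fields, props


@pytest.fixture()
def tiny_config():
    """Degenerate-friendly config for exact-value tests."""
    return SyntheticConfig(
        n_fields_per_crop=5,
        crops=(CropSpec("wheat", "arable"),),
        compounds_per_field_range=(1, 2),
        n_dietary_individuals=10,
        n_survey_days=2,
        foods=(FoodSpec("F001", p_consume=1.0, median_g=100.0, sigma=0.0),),
        n_compounds=3,
        n_residue_samples=5,
        reference_compound="C001",
        seed=1,
    )


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
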