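"""Synthetic study-data generators.

Emulates the four input tables the aggregate assessment consumes: a
stratified field survey of pesticide applications (with raising factors and
nearby-resident counts), a multi-day dietary consumption diary, a residue
concentration table with nondetects, and a compound hazard (NOAEL/LOAEL)
table.  Applied amounts are generated as dose rate x area so dose-rate
derivation has an exact known answer, and resident counts are drawn per field
directly (Poisson) with a missing flag standing in for fields whose postcode
was not recorded.

All generators are deterministic functions of ``config.seed`` via the
package's stream-splitting scheme (:mod:`aggexpo._rng`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .config import SyntheticConfig

FIELD_SURVEY_COLUMNS = [
    "field_id", "survey_id", "crop", "scenario_class", "area_ha",
    "raising_factor", "residents", "compound", "amount_kg",
]
DIETARY_COLUMNS = ["individual_id", "bodyweight_kg", "day", "food", "amount_g"]
CONCENTRATION_COLUMNS = ["sample_id", "food", "compound", "concentration_mg_kg", "nondetect"]
COMPOUND_COLUMNS = ["compound", "noael_mg_kg_bw_day", "loael_mg_kg_bw_day", "is_reference"]


def generate_field_survey(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a long-format field survey table.

    One row per (field, applied compound).  Per field: log-normal area and
    raising factor, Poisson resident count (set to NA for a
    ``postcode_missing_fraction`` share of fields), a uniform number of
    distinct compounds in ``compounds_per_field_range``, and per-compound
    applied amount = log-normal dose rate x area.
    """
    rows = []
    compounds = np.array(config.compound_names())
    lo, hi = config.compounds_per_field_range
    for ci, crop in enumerate(config.crops):
        rng = substream(config.seed, "field_survey", ci)
        n = config.n_fields_per_crop
        if n == 0:
            continue
        areas = config.field_area_distribution.sample(rng, n)
        raising = config.raising_factor_distribution.sample(rng, n)
        res_mean = (
            crop.resident_count_mean
            if crop.resident_count_mean is not None
            else config.resident_count_mean
        )
        residents = rng.poisson(res_mean, size=n).astype(float)
        missing = rng.random(n) < config.postcode_missing_fraction
        residents[missing] = np.nan
        n_comp = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            chosen = rng.choice(compounds, size=n_comp[i], replace=False)
            rates = config.dose_rate_distribution.sample(rng, n_comp[i])
            for comp, rate in zip(chosen, rates):
                rows.append((
                    f"{crop.name}_f{i + 1:05d}", crop.name, crop.name,
                    crop.scenario_class, areas[i], raising[i], residents[i],
                    comp, rate * areas[i],
                ))
    df = pd.DataFrame(rows, columns=FIELD_SURVEY_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=FIELD_SURVEY_COLUMNS)
    return df


def generate_dietary_survey(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a long-format consumption diary.

    One row per (individual, day, food) including zero-consumption rows, so
    every individual appears on all ``n_survey_days`` days.  Bodyweights are
    normal, truncated below at 30 kg.
    """
    rng = substream(config.seed, "dietary_survey")
    n = config.n_dietary_individuals
    ids = [f"ind{k + 1:05d}" for k in range(n)]
    bw = rng.normal(config.bodyweight_mean, config.bodyweight_sd, size=n)
    bw = np.clip(bw, 30.0, None)
    frames = []
    days = np.arange(1, config.n_survey_days + 1)
    for f in config.foods:
        # (individual, day) consumption for this food
        eat = rng.random((n, len(days))) < f.p_consume
        if f.median_g == 0 or f.p_consume == 0:
            amounts = np.zeros((n, len(days)))
        else:
            amounts = f.median_g * rng.lognormal(0.0, f.sigma, size=(n, len(days)))
        amounts = np.where(eat, amounts, 0.0)
        frames.append(pd.DataFrame({
            "individual_id": np.repeat(ids, len(days)),
            "bodyweight_kg": np.repeat(bw, len(days)),
            "day": np.tile(days, n),
            "food": f.code,
            "amount_g": amounts.reshape(-1),
        }))
    if not frames:
        return pd.DataFrame(columns=DIETARY_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["individual_id", "day", "food"], kind="stable").reset_index(drop=True)


def generate_concentration_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate residue monitoring samples for every (food, compound) pair in
    the residue-mean grid, with a Bernoulli(``nondetect_fraction``) nondetect
    flag; nondetect rows carry concentration 0 (optimistic reporting)."""
    rng = substream(config.seed, "concentration")
    grid = config.default_residue_means()
    rows = []
    sid = 0
    for (food, comp), mean in sorted(grid.items()):
        m = config.n_residue_samples
        # log-normal with the configured arithmetic mean
        sigma = config.residue_sigma
        med = mean / np.exp(sigma**2 / 2) if sigma > 0 else mean
        vals = med * rng.lognormal(0.0, sigma, size=m) if med > 0 else np.zeros(m)
        nd = rng.random(m) < config.nondetect_fraction
        for v, flag in zip(vals, nd):
            sid += 1
            rows.append((f"s{sid:06d}", food, comp, 0.0 if flag else v, int(flag)))
    return pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS)


def generate_compound_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the hazard table: one row per compound with a NOAEL, or (with
    probability ``loael_only_fraction``) only a LOAEL.  The reference compound
    always keeps its NOAEL."""
    rng = substream(config.seed, "compound_table")
    names = config.compound_names()
    noael = config.noael_distribution.sample(rng, len(names))
    # LOAEL sits a study-spacing factor above the NOAEL
    loael = noael * rng.uniform(2.0, 5.0, size=len(names))
    loael_only = rng.random(len(names)) < config.loael_only_fraction
    rows = []
    for i, name in enumerate(names):
        is_ref = name == config.reference_compound
        drop_noael = loael_only[i] and not is_ref
        rows.append((
            name,
            np.nan if drop_noael else noael[i],
            loael[i],
            int(is_ref),
        ))
    return pd.DataFrame(rows, columns=COMPOUND_COLUMNS)


def generate_all(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Generate the four input tables as a dict keyed by table name."""
    return {
        "field_survey": generate_field_survey(config),
        "dietary_survey": generate_dietary_survey(config),
        "concentration": generate_concentration_table(config),
        "compound": generate_compound_table(config),
    }
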