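"""Field-survey processing: dose rates, resident imputation and national
resident proportions.

A field survey is a long-format DataFrame (one row per field x applied
compound) with per-field attributes ``area_ha``, ``raising_factor`` and
``residents`` repeated across the field's rows; see
:data:`aggexpo.synthetic.FIELD_SURVEY_COLUMNS`.  The raising factor is the
survey weight extrapolating a sampled field to the national total; the same
factor used to raise farm areas is applied to raise resident counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._rng import substream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FieldRecord:
    """One surveyed field: crop, area, per-compound applied amounts (kg over
    the year), raising factor, nearby resident count (None = missing)."""

    field_id: str
    crop: str
    area_ha: float
    applied: Mapping[str, float]
    raising_factor: float
    residents: int | None = None
    survey_id: str | None = None

    def __post_init__(self):
        if self.area_ha <= 0:
            raise ValueError(f"field {self.field_id}: area_ha must be > 0")
        if self.raising_factor <= 0:
            raise ValueError(f"field {self.field_id}: raising_factor must be > 0")
        if any(v < 0 for v in self.applied.values()):
            raise ValueError(f"field {self.field_id}: applied amounts must be >= 0")


@dataclass(frozen=True)
class ResidentProportionTable:
    """Per-crop national resident estimates relative to the adult population.

    ``proportion`` is the share of the adult subpopulation living beside
    fields of each crop; an individual lives near at most one crop, so the
    proportions must sum to at most 1.
    """

    table: pd.DataFrame  # columns: crop, national_residents, proportion
    adult_population: float
    adult_fraction: float

    def proportions(self) -> dict[str, float]:
        return dict(zip(self.table["crop"], self.table["proportion"]))


def derive_dose_rates(record: FieldRecord) -> dict[str, float]:
    """Dose rate (kg/ha) per compound: applied amount over the year divided
    by field area.  Compounds with zero applied amount are dropped."""
    if record.area_ha <= 0:
        raise ValueError(f"field {record.field_id}: area_ha must be > 0")
    return {
        comp: amount / record.area_ha
        for comp, amount in record.applied.items()
        if amount > 0
    }


def add_dose_rates(survey: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive_dose_rates` over a long-format survey: adds a
    ``dose_rate_kg_ha`` column and drops zero-amount rows."""
    if (survey["area_ha"] <= 0).any():
        bad = survey.loc[survey["area_ha"] <= 0, "field_id"].unique()
        raise ValueError(f"non-positive field area for fields: {list(bad)[:5]}")
    out = survey[survey["amount_kg"] > 0].copy()
    out["dose_rate_kg_ha"] = out["amount_kg"] / out["area_ha"]
    return out


def restrict_to_cag(survey: pd.DataFrame, cag: Sequence[str]) -> pd.DataFrame:
    """Keep only rows whose compound is in the cumulative assessment group;
    the number of dropped rows is logged."""
    keep = survey["compound"].isin(set(cag))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("restrict_to_cag: dropped %d non-CAG application rows", dropped)
    return survey[keep].reset_index(drop=True)


def impute_missing_residents(survey: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Fill missing resident counts by resampling (with replacement) from the
    observed counts of fields of the same crop.

    Raises ``ValueError`` for a crop whose counts are all missing.
    """
    rng = substream(seed, "resident_imputation")
    out = survey.copy()
    fields = out.drop_duplicates("field_id")[["field_id", "crop", "residents"]]
    imputed = {}
    for crop, grp in fields.groupby("crop", sort=True):
        miss = grp["residents"].isna()
        if not miss.any():
            continue
        pool = grp.loc[~miss, "residents"].to_numpy()
        if pool.size == 0:
            raise ValueError(
                f"crop {crop!r}: all resident counts missing, cannot impute"
            )
        draws = rng.choice(pool, size=int(miss.sum()), replace=True)
        imputed.update(dict(zip(grp.loc[miss, "field_id"], draws)))
    if imputed:
        mask = out["field_id"].isin(imputed.keys())
        out.loc[mask, "residents"] = out.loc[mask, "field_id"].map(imputed)
    return out


def estimate_resident_proportions(
    survey: pd.DataFrame,
    total_population: float,
    adult_fraction: float = 0.824,
) -> ResidentProportionTable:
    """Raise per-field resident counts to national totals and express them as
    proportions of the adult population.

    Per crop: national adult residents = sum over fields of raising_factor x
    residents x adult_fraction; proportion = national adult residents /
    (total_population x adult_fraction).  The adult_fraction cancels in the
    proportion — proportions are relative to the adult subpopulation — but
    both the raised count and the denominator are reported on the adult
    scale.
    """
    if total_population <= 0:
        raise ValueError(f"total_population must be > 0, got {total_population}")
    if not 0 < adult_fraction <= 1:
        raise ValueError(f"adult_fraction must be in (0,1], got {adult_fraction}")
    fields = survey.drop_duplicates("field_id")
    if fields["residents"].isna().any():
        raise ValueError(
            "survey has missing resident counts; run impute_missing_residents first"
        )
    adult_population = total_population * adult_fraction
    agg = (
        fields.assign(
            national=fields["raising_factor"] * fields["residents"] * adult_fraction
        )
        .groupby("crop", sort=True)["national"]
        .sum()
        .rename("national_residents")
        .reset_index()
    )
    agg["proportion"] = agg["national_residents"] / adult_population
    total = agg["proportion"].sum()
    if total > 1.0:
        raise ValueError(
            f"resident proportions sum to {total:.3f} > 1; an individual can "
            "live near at most one crop — rescale resident counts or raising "
            "factors"
        )
    return ResidentProportionTable(
        table=agg, adult_population=adult_population, adult_fraction=adult_fraction
    )


def survey_to_records(survey: pd.DataFrame) -> list[FieldRecord]:
    """Convert a long-format survey into :class:`FieldRecord` objects."""
    records = []
    for fid, grp in survey.groupby("field_id", sort=True):
        first = grp.iloc[0]
        residents = first["residents"]
        records.append(FieldRecord(
            field_id=fid,
            crop=first["crop"],
            area_ha=float(first["area_ha"]),
            applied=dict(zip(grp["compound"], grp["amount_kg"])),
            raising_factor=float(first["raising_factor"]),
            residents=None if pd.isna(residents) else int(residents),
            survey_id=first.get("survey_id", first["crop"]),
        ))
    return records
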