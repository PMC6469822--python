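"""Build per-crop non-dietary exposure surveys from unit-dose triples and
surveyed field dose rates, and combine them into one survey set.

For each crop a fixed number ``I`` of positive-exposure residents is
simulated: each resident is assigned a surveyed field of that crop, and for
each of the field's compounds an independently drawn unit-dose triple is
multiplied by the compound's dose rate (exposure is linear in dose).  The
independent triple per compound reflects that a field's yearly amounts of
different compounds need not come from the same spray events.  Each crop
forms its own survey; a resident belongs to exactly one crop's survey, and
each survey carries a zero-proportion parameter — the probability that a
member of the full (sub)population has no exposure from that survey —
derived from the per-crop resident proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from ._stats import weighted_mean, weighted_quantile

ROUTES = ("dermal", "oral", "inhalation")

NONDIETARY_COLUMNS = [
    "idIndividual", "idSurvey", "compound",
    "Dermal", "Oral", "Inhalation", "idUncertaintySet",
]


@dataclass
class NonDietarySurveySet:
    """Combined non-dietary exposure records plus per-survey link parameters.

    ``records`` has one row per (individual, compound[, uncertainty set]) in
    the MCRA-style layout (:data:`NONDIETARY_COLUMNS`), with exposures in
    mg/day, unscaled for potency and bodyweight.  ``crop_weights[s]`` is the
    probability a population member belongs to survey ``s``;
    ``zero_proportion[s] = 1 - crop_weights[s]``.
    """

    records: pd.DataFrame
    zero_proportion: dict[str, float] = field(default_factory=dict)
    crop_weights: dict[str, float] = field(default_factory=dict)

    def uncertainty_ids(self) -> list:
        col = self.records["idUncertaintySet"]
        ids = sorted(x for x in col.dropna().unique() if x != 0)
        return ids

    def for_uncertainty(self, uid) -> "NonDietarySurveySet":
        """Restrict records to one uncertainty realisation."""
        mask = self.records["idUncertaintySet"] == uid
        return NonDietarySurveySet(
            records=self.records[mask].reset_index(drop=True),
            zero_proportion=dict(self.zero_proportion),
            crop_weights=dict(self.crop_weights),
        )


def build_crop_survey(
    fields: pd.DataFrame,
    triples: pd.DataFrame,
    I: int,
    seed: int,
    crop_key: int = 0,
    weight_by_residents: bool = False,
) -> pd.DataFrame:
    """Simulate ``I`` positive-exposure residents for one crop.

    ``fields`` is the long-format survey restricted to one crop with a
    ``dose_rate_kg_ha`` column (see :func:`aggexpo.usage.add_dose_rates`);
    ``triples`` a unit-dose pool.  Each resident draws a field (uniform by
    default, or with probability proportional to raising_factor x residents
    when ``weight_by_residents``), then one independent triple per compound
    of that field.  Returns records in the MCRA-style layout, exposures in
    mg/day.
    """
    if fields.empty:
        raise ValueError("field list is empty")
    if triples.empty:
        raise ValueError("unit-dose triple pool is empty")
    if "dose_rate_kg_ha" not in fields.columns:
        raise ValueError("fields must carry dose_rate_kg_ha; run add_dose_rates first")
    rng = substream(seed, "nondietary_assign", crop_key)
    survey_id = str(fields["survey_id"].iloc[0])
    field_ids = fields["field_id"].unique()
    if weight_by_residents:
        per_field = fields.drop_duplicates("field_id").set_index("field_id")
        w = (per_field["raising_factor"] * per_field["residents"]).reindex(field_ids)
        if w.isna().any():
            raise ValueError("weight_by_residents requires imputed resident counts")
        p = w.to_numpy(dtype=float)
        if p.sum() <= 0:
            raise ValueError("all resident weights are zero")
        p = p / p.sum()
        chosen = rng.choice(len(field_ids), size=I, p=p)
    else:
        chosen = rng.integers(0, len(field_ids), size=I)

    by_field = {
        fid: grp[["compound", "dose_rate_kg_ha"]].to_numpy(dtype=object)
        for fid, grp in fields.groupby("field_id", sort=False)
    }
    pool = triples[["dermal", "oral", "inhalation"]].to_numpy(dtype=float)

    ind_ids, comps, rates = [], [], []
    for i, fi in enumerate(chosen, start=1):
        arr = by_field[field_ids[fi]]
        for comp, rate in arr:
            ind_ids.append(f"{survey_id}_i{i:05d}")
            comps.append(comp)
            rates.append(float(rate))
    rates = np.asarray(rates)
    pick = rng.integers(0, pool.shape[0], size=rates.size)
    expo = pool[pick] * rates[:, None]
    return pd.DataFrame({
        "idIndividual": ind_ids,
        "idSurvey": survey_id,
        "compound": comps,
        "Dermal": expo[:, 0],
        "Oral": expo[:, 1],
        "Inhalation": expo[:, 2],
        "idUncertaintySet": 0,
    })


def combine_surveys(per_crop: list[pd.DataFrame], proportions) -> NonDietarySurveySet:
    """Combine per-crop surveys into one survey set with zero-proportion
    parameters ``1 - proportion`` taken from a
    :class:`~aggexpo.usage.ResidentProportionTable` (or a plain
    survey_id -> proportion mapping)."""
    props = proportions.proportions() if hasattr(proportions, "proportions") else dict(proportions)
    seen = set()
    for df in per_crop:
        sids = set(df["idSurvey"].unique())
        if sids & seen:
            raise ValueError(f"duplicate survey_id(s): {sorted(sids & seen)}")
        seen |= sids
    missing = seen - props.keys()
    if missing:
        raise ValueError(f"no resident proportion for survey(s): {sorted(missing)}")
    records = pd.concat(per_crop, ignore_index=True) if per_crop else pd.DataFrame(
        columns=NONDIETARY_COLUMNS
    )
    crop_weights = {s: float(props[s]) for s in sorted(seen)}
    zero_proportion = {s: 1.0 - w for s, w in crop_weights.items()}
    return NonDietarySurveySet(records, zero_proportion, crop_weights)


def summarize_nondietary(
    surveys: NonDietarySurveySet,
    rpf,
    field_weights: pd.Series | None = None,
    p: float = 0.95,
) -> pd.DataFrame:
    """Population summaries of exposure by route and by (route, compound).

    For each route total and each (route, compound) cell: weighted mean,
    median and P95 for (a) the exposed subpopulation and (b) the full
    population, where the full population mixes in zeros with probability
    equal to the overall zero share ``1 - sum(crop_weights)`` plus the
    non-membership of other surveys.  Exposure columns are raw mg/day; the
    contribution column is RPF-weighted and sums to 100% over all
    (route, compound) cells.
    """
    rec = surveys.records
    if rec.empty:
        raise ValueError("survey set has no records")
    rpf_map = rpf.rpf if hasattr(rpf, "rpf") else dict(rpf)
    missing = sorted(set(rec["compound"]) - rpf_map.keys())
    if missing:
        raise ValueError(f"missing RPF for compounds: {missing}")

    rec = rec.copy()
    n_per_survey = rec.groupby("idSurvey")["idIndividual"].nunique()
    # population weight of one simulated individual in survey s; with an
    # all-zero-weight survey set the exposed-subpopulation view falls back
    # to uniform weights (conditional-on-exposure measure is degenerate)
    if sum(surveys.crop_weights.values()) > 0:
        ind_w = {s: surveys.crop_weights[s] / n_per_survey[s]
                 for s in n_per_survey.index}
    else:
        total = int(n_per_survey.sum())
        ind_w = {s: 1.0 / total for s in n_per_survey.index}
    if field_weights is not None:
        fw = rec["idIndividual"].map(field_weights)
        if fw.isna().any():
            raise ValueError("field_weights does not cover every individual")
        # renormalise within survey so crop_weights are preserved
        tot = fw.groupby(rec["idSurvey"]).transform("sum")
        rec["_w"] = fw / tot * rec["idSurvey"].map(surveys.crop_weights)
    else:
        rec["_w"] = rec["idSurvey"].map(ind_w)

    exposed_mass = sum(surveys.crop_weights.values())
    zero_mass = 1.0 - exposed_mass

    # per-individual route totals (for the route-level rows)
    per_ind = rec.groupby(["idSurvey", "idIndividual"], sort=False).agg(
        Dermal=("Dermal", "sum"), Oral=("Oral", "sum"),
        Inhalation=("Inhalation", "sum"), _w=("_w", "first"),
    ).reset_index()

    rpf_col = rec["compound"].map(rpf_map)
    grand = 0.0
    cells = []
    for route in ("Dermal", "Oral", "Inhalation"):
        contrib = (rec[route] * rpf_col * rec["_w"]).groupby(rec["compound"]).sum()
        grand += contrib.sum()
        cells.append((route, contrib))

    rows = []
    for route in ("Dermal", "Oral", "Inhalation"):
        v = per_ind[route].to_numpy()
        w = per_ind["_w"].to_numpy()
        rows.append({
            "route": route, "compound": "(all)", "contribution_pct": np.nan,
            "exposed_mean": weighted_mean(v, w),
            "exposed_median": weighted_quantile(v, 0.5, w),
            "exposed_p95": weighted_quantile(v, p, w),
            "full_mean": weighted_mean(v, w, zero_mass=zero_mass),
            "full_median": weighted_quantile(v, 0.5, w, zero_mass=zero_mass),
            "full_p95": weighted_quantile(v, p, w, zero_mass=zero_mass),
        })
    for route, contrib in cells:
        for comp in contrib.index:
            sub = rec[rec["compound"] == comp]
            v = sub[route].to_numpy()
            w = sub["_w"].to_numpy()
            if w.sum() == 0:  # compound confined to zero-weight surveys
                rows.append({
                    "route": route, "compound": comp, "contribution_pct": 0.0,
                    "exposed_mean": np.nan, "exposed_median": np.nan,
                    "exposed_p95": np.nan, "full_mean": 0.0,
                    "full_median": 0.0, "full_p95": 0.0,
                })
                continue
            # individuals without this compound count as zero exposure
            comp_mass = w.sum()
            zm_comp = 1.0 - comp_mass
            rows.append({
                "route": route, "compound": comp,
                "contribution_pct": 100.0 * contrib[comp] / grand if grand > 0 else 0.0,
                "exposed_mean": weighted_mean(v, w),
                "exposed_median": weighted_quantile(v, 0.5, w),
                "exposed_p95": weighted_quantile(v, p, w),
                "full_mean": weighted_mean(v, w, zero_mass=zm_comp),
                "full_median": weighted_quantile(v, 0.5, w, zero_mass=zm_comp),
                "full_p95": weighted_quantile(v, p, w, zero_mass=zm_comp),
            })
    return pd.DataFrame(rows)
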