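"""RPF computation, chronic dietary exposure (OIM), probabilistic linking of
dietary individuals to non-dietary records, and aggregation on the reference-
compound scale.

Unit conventions, fixed throughout the package:

* non-dietary inputs are mg/day per individual, unscaled for potency and
  bodyweight;
* dietary and aggregate outputs are ug/kg bw/day (conversion factor 1000 at
  aggregation, divided by the dietary-survey bodyweight);
* RPF weighting is applied after linking and aggregation, never stored in
  input files.

Cumulative exposure for individual i:

    total_i = sum_j RPF_j * ( dietary_ij + sum_routes absorption_r * nd_irj )

in reference-compound equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .nondietary import NonDietarySurveySet

ROUTE_NAMES = ("Dermal", "Oral", "Inhalation")


@dataclass(frozen=True)
class RPFMap:
    """Relative potency factors on a reference-compound scale.

    ``rpf[j] = NOAEL_ref / NOAEL_j``, or ``NOAEL_ref / (LOAEL_j / 3)`` for
    compounds with only a LOAEL; ``provenance[j]`` records which.  The
    reference compound has RPF 1 by construction.
    """

    reference: str
    rpf: dict[str, float]
    provenance: dict[str, str]

    def __post_init__(self):
        if abs(self.rpf[self.reference] - 1.0) > 1e-12:
            raise ValueError("rpf[reference] must be 1")
        if any(v <= 0 for v in self.rpf.values()):
            raise ValueError("all RPFs must be > 0")

    def series(self, compounds) -> pd.Series:
        return pd.Series({c: self.rpf[c] for c in compounds})


@dataclass
class AggregateResult:
    """Per-individual exposures on the dietary survey population.

    ``dietary``: individuals x compounds, ug/kg bw/day (no RPF weighting).
    ``nondietary``: dict route -> individuals x compounds matrix, ug/kg
    bw/day after absorption and bodyweight scaling (zero for unlinked
    individuals).  ``totals``: per individual the RPF-weighted dietary-only
    and aggregate cumulative exposures plus the linked survey (or NaN).
    """

    dietary: pd.DataFrame
    nondietary: dict[str, pd.DataFrame]
    totals: pd.DataFrame  # columns: bodyweight_kg, dietary_total, aggregate_total, survey_id
    rpf: RPFMap

    @property
    def individuals(self) -> pd.Index:
        return self.dietary.index

    def exposure_matrix(self, rpf_weighted: bool = True) -> pd.DataFrame:
        """Individuals x compounds matrix of total (dietary + all routes)
        exposure, RPF-weighted by default (reference-compound equivalents)."""
        X = self.dietary.copy()
        for route in self.nondietary:
            X = X.add(self.nondietary[route], fill_value=0.0)
        if rpf_weighted:
            X = X * self.rpf.series(X.columns)
        return X


def compute_rpf(compound_table: pd.DataFrame, reference: str) -> RPFMap:
    """Compute RPFs from a hazard table with columns ``compound``,
    ``noael_mg_kg_bw_day``, ``loael_mg_kg_bw_day``."""
    tab = compound_table.set_index("compound")
    if reference not in tab.index:
        raise ValueError(f"reference compound {reference!r} not in table")
    ref_noael = tab.loc[reference, "noael_mg_kg_bw_day"]
    if pd.isna(ref_noael) or ref_noael <= 0:
        raise ValueError(f"reference compound {reference!r} must have a positive NOAEL")
    rpf, prov = {}, {}
    missing = []
    for comp, row in tab.iterrows():
        noael = row["noael_mg_kg_bw_day"]
        loael = row.get("loael_mg_kg_bw_day", np.nan)
        if pd.notna(noael) and noael > 0:
            rpf[comp] = float(ref_noael / noael)
            prov[comp] = "NOAEL"
        elif pd.notna(loael) and loael > 0:
            rpf[comp] = float(ref_noael / (loael / 3.0))
            prov[comp] = "LOAEL3"
        else:
            missing.append(comp)
    if missing:
        raise ValueError(f"compounds with neither NOAEL nor LOAEL: {missing}")
    return RPFMap(reference=reference, rpf=rpf, provenance=prov)


def mean_concentrations(conc: pd.DataFrame) -> pd.DataFrame:
    """Mean residue concentration (mg/kg) per (food, compound) under the
    optimistic treatment: nondetect samples contribute zero."""
    c = conc.copy()
    c.loc[c["nondetect"].astype(bool), "concentration_mg_kg"] = 0.0
    return (
        c.groupby(["food", "compound"])["concentration_mg_kg"]
        .mean()
        .unstack(fill_value=0.0)
    )


def compute_dietary_oim(dietary: pd.DataFrame, conc: pd.DataFrame) -> pd.DataFrame:
    """Observed-individual-mean chronic dietary exposure.

    For each individual and compound: the mean over survey days of the day's
    total intake ``sum_f consumption_f (g) x mean_conc(f, j) (mg/kg)``,
    divided by bodyweight.  With grams x mg/kg / kg bodyweight the result is
    already ug/kg bw/day.  Returns an individuals x compounds DataFrame.
    """
    cmat = mean_concentrations(conc)
    foods_consumed = set(dietary.loc[dietary["amount_g"] > 0, "food"].unique())
    uncovered = sorted(foods_consumed - set(cmat.index))
    if uncovered:
        raise ValueError(f"foods with no concentration data: {uncovered}")
    n_days = dietary.groupby("individual_id")["day"].nunique()
    intake = (
        dietary[dietary["amount_g"] > 0]
        .groupby(["individual_id", "food"])["amount_g"]
        .sum()
        .unstack(fill_value=0.0)
    )
    # individuals with zero consumption everywhere still need rows
    all_ids = dietary["individual_id"].unique()
    intake = intake.reindex(all_ids, fill_value=0.0)
    if intake.shape[1] == 0:
        expo = pd.DataFrame(0.0, index=all_ids, columns=cmat.columns)
    else:
        cols = [f for f in intake.columns if f in cmat.index]
        expo = intake[cols].to_numpy() @ cmat.loc[cols].to_numpy()
        expo = pd.DataFrame(expo, index=intake.index, columns=cmat.columns)
    bw = dietary.drop_duplicates("individual_id").set_index("individual_id")["bodyweight_kg"]
    expo = expo.div(n_days.reindex(expo.index), axis=0).div(bw.reindex(expo.index), axis=0)
    expo.index.name = "individual_id"
    return expo


def link_nondietary(
    dietary: pd.DataFrame, surveys: NonDietarySurveySet, seed: int
) -> pd.DataFrame:
    """Assign each dietary individual a non-dietary record or none.

    With probability ``1 - sum(crop_weights)`` an individual is unlinked
    (zero non-dietary exposure); otherwise it joins survey ``s`` with
    probability ``crop_weights[s]`` and is paired with a uniformly random
    simulated individual of that survey.  Returns a DataFrame indexed by
    dietary individual with columns ``survey_id`` and ``nd_individual``
    (NaN when unlinked).
    """
    weights = surveys.crop_weights
    total = sum(weights.values())
    if total > 1.0 + 1e-12:
        raise ValueError(f"crop weights sum to {total:.4f} > 1")
    ids = dietary["individual_id"].unique()
    rng = substream(seed, "link")
    names = sorted(weights)
    probs = np.array([weights[s] for s in names])
    u = rng.random(ids.size)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    which = np.searchsorted(edges, u, side="right") - 1  # >= len(names) -> unlinked
    nd_ind = {
        s: surveys.records.loc[surveys.records["idSurvey"] == s, "idIndividual"].unique()
        for s in names
    }
    survey_col, ind_col = [], []
    for k, i in enumerate(which):
        if i < len(names) and u[k] < edges[-1]:
            s = names[i]
            pool = nd_ind[s]
            survey_col.append(s)
            ind_col.append(pool[rng.integers(0, pool.size)])
        else:
            survey_col.append(None)
            ind_col.append(None)
    return pd.DataFrame(
        {"survey_id": survey_col, "nd_individual": ind_col},
        index=pd.Index(ids, name="individual_id"),
    )


def aggregate(
    dietary_exposure: pd.DataFrame,
    link: pd.DataFrame,
    surveys: NonDietarySurveySet,
    rpf: RPFMap,
    bodyweights: pd.Series,
    absorption: dict[str, float] | None = None,
) -> AggregateResult:
    """Combine dietary and linked non-dietary exposures per individual.

    Non-dietary mg/day values are converted to ug/kg bw/day with the dietary
    survey bodyweight (x1000 / bw) and per-route absorption factors
    (default 1), then the cumulative total is formed with RPF weighting.
    """
    absorption = {r: 1.0 for r in ROUTE_NAMES} | (absorption or {})
    ids = dietary_exposure.index
    missing_bw = [i for i in ids if i not in bodyweights.index or pd.isna(bodyweights[i])]
    if missing_bw:
        raise ValueError(f"missing bodyweight for individuals: {missing_bw[:5]}")
    if not link.index.equals(ids):
        link = link.reindex(ids)
        if link["survey_id"].isna().all() and len(link) != len(ids):
            raise ValueError("link map does not cover all individuals")

    compounds = list(dietary_exposure.columns)
    comp_index = {c: k for k, c in enumerate(compounds)}
    nd = {r: np.zeros((len(ids), len(compounds))) for r in ROUTE_NAMES}

    linked = link[link["survey_id"].notna()]
    if not linked.empty and not surveys.records.empty:
        rec = surveys.records.set_index(["idSurvey", "idIndividual"])
        rec = rec.sort_index()
        row_of = {i: k for k, i in enumerate(ids)}
        for ind, lrow in linked.iterrows():
            sub = rec.loc[(lrow["survey_id"], lrow["nd_individual"])]
            if isinstance(sub, pd.Series):
                sub = sub.to_frame().T
            k = row_of[ind]
            bw = bodyweights[ind]
            for _, r in sub.iterrows():
                j = comp_index.get(r["compound"])
                if j is None:
                    raise ValueError(
                        f"non-dietary compound {r['compound']!r} missing from "
                        "dietary exposure columns"
                    )
                for route in ROUTE_NAMES:
                    nd[route][k, j] += (
                        float(r[route]) * 1000.0 / bw * absorption[route]
                    )

    nondiet = {
        r: pd.DataFrame(nd[r], index=ids, columns=compounds) for r in ROUTE_NAMES
    }
    rpf_vec = rpf.series(compounds)
    dietary_total = dietary_exposure.mul(rpf_vec, axis=1).sum(axis=1)
    nd_total = sum(
        nondiet[r].mul(rpf_vec, axis=1).sum(axis=1) for r in ROUTE_NAMES
    )
    totals = pd.DataFrame({
        "bodyweight_kg": bodyweights.reindex(ids),
        "dietary_total": dietary_total,
        "aggregate_total": dietary_total + nd_total,
        "survey_id": link["survey_id"],
    })
    return AggregateResult(
        dietary=dietary_exposure, nondietary=nondiet, totals=totals, rpf=rpf
    )


def population_percentiles(
    result: AggregateResult, probs=(50, 90, 95, 99, 99.9, 99.99)
) -> pd.DataFrame:
    """Empirical percentiles (linear interpolation) of the dietary-only and
    aggregate cumulative exposures at the requested percentage levels."""
    probs = list(probs)
    if len(result.totals) == 0:
        raise ValueError("empty result set")
    if any(not 0 < p < 100 for p in probs):
        raise ValueError("percentile levels must be in (0, 100)")
    q = np.array(probs) / 100.0
    return pd.DataFrame({
        "percentage": probs,
        "dietary": np.quantile(result.totals["dietary_total"], q),
        "aggregate": np.quantile(result.totals["aggregate_total"], q),
    })


def route_contributions(result: AggregateResult) -> pd.DataFrame:
    """Contribution of each route (Dietary, Dermal, Inhalation, Oral
    non-dietary) to the population's total RPF-weighted exposure, with
    exposed counts and summaries over all and over exposed individuals."""
    if len(result.totals) == 0:
        raise ValueError("empty result set")
    rpf_vec = result.rpf.series(result.dietary.columns)
    route_tot = {"Dietary": result.dietary.mul(rpf_vec, axis=1).sum(axis=1)}
    for route in ROUTE_NAMES:
        label = "Oral non-dietary" if route == "Oral" else route
        route_tot[label] = result.nondietary[route].mul(rpf_vec, axis=1).sum(axis=1)
    grand = sum(t.sum() for t in route_tot.values())
    n = len(result.totals)
    rows = []
    for label, tot in route_tot.items():
        pos = tot > 0
        rows.append({
            "route": label,
            "contribution_pct": 100.0 * tot.sum() / grand if grand > 0 else 0.0,
            "n_exposed": int(pos.sum()),
            "pct_exposed": 100.0 * pos.sum() / n,
            "mean_all": tot.mean(),
            "median_all": tot.median(),
            "p95_all": tot.quantile(0.95),
            "mean_exposed": tot[pos].mean() if pos.any() else 0.0,
            "p95_exposed": tot[pos].quantile(0.95) if pos.any() else 0.0,
        })
    return pd.DataFrame(rows)


def compound_contributions(result: AggregateResult) -> pd.DataFrame:
    """Per (route, compound): RPF-weighted contribution % to total
    non-dietary exposure, with raw (non-RPF) exposure summaries."""
    rpf_vec = result.rpf.series(result.dietary.columns)
    grand = sum(
        (result.nondietary[r] * rpf_vec).to_numpy().sum() for r in ROUTE_NAMES
    )
    n = len(result.totals)
    rows = []
    for route in ROUTE_NAMES:
        mat = result.nondietary[route]
        for comp in mat.columns:
            col = mat[comp]
            if (col > 0).sum() == 0:
                continue
            pos = col > 0
            rows.append({
                "route": route,
                "compound": comp,
                "contribution_pct": (
                    100.0 * (col * rpf_vec[comp]).sum() / grand if grand > 0 else 0.0
                ),
                "mean_all": col.mean(),
                "pct_exposed": 100.0 * pos.sum() / n,
                "mean_exposed": col[pos].mean(),
                "rpf": rpf_vec[comp],
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("contribution_pct", ascending=False).reset_index(drop=True)
    return out
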