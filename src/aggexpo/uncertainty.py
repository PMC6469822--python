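"""Two-dimensional Monte Carlo: propagate dietary sampling uncertainty and
non-dietary model uncertainty into percentile interval estimates.

Each uncertainty cycle (outer loop) bootstrap-resamples the dietary
individuals with replacement (a resampled individual carries its consumption
days and bodyweight with it), draws one non-dietary uncertainty realisation
uniformly, re-links and re-aggregates on that slice, and records the
population percentiles.  Over ``n_cycles`` cycles the 2.5th and 97.5th
empirical quantiles per percentile form the uncertainty interval, reported
alongside a nominal estimate computed from a separate full run at the
central uncertainty realisation (the realisation whose mean RPF-weighted
record total is the median across realisations).

The inner variability dimension is the population itself: the spread across
individuals within one cycle is variability, the spread across cycles is
uncertainty, and the two are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .aggregate import RPFMap, compute_dietary_oim
from .nondietary import NonDietarySurveySet

ROUTE_NAMES = ("Dermal", "Oral", "Inhalation")


@dataclass
class UncertaintyRun:
    """Point estimates and 2.5-97.5% uncertainty intervals per percentile.

    ``table`` columns: percentage, dietary, dietary_lo, dietary_hi,
    aggregate, aggregate_lo, aggregate_hi.  ``cycle_percentiles`` keeps the
    raw per-cycle percentile vectors (cycles x percentiles) for both
    distributions; ``mean`` rows summarise the population mean the same way.
    """

    table: pd.DataFrame
    mean: pd.DataFrame
    cycle_percentiles: dict[str, np.ndarray]
    n_cycles: int
    uncertainty_ids: list


def _record_totals(
    surveys: NonDietarySurveySet, rpf: RPFMap, absorption: dict[str, float]
) -> pd.DataFrame:
    """Per (uncertainty_id, survey, nd individual): RPF-weighted total
    non-dietary exposure in mg/day (before bodyweight scaling)."""
    rec = surveys.records
    rpf_col = rec["compound"].map(rpf.rpf)
    if rpf_col.isna().any():
        missing = sorted(rec.loc[rpf_col.isna(), "compound"].unique())
        raise ValueError(f"missing RPF for compounds: {missing}")
    total = sum(
        rec[route] * absorption.get(route, 1.0) * rpf_col for route in ROUTE_NAMES
    )
    out = rec.assign(_tot=total).groupby(
        ["idUncertaintySet", "idSurvey", "idIndividual"], sort=True
    )["_tot"].sum()
    return out.reset_index()


def run_2dmc(
    dietary: pd.DataFrame,
    conc: pd.DataFrame,
    surveys: NonDietarySurveySet,
    rpf: RPFMap,
    n_cycles: int = 100,
    probs=(50, 90, 95, 99, 99.9, 99.99),
    seed: int = 0,
    absorption: dict[str, float] | None = None,
    bootstrap: bool = True,
) -> UncertaintyRun:
    """Run the two-dimensional Monte Carlo and return percentile intervals.

    ``surveys`` must carry at least one nonzero ``idUncertaintySet``;
    ``bootstrap=False`` disables dietary resampling (cycles then differ only
    through the non-dietary uncertainty realisation and the linking draw).
    """
    if n_cycles < 2:
        raise ValueError(f"n_cycles must be >= 2, got {n_cycles}")
    uids = surveys.uncertainty_ids()
    if not uids:
        raise ValueError(
            "survey set has no uncertainty realisations; run the standard "
            "(non-uncertainty) aggregation pipeline instead"
        )
    absorption = {r: 1.0 for r in ROUTE_NAMES} | (absorption or {})
    probs = list(probs)
    q = np.asarray(probs) / 100.0

    # variability-side quantities, computed once
    diet_expo = compute_dietary_oim(dietary, conc)
    rpf_vec = rpf.series(diet_expo.columns).to_numpy()
    diet_total = (diet_expo.to_numpy() * rpf_vec).sum(axis=1)
    bw = (
        dietary.drop_duplicates("individual_id")
        .set_index("individual_id")["bodyweight_kg"]
        .reindex(diet_expo.index)
        .to_numpy()
    )
    n = diet_total.size

    # per-realisation pools of RPF-weighted non-dietary record totals (mg/day)
    totals = _record_totals(surveys, rpf, absorption)
    pools = {
        uid: {
            s: g["_tot"].to_numpy()
            for s, g in grp.groupby("idSurvey", sort=True)
        }
        for uid, grp in totals.groupby("idUncertaintySet", sort=True)
        if uid in uids
    }
    names = sorted(surveys.crop_weights)
    weights = np.array([surveys.crop_weights[s] for s in names])
    edges = np.concatenate([[0.0], np.cumsum(weights)])

    def one_pass(rows: np.ndarray, uid, rng) -> tuple[np.ndarray, np.ndarray]:
        """Dietary + aggregate totals for resampled rows under realisation uid."""
        d = diet_total[rows]
        agg = d.copy()
        u = rng.random(rows.size)
        which = np.searchsorted(edges, u, side="right") - 1
        linked = (which >= 0) & (which < len(names)) & (u < edges[-1])
        for si, s in enumerate(names):
            sel = linked & (which == si)
            if not sel.any():
                continue
            pool = pools[uid].get(s)
            if pool is None or pool.size == 0:
                continue
            picks = rng.integers(0, pool.size, size=int(sel.sum()))
            agg[sel] = agg[sel] + pool[picks] * 1000.0 / bw[rows][sel]
        return d, agg

    # nominal run: central realisation (median mean record total), no resample
    uid_means = {
        uid: np.concatenate([p for p in pools[uid].values()]).mean()
        if pools.get(uid) else 0.0
        for uid in uids
    }
    order = sorted(uids, key=lambda u: (uid_means[u], str(u)))
    central = order[(len(order) - 1) // 2]
    rng_nom = substream(seed, "link")
    all_rows = np.arange(n)
    d_nom, a_nom = one_pass(all_rows, central, rng_nom)

    diet_cycles = np.empty((n_cycles, len(probs)))
    agg_cycles = np.empty((n_cycles, len(probs)))
    diet_mean = np.empty(n_cycles)
    agg_mean = np.empty(n_cycles)
    for c in range(n_cycles):
        rng = substream(seed, "bootstrap", c)
        rows = rng.integers(0, n, size=n) if bootstrap else all_rows
        uid = uids[rng.integers(0, len(uids))]
        d, a = one_pass(rows, uid, rng)
        diet_cycles[c] = np.quantile(d, q)
        agg_cycles[c] = np.quantile(a, q)
        diet_mean[c] = d.mean()
        agg_mean[c] = a.mean()

    lo, hi = 0.025, 0.975
    table = pd.DataFrame({
        "percentage": probs,
        "dietary": np.quantile(d_nom, q),
        "dietary_lo": np.quantile(diet_cycles, lo, axis=0),
        "dietary_hi": np.quantile(diet_cycles, hi, axis=0),
        "aggregate": np.quantile(a_nom, q),
        "aggregate_lo": np.quantile(agg_cycles, lo, axis=0),
        "aggregate_hi": np.quantile(agg_cycles, hi, axis=0),
    })
    mean = pd.DataFrame({
        "quantity": ["dietary_mean", "aggregate_mean"],
        "point": [d_nom.mean(), a_nom.mean()],
        "lo": [np.quantile(diet_mean, lo), np.quantile(agg_mean, lo)],
        "hi": [np.quantile(diet_mean, hi), np.quantile(agg_mean, hi)],
    })
    return UncertaintyRun(
        table=table,
        mean=mean,
        cycle_percentiles={"dietary": diet_cycles, "aggregate": agg_cycles},
        n_cycles=n_cycles,
        uncertainty_ids=list(uids),
    )
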