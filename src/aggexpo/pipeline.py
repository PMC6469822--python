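"""Pipeline driver: chain the assessment stages end to end.

Order of stages (matching the assessment workflow): synthesise or load input
tables; restrict applications to the CAG and derive dose rates; impute
missing resident counts and estimate per-crop resident proportions; simulate
unit-dose spray exposure per scenario class; build per-crop non-dietary
surveys and combine them; compute RPFs and dietary OIM exposure; link and
aggregate; write percentile, route- and compound-contribution reports;
optionally prioritise mixtures and run the two-dimensional Monte Carlo.
Identical config + seed gives a byte-identical report bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import io as aio
from .aggregate import (
    aggregate,
    compound_contributions,
    compute_dietary_oim,
    compute_rpf,
    link_nondietary,
    population_percentiles,
    route_contributions,
)
from .config import ConfigurationError, SyntheticConfig, scenario_for
from .mixtures import select_mixtures
from .nondietary import build_crop_survey, combine_surveys, summarize_nondietary
from .spray import simulate_unit_dose, simulate_unit_dose_with_uncertainty
from .synthetic import generate_all
from .uncertainty import run_2dmc
from .usage import (
    add_dose_rates,
    estimate_resident_proportions,
    impute_missing_residents,
    restrict_to_cag,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Either ``synthesis`` (a :class:`SyntheticConfig`) or all four input
    paths must be given.  ``cag`` defaults to every compound in the hazard
    table; ``reference`` must be in the CAG.
    """

    output_dir: str = "results/pipeline"
    seed: int = 0
    synthesis: SyntheticConfig | None = None
    field_survey_path: str | None = None
    dietary_survey_path: str | None = None
    concentration_path: str | None = None
    compound_path: str | None = None
    cag: list[str] | None = None
    reference: str | None = None
    total_population: float = 63.2e6
    adult_fraction: float = 0.824
    I_per_crop: int = 2000
    n_unit_dose: int = 17500
    scenario_overrides: dict = dc_field(default_factory=dict)
    absorption: dict[str, float] = dc_field(default_factory=dict)
    percentiles: tuple = (50, 90, 95, 99, 99.9, 99.99)
    mixtures_k: int | None = 3
    mixtures_sparsity: float = 0.05
    mcr_threshold: float | None = 2.0
    uncertainty_cycles: int | None = None
    n_uncertainty_sets: int = 100

    def __post_init__(self):
        paths = (self.field_survey_path, self.dietary_survey_path,
                 self.concentration_path, self.compound_path)
        if self.synthesis is None and any(p is None for p in paths):
            raise ConfigurationError(
                "either a synthesis block or all four input paths must be set"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the report bundle as a dict of
    DataFrames/objects and writes CSV reports plus a run log under
    ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    bundle: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- inputs
    if config.synthesis is not None:
        tables = stage("synthesize")(lambda: generate_all(
            dataclasses.replace(config.synthesis, seed=config.seed)
        ))
    else:
        tables = stage("load")(lambda: {
            "field_survey": aio.read_table(config.field_survey_path, "field_survey"),
            "dietary_survey": aio.read_table(config.dietary_survey_path, "dietary_survey"),
            "concentration": aio.read_table(config.concentration_path, "concentration"),
            "compound": aio.read_table(config.compound_path, "compound"),
        })
    fields = tables["field_survey"]
    dietary = tables["dietary_survey"]
    compound_table = tables["compound"]
    cag = config.cag or list(compound_table["compound"])
    reference = config.reference
    if reference is None:
        ref_rows = compound_table.loc[compound_table["is_reference"] == 1, "compound"]
        if ref_rows.empty:
            raise ConfigurationError("no reference compound flagged or configured")
        reference = ref_rows.iloc[0]
    if reference not in cag:
        raise ConfigurationError(f"reference {reference!r} not in CAG list")

    # --- usage survey
    def usage_stage():
        f = restrict_to_cag(fields, cag)
        f = add_dose_rates(f)
        f = impute_missing_residents(f, config.seed)
        props = estimate_resident_proportions(
            f, config.total_population, config.adult_fraction
        )
        return f, props

    fields_p, props = stage("usage_survey")(usage_stage)
    bundle["resident_proportions"] = props.table
    props.table.to_csv(out / "resident_proportions.csv", index=False)
    log["stages"]["usage_survey"] = {
        "n_fields": int(fields_p["field_id"].nunique()),
        "proportion_sum": float(props.table["proportion"].sum()),
    }

    # --- spray simulation + non-dietary surveys per crop
    def nondietary_stage():
        per_crop = []
        for ci, (crop, grp) in enumerate(fields_p.groupby("crop", sort=True)):
            scen_class = grp["scenario_class"].iloc[0]
            settings = scenario_for(
                scen_class, **config.scenario_overrides.get(scen_class, {})
            )
            if config.uncertainty_cycles:
                triples = simulate_unit_dose_with_uncertainty(
                    settings, config.n_unit_dose, config.n_uncertainty_sets,
                    seed=config.seed + ci,
                )
                recs = []
                for uid, tgrp in triples.groupby("uncertainty_id"):
                    r = build_crop_survey(
                        grp, tgrp, config.I_per_crop, config.seed, crop_key=ci
                    )
                    r["idUncertaintySet"] = uid
                    recs.append(r)
                per_crop.append(pd.concat(recs, ignore_index=True))
            else:
                triples = simulate_unit_dose(
                    settings, config.n_unit_dose, seed=config.seed + ci
                )
                per_crop.append(build_crop_survey(
                    grp, triples, config.I_per_crop, config.seed, crop_key=ci
                ))
        return combine_surveys(per_crop, props)

    surveys = stage("build_nondietary")(nondietary_stage)
    aio.write_table(surveys.records, out / "nondietary_exposure.csv", "nondietary")
    aio.write_survey_properties(surveys, out / "nondietary_survey_properties.csv")
    bundle["surveys"] = surveys
    log["stages"]["build_nondietary"] = {
        "n_records": int(len(surveys.records)),
        "zero_proportion": surveys.zero_proportion,
    }

    # --- aggregation
    def aggregate_stage():
        rpf = compute_rpf(compound_table, reference)
        base = (
            surveys.for_uncertainty(surveys.uncertainty_ids()[0])
            if config.uncertainty_cycles else surveys
        )
        diet_expo = compute_dietary_oim(dietary, tables["concentration"])
        diet_expo = diet_expo.reindex(
            columns=sorted(set(diet_expo.columns) | set(base.records["compound"])),
            fill_value=0.0,
        )
        link = link_nondietary(dietary, base, config.seed)
        bw = dietary.drop_duplicates("individual_id").set_index("individual_id")[
            "bodyweight_kg"
        ]
        return rpf, aggregate(diet_expo, link, base, rpf, bw, config.absorption)

    rpf, result = stage("aggregate")(aggregate_stage)
    bundle["rpf"] = rpf
    bundle["result"] = result
    pct = population_percentiles(result, config.percentiles)
    routes = route_contributions(result)
    comps = compound_contributions(result)
    nd_summary = summarize_nondietary(surveys, rpf)
    pct.to_csv(out / "percentiles.csv", index=False)
    routes.to_csv(out / "route_contributions.csv", index=False)
    comps.to_csv(out / "compound_contributions.csv", index=False)
    nd_summary.to_csv(out / "nondietary_summary.csv", index=False)
    bundle.update(percentiles=pct, routes=routes, compounds=comps,
                  nondietary_summary=nd_summary)
    log["stages"]["aggregate"] = {
        "n_individuals": int(len(result.totals)),
        "n_linked": int(result.totals["survey_id"].notna().sum()),
    }

    # --- mixtures
    if config.mixtures_k:
        def mixtures_stage():
            X = result.exposure_matrix(rpf_weighted=True)
            raw = result.exposure_matrix(rpf_weighted=False)
            return select_mixtures(
                X, k=config.mixtures_k, sparsity=config.mixtures_sparsity,
                mcr_threshold=config.mcr_threshold, seed=config.seed,
                raw_exposure=raw,
            )

        mixtures = stage("mixtures")(mixtures_stage)
        bundle["mixtures"] = mixtures
        rows = []
        for m in mixtures:
            s = m.summaries.assign(
                mixture=m.rank, variance_explained=m.variance_explained
            )
            rows.append(s)
        mix_df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        mix_df.to_csv(out / "mixtures.csv", index=False)
        log["stages"]["mixtures"] = {"n_mixtures": len(mixtures)}
    else:
        logger.info("mixtures stage skipped (mixtures_k not set)")
        log["stages"]["mixtures"] = "skipped"

    # --- uncertainty
    if config.uncertainty_cycles:
        def uncertainty_stage():
            return run_2dmc(
                dietary, tables["concentration"], surveys, rpf,
                n_cycles=config.uncertainty_cycles, probs=config.percentiles,
                seed=config.seed, absorption=config.absorption,
            )

        urun = stage("uncertainty")(uncertainty_stage)
        bundle["uncertainty"] = urun
        urun.table.to_csv(out / "percentiles_with_uncertainty.csv", index=False)
        log["stages"]["uncertainty"] = {"n_cycles": urun.n_cycles}
    else:
        log["stages"]["uncertainty"] = "skipped"

    import aggexpo

    log["version"] = aggexpo.__version__
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)
    bundle["log"] = log
    return bundle
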