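"""Turn the field survey into dose rates and national resident proportions.

Derives per-field per-compound dose rates (applied amount over sprayed
area), imputes missing resident counts from same-crop fields, raises the
counts to national totals with the survey raising factors, and expresses
them as shares of the 52.1-million adult population.  Writes the per-crop
proportion table the linking stage consumes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import STUDY_SEED, study_config, outdir

from aggexpo.synthetic import generate_field_survey
from aggexpo.usage import (
    add_dose_rates,
    estimate_resident_proportions,
    impute_missing_residents,
)

TOTAL_POPULATION = 63.2e6
ADULT_FRACTION = 0.824


def main():
    cfg = study_config()
    fields = generate_field_survey(cfg)
    n_missing = fields.drop_duplicates("field_id")["residents"].isna().sum()

    fields = add_dose_rates(fields)
    fields = impute_missing_residents(fields, STUDY_SEED)
    print(f"imputed resident counts for {n_missing} fields from same-crop pools")
    print("dose rates (kg/ha): "
          f"median {fields['dose_rate_kg_ha'].median():.3f}, "
          f"P95 {fields['dose_rate_kg_ha'].quantile(0.95):.3f}")

    props = estimate_resident_proportions(fields, TOTAL_POPULATION, ADULT_FRACTION)
    table = props.table.copy()
    table["pct_of_adults"] = 100 * table["proportion"]
    print(f"adult population: {props.adult_population / 1e6:.1f} million")
    print(table.to_string(index=False))
    print(f"total share of adults living beside a surveyed crop: "
          f"{table['pct_of_adults'].sum():.2f}%")

    out = outdir("02_usage")
    table.to_csv(out / "resident_proportions.csv", index=False)
    print(f"wrote {out / 'resident_proportions.csv'}")


if __name__ == "__main__":
    main()
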