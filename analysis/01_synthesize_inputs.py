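"""Generate the synthetic study inputs and sanity-check their structure.

Produces the four input tables (field survey, dietary diary, residue
concentrations, compound hazards), reports their shapes and the structural
facts the downstream stages rely on, and writes small samples plus the full
compound table under results/01_inputs/ (full tables are regenerated
deterministically by later scripts from the shared seed).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import study_config, outdir

from aggexpo import io as aio
from aggexpo.synthetic import generate_all


def main():
    cfg = study_config()
    tables = generate_all(cfg)
    out = outdir("01_inputs")

    fields = tables["field_survey"]
    per_field = fields.drop_duplicates("field_id")
    counts = fields.groupby("field_id")["compound"].nunique()
    print(f"field survey: {per_field.shape[0]} fields over "
          f"{fields['crop'].nunique()} crops, {len(fields)} application rows")
    print(f"  compounds per field: {counts.min()}-{counts.max()} "
          f"(mean {counts.mean():.1f})")
    print(f"  resident count missing for {per_field['residents'].isna().mean():.1%} of fields")

    diary = tables["dietary_survey"]
    print(f"dietary survey: {diary['individual_id'].nunique()} individuals x "
          f"{diary['day'].nunique()} days x {diary['food'].nunique()} foods")

    conc = tables["concentration"]
    print(f"concentrations: {len(conc)} samples, "
          f"{conc['nondetect'].mean():.1%} nondetects")

    comp = tables["compound"]
    print(f"compounds: {len(comp)} in the assessment group, "
          f"{comp['noael_mg_kg_bw_day'].isna().sum()} with LOAEL only, "
          f"reference {comp.loc[comp['is_reference'] == 1, 'compound'].iloc[0]}")

    aio.write_table(comp, out / "compound.csv", "compound")
    for name in ("field_survey", "dietary_survey", "concentration"):
        aio.write_table(tables[name].head(200), out / f"{name}_sample.csv", name)
    print(f"wrote compound table and 200-row samples to {out}")


if __name__ == "__main__":
    main()
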