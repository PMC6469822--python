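"""CSV dialects for the pipeline's input and output tables.

All tables are UTF-8 CSV with a mandatory header row, dot decimal separator
and a fixed column order per dialect; the non-dietary dialect mirrors the
MCRA NonDietaryExposure layout (idIndividual, idSurvey, compound, Dermal,
Oral, Inhalation, idUncertaintySet).  Readers validate the header and report
malformed rows with their line number; write-then-read round-trips are
lossless (floats are written at full shortest-repr precision).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .nondietary import NONDIETARY_COLUMNS
from .synthetic import (
    COMPOUND_COLUMNS,
    CONCENTRATION_COLUMNS,
    DIETARY_COLUMNS,
    FIELD_SURVEY_COLUMNS,
)

UNIT_DOSE_COLUMNS = ["draw_id", "uncertainty_id", "dermal", "oral", "inhalation"]
SURVEY_PROPS_COLUMNS = ["idSurvey", "crop_weight", "zero_proportion"]

DIALECTS: dict[str, list[str]] = {
    "field_survey": FIELD_SURVEY_COLUMNS,
    "dietary_survey": DIETARY_COLUMNS,
    "concentration": CONCENTRATION_COLUMNS,
    "compound": COMPOUND_COLUMNS,
    "nondietary": NONDIETARY_COLUMNS,
    "unit_dose": UNIT_DOSE_COLUMNS,
    "survey_properties": SURVEY_PROPS_COLUMNS,
}

_NUMERIC = {
    "area_ha", "raising_factor", "residents", "amount_kg", "bodyweight_kg",
    "amount_g", "concentration_mg_kg", "noael_mg_kg_bw_day",
    "loael_mg_kg_bw_day", "Dermal", "Oral", "Inhalation", "dermal", "oral",
    "inhalation", "crop_weight", "zero_proportion",
}
_INTEGER = {"day", "nondetect", "is_reference", "draw_id", "uncertainty_id",
            "idUncertaintySet"}


class TableFormatError(ValueError):
    """Malformed table: wrong header or unparseable row (with line number)."""


def write_table(df: pd.DataFrame, path, dialect: str) -> None:
    """Write ``df`` in the named dialect's fixed column order."""
    cols = _columns(dialect)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"cannot write {dialect}: missing columns {missing}"
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False)


def read_table(path, dialect: str) -> pd.DataFrame:
    """Read and validate a table in the named dialect.

    The header must match the dialect's columns in order; numeric fields are
    validated row by row and errors carry the 1-based file line number.
    """
    cols = _columns(dialect)
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file, expected header {cols}")
        if header != cols:
            raise TableFormatError(
                f"{path}: header {header} does not match expected columns {cols}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(cols):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(row)}"
                )
            rows.append(row)
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    for c in cols:
        if c in _NUMERIC or c in _INTEGER:
            try:
                df[c] = pd.to_numeric(df[c].replace("", None))
            except (ValueError, TypeError) as exc:
                bad = _first_bad_line(df[c])
                raise TableFormatError(
                    f"{path}:{bad}: non-numeric value in column {c!r}: {exc}"
                ) from exc
    return df


def _columns(dialect: str) -> list[str]:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise TableFormatError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


def _first_bad_line(col: pd.Series) -> int:
    for i, v in enumerate(col):
        if v is None or v == "":
            continue
        try:
            float(v)
        except (ValueError, TypeError):
            return i + 2
    return 2


def write_survey_properties(surveys, path) -> None:
    """Write the per-survey zero-proportion sidecar of a survey set."""
    df = pd.DataFrame({
        "idSurvey": sorted(surveys.crop_weights),
        "crop_weight": [surveys.crop_weights[s] for s in sorted(surveys.crop_weights)],
        "zero_proportion": [
            surveys.zero_proportion[s] for s in sorted(surveys.crop_weights)
        ],
    })
    write_table(df, path, "survey_properties")


def read_survey_set(records_path, properties_path):
    """Read a non-dietary survey set from its records + properties files."""
    from .nondietary import NonDietarySurveySet

    records = read_table(records_path, "nondietary")
    props = read_table(properties_path, "survey_properties")
    return NonDietarySurveySet(
        records=records,
        zero_proportion=dict(zip(props["idSurvey"], props["zero_proportion"])),
        crop_weights=dict(zip(props["idSurvey"], props["crop_weight"])),
    )
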