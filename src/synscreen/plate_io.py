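"""Reading, validation and writing of plate-level screen data.

The canonical input is a long (tidy) CSV, one well per row, with columns
``plate_id,row,col,cell_line,dose_level,drug1,drug2,is_control,count``
describing 1536-well (or smaller) screening plates.  A column-name mapping
can adapt files with other headers.  Every record is classified into exactly
one of three well classes:

* ``control`` -- vehicle (DMSO) well, no drug annotations;
* ``singlet`` -- a single drug;
* ``pair``    -- a two-drug combination well.

Rows and columns are 1-based, matching plate-reader conventions.  Drug
identity is the drug-name string after whitespace trimming; matching is
case-sensitive so that distinct compounds are never silently merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard 1536-well plate geometry (32 rows x 48 columns).
PLATE_SHAPE_1536: tuple[int, int] = (32, 48)

#: Canonical column order of a plate table CSV.
CANONICAL_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "cell_line",
    "dose_level",
    "drug1",
    "drug2",
    "is_control",
    "count",
]

DOSE_LEVELS = ("high", "low")

WELL_CONTROL = "control"
WELL_SINGLET = "singlet"
WELL_PAIR = "pair"


class SchemaError(ValueError):
    """An input file does not provide the required columns."""


class ValidationError(ValueError):
    """A plate table violates a structural invariant."""


@dataclass(frozen=True, order=True)
class AssayKey:
    """One (cell line, dose level) unit of the screen, fitted independently."""

    cell_line: str
    dose_level: str

    def __post_init__(self) -> None:
        if self.dose_level not in DOSE_LEVELS:
            raise ValidationError(
                f"dose_level must be one of {DOSE_LEVELS}, got {self.dose_level!r}"
            )

    def __str__(self) -> str:  # used in log messages and file names
        return f"{self.cell_line}:{self.dose_level}"


def _clean_drug(value) -> object:
    """Normalize a drug annotation: strip whitespace, empty -> pd.NA."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return pd.NA
    text = str(value).strip()
    return text if text else pd.NA


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "1", "yes"}:
        return True
    if text in {"false", "f", "0", "no", ""}:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean is_control flag")


def classify_wells(records: pd.DataFrame) -> pd.Series:
    """Classify each record as control / singlet / pair.

    Raises :class:`ValidationError` if any record fits no class (e.g. a
    control well carrying a drug annotation, or drug2 without drug1).
    """
    has1 = records["drug1"].notna()
    has2 = records["drug2"].notna()
    ctrl = records["is_control"].astype(bool)

    bad_ctrl = ctrl & (has1 | has2)
    if bad_ctrl.any():
        idx = records.index[bad_ctrl][0]
        raise ValidationError(
            f"record {idx}: control well carries a drug annotation "
            f"({records.loc[idx, 'drug1']!r}, {records.loc[idx, 'drug2']!r})"
        )
    orphan2 = has2 & ~has1
    if orphan2.any():
        idx = records.index[orphan2][0]
        raise ValidationError(f"record {idx}: drug2 present without drug1")
    self_pair = has1 & has2 & (records["drug1"] == records["drug2"])
    if self_pair.any():
        idx = records.index[self_pair][0]
        raise ValidationError(
            f"record {idx}: drug1 == drug2 == {records.loc[idx, 'drug1']!r} "
            "(self-combinations are not allowed)"
        )
    empty = ~ctrl & ~has1
    if empty.any():
        idx = records.index[empty][0]
        raise ValidationError(f"record {idx}: non-control well without any drug")

    classes = pd.Series(WELL_SINGLET, index=records.index, dtype=object)
    classes[ctrl] = WELL_CONTROL
    classes[has1 & has2] = WELL_PAIR
    return classes


@dataclass
class PlateTable:
    """Validated per-well records for one or more plates.

    ``records`` holds one row per well with the canonical columns plus a
    derived ``well_class`` column.  Row order of the input is preserved.
    """

    records: pd.DataFrame
    plate_shape: tuple[int, int] = PLATE_SHAPE_1536
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self._validated:
            self.records = _validate_records(self.records, self.plate_shape)
            self._validated = True

    @property
    def plate_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["plate_id"]))

    @property
    def assay_keys(self) -> list[AssayKey]:
        keys = self.records[["cell_line", "dose_level"]].drop_duplicates()
        return [AssayKey(c, d) for c, d in keys.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.records)


def _validate_records(records: pd.DataFrame, plate_shape: tuple[int, int]) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(records) == 0:
        raise ValidationError("plate table has no records")

    out = records.copy()
    out["plate_id"] = out["plate_id"].astype(str)
    out["cell_line"] = out["cell_line"].astype(str)
    out["dose_level"] = out["dose_level"].astype(str).str.strip().str.lower()
    bad_dose = ~out["dose_level"].isin(DOSE_LEVELS)
    if bad_dose.any():
        raise ValidationError(
            f"dose_level must be one of {DOSE_LEVELS}; "
            f"found {sorted(out.loc[bad_dose, 'dose_level'].unique())}"
        )
    for c in ("row", "col"):
        out[c] = pd.to_numeric(out[c], errors="raise").astype(int)
    out["count"] = pd.to_numeric(out["count"], errors="raise").astype(float)
    if (out["count"] < 0).any():
        idx = out.index[out["count"] < 0][0]
        raise ValidationError(f"record {idx}: negative nuclei count")
    if out["count"].isna().any():
        raise ValidationError("nuclei counts contain missing values")

    out["is_control"] = out["is_control"].map(_parse_bool)
    out["drug1"] = out["drug1"].map(_clean_drug)
    out["drug2"] = out["drug2"].map(_clean_drug)

    n_rows, n_cols = plate_shape
    oob = (out["row"] < 1) | (out["row"] > n_rows) | (out["col"] < 1) | (out["col"] > n_cols)
    if oob.any():
        idx = out.index[oob][0]
        raise ValidationError(
            f"record {idx}: well ({out.loc[idx, 'row']}, {out.loc[idx, 'col']}) "
            f"outside plate shape {plate_shape}"
        )

    dup = out.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        key = out.loc[out.index[dup][0], ["plate_id", "row", "col"]]
        raise ValidationError(
            f"duplicate well (plate={key['plate_id']!r}, row={key['row']}, col={key['col']})"
        )

    out["well_class"] = classify_wells(out)

    n_ctrl = out.groupby("plate_id", sort=False)["is_control"].sum()
    short = n_ctrl[n_ctrl < 2]
    if len(short):
        raise ValidationError(
            "every plate needs >= 2 control wells for a sample variance; "
            f"plate(s) {list(short.index)} have {list(short.values)}"
        )
    return out


def read_plate_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    plate_shape: tuple[int, int] = PLATE_SHAPE_1536,
) -> PlateTable:
    """Read and validate a long-format plate CSV.

    Parameters
    ----------
    path:
        CSV file, one well per row.
    schema:
        Optional mapping {file column name -> canonical column name} to adapt
        non-canonical headers.
    plate_shape:
        (n_rows, n_cols) geometry of the plates in the file.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    if schema:
        raw = raw.rename(columns=schema)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) after mapping: {', '.join(missing)}"
        )
    return PlateTable(records=raw[CANONICAL_COLUMNS], plate_shape=plate_shape)


def write_plate_table(table: PlateTable, path: str | Path) -> None:
    """Write a plate table back to canonical CSV (drops derived columns)."""
    table.records[CANONICAL_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any downstream result table to CSV.

    Floating-point values are written with 12 significant digits so that
    read-back reproduces comparisons at the precision they were made.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, index=False, float_format="%.12g")
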