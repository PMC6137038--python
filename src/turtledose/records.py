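"""Domain records and delimited-text I/O.

Two record types flow through the pipeline:

* :class:`NecropsyRecord` — one necropsied animal with its covariates,
  ingested-debris load (item count and total dry mass) and a four-way
  cause-of-death label.
* :class:`StrandNetRecord` — one stranding-register report, carrying only a
  debris presence/absence flag, the level to which the gastro-intestinal
  tract (GIT) was examined, and a binary age class.

Files are comma-delimited UTF-8 with a header row, "." decimal separator,
and missing mass encoded as an empty field.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import math

import pandas as pd

AGE_CLASSES = ("hatchling", "post_hatchling", "juvenile", "subadult", "adult")
#: Age classes after aggregating subadult into adult, as used in all
#: regression analyses (four levels).
AGE4_CLASSES = ("hatchling", "post_hatchling", "juvenile", "adult")
SPECIES = ("green", "hawksbill", "loggerhead", "flatback", "olive_ridley",
           "unidentified")
CAUSES = ("Ukn", "KNP", "Ind", "KP")
EXAM_LEVELS = (0, 1, 2, 3)

NECROPSY_COLUMNS = ("animal_id", "species", "age_class", "ccl_cm", "cod",
                    "debris_count", "debris_mass_g")
STRANDNET_COLUMNS = ("record_id", "debris_present", "exam_level", "adult",
                     "cod", "species")


class SchemaError(ValueError):
    """A mandatory column is missing or the file has no usable header."""


class RecordError(ValueError):
    """A row violates an enum constraint or a record invariant."""


def aggregate_age(age_class: str) -> str:
    """Collapse the five sampling age classes to the four analysis classes.

    Subadults are pooled with adults; the regressions use a single adult
    group.
    """
    if age_class not in AGE_CLASSES:
        raise RecordError(f"unknown age class {age_class!r}")
    return "adult" if age_class == "subadult" else age_class


@dataclass(frozen=True)
class NecropsyRecord:
    """One examined animal.

    ``debris_mass_g`` is the total dry mass of recovered debris; masses below
    0.01 g are floored at 0.01 g so every debris-positive animal has an
    absolute value, and mass may be missing (``None``) even when debris was
    counted.
    """

    animal_id: str
    species: str
    age_class: str
    ccl_cm: float
    cod: str
    debris_count: int
    debris_mass_g: float | None = None

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise RecordError(f"unknown species {self.species!r}")
        if self.age_class not in AGE_CLASSES:
            raise RecordError(f"unknown age class {self.age_class!r}")
        if self.cod not in CAUSES:
            raise RecordError(f"unknown cause of death {self.cod!r}")
        if not (self.ccl_cm > 0 and math.isfinite(self.ccl_cm)):
            raise RecordError(f"ccl_cm must be positive, got {self.ccl_cm}")
        if self.debris_count < 0:
            raise RecordError("debris_count must be non-negative")
        if self.cod == "KP" and self.debris_count < 1:
            raise RecordError(
                "cod 'KP' (known plastic-ingestion death) requires "
                "debris_count >= 1")
        if (self.debris_mass_g is not None and self.debris_count > 0
                and self.debris_mass_g < 0.01):
            raise RecordError(
                "debris_mass_g below the 0.01 g floor for a debris-positive "
                "animal")
        if self.debris_mass_g is not None and self.debris_mass_g < 0:
            raise RecordError("debris_mass_g must be non-negative")


@dataclass(frozen=True)
class StrandNetRecord:
    """One stranding-register report.

    ``exam_level`` scores how thoroughly the GIT contents were examined
    (0 = not examined … 3 = sieved); ``adult`` is the binary age class used
    in the presence/absence model.
    """

    record_id: str
    debris_present: bool
    exam_level: int
    adult: bool
    cod: str
    species: str | None = None

    def validate(self) -> None:
        if self.exam_level not in EXAM_LEVELS:
            raise RecordError(f"exam_level must be 0-3, got {self.exam_level}")
        if self.cod not in CAUSES:
            raise RecordError(f"unknown cause of death {self.cod!r}")
        if self.species is not None and self.species not in SPECIES:
            raise RecordError(f"unknown species {self.species!r}")
        if self.cod == "KP" and not self.debris_present:
            raise RecordError(
                "cod 'KP' requires debris_present to be true")


def necropsy_frame(records: Iterable[NecropsyRecord]) -> pd.DataFrame:
    """Tabulate necropsy records, adding the aggregated ``age4`` column."""
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(NecropsyRecord)}
            for r in records]
    df = pd.DataFrame(rows, columns=list(NECROPSY_COLUMNS))
    if len(df):
        df["age4"] = df["age_class"].map(aggregate_age)
    else:
        df["age4"] = pd.Series(dtype=object)
    return df


def strandnet_frame(records: Iterable[StrandNetRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(StrandNetRecord)}
            for r in records]
    return pd.DataFrame(rows, columns=list(STRANDNET_COLUMNS))


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_bool(value, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise RecordError(f"line {line}: cannot parse {column}={value!r} as bool")


def read_necropsy(path: str | Path) -> list[NecropsyRecord]:
    """Read a necropsy CSV; unknown columns are preserved in the file but
    ignored here.  Row errors carry the 1-based file line number."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, NECROPSY_COLUMNS, path)
    out: list[NecropsyRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            mass = row["debris_mass_g"].strip()
            rec = NecropsyRecord(
                animal_id=row["animal_id"],
                species=row["species"].strip(),
                age_class=row["age_class"].strip(),
                ccl_cm=float(row["ccl_cm"]),
                cod=row["cod"].strip(),
                debris_count=int(row["debris_count"]),
                debris_mass_g=float(mass) if mass != "" else None,
            )
            rec.validate()
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path} line {line}: {exc}") from exc
        out.append(rec)
    return out


def read_strandnet(path: str | Path) -> list[StrandNetRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, STRANDNET_COLUMNS, path)
    out: list[StrandNetRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            sp = row["species"].strip()
            rec = StrandNetRecord(
                record_id=row["record_id"],
                debris_present=_parse_bool(row["debris_present"], line,
                                           "debris_present"),
                exam_level=int(row["exam_level"]),
                adult=_parse_bool(row["adult"], line, "adult"),
                cod=row["cod"].strip(),
                species=sp if sp != "" else None,
            )
            rec.validate()
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path} line {line}: {exc}") from exc
        out.append(rec)
    return out


def write_necropsy(records: Iterable[NecropsyRecord], path: str | Path) -> None:
    df = necropsy_frame(records).drop(columns=["age4"])
    df["debris_mass_g"] = df["debris_mass_g"].map(
        lambda m: "" if m is None or (isinstance(m, float) and math.isnan(m))
        else repr(float(m)))
    df.to_csv(path, index=False)


def write_strandnet(records: Iterable[StrandNetRecord],
                    path: str | Path) -> None:
    df = strandnet_frame(records).copy()
    df["species"] = df["species"].map(lambda s: "" if s is None else s)
    df.to_csv(path, index=False)
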