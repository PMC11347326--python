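"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS quarterly extracts ship as dollar-delimited UTF-8 text files, one
table per file (DEMO, DRUG, REAC, THER, ...), first line a header of
column names.  The dialect has no quoting or escaping: the ``$``
delimiter never occurs inside a field.  Column-name case changed across
FDA release years, so names are upper-cased on read.

Dates in FAERS are partial: ``YYYYMMDD``, ``YYYYMM``, ``YYYY`` or blank.
:class:`PartialDate` keeps the stated precision explicit so downstream
steps (time-to-onset needs day precision) can filter on it.
"""

from __future__ import annotations

import datetime
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "TableKind",
    "DatePrecision",
    "PartialDate",
    "RawTable",
    "SchemaError",
    "read_faers_table",
    "write_faers_table",
    "parse_partial_date",
]

DELIMITER = "$"


class TableKind(str, enum.Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    THER = "THER"


#: Columns that must be present (possibly among others) for each table kind.
REQUIRED_COLUMNS: dict[TableKind, tuple[str, ...]] = {
    TableKind.DEMO: (
        "PRIMARYID",
        "CASEID",
        "FDA_DT",
        "EVENT_DT",
        "SEX",
        "AGE",
        "AGE_COD",
        "OCCP_COD",
        "REPORTER_COUNTRY",
    ),
    TableKind.DRUG: ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
    TableKind.REAC: ("PRIMARYID", "PT"),
    TableKind.THER: ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT"),
}


class SchemaError(ValueError):
    """A table is missing a column required for its kind."""


class DatePrecision(str, enum.Enum):
    DAY = "DAY"
    MONTH = "MONTH"
    YEAR = "YEAR"
    MISSING = "MISSING"


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date at whatever precision the report stated.

    Invariants: DAY precision has a valid calendar (year, month, day);
    MONTH precision has day ``None``; YEAR precision has month and day
    ``None``; MISSING has all three ``None``.
    """

    year: int | None
    month: int | None
    day: int | None
    precision: DatePrecision

    @staticmethod
    def missing() -> "PartialDate":
        return PartialDate(None, None, None, DatePrecision.MISSING)

    def to_date(self) -> datetime.date:
        """Calendar date; only defined at DAY precision."""
        if self.precision is not DatePrecision.DAY:
            raise ValueError(f"date has {self.precision.value} precision, not DAY")
        return datetime.date(self.year, self.month, self.day)

    def __str__(self) -> str:  # FAERS-style rendering
        if self.precision is DatePrecision.DAY:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.precision is DatePrecision.MONTH:
            return f"{self.year:04d}{self.month:02d}"
        if self.precision is DatePrecision.YEAR:
            return f"{self.year:04d}"
        return ""


@dataclass
class RawTable:
    """One FAERS ASCII table held as a list of field-maps.

    Every row shares the same key set (the upper-cased header), which is
    a superset of :data:`REQUIRED_COLUMNS` for ``table_kind``.
    """

    table_kind: TableKind
    quarter_label: str
    rows: list[dict[str, str]] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        if self.rows:
            return list(self.rows[0].keys())
        return list(REQUIRED_COLUMNS[self.table_kind])

    def validate(self) -> None:
        required = set(REQUIRED_COLUMNS[self.table_kind])
        cols = set(self.columns)
        missing = required - cols
        if missing:
            raise SchemaError(
                f"{self.table_kind.value} table missing required column(s): "
                + ", ".join(sorted(missing))
            )
        for i, row in enumerate(self.rows):
            if set(row.keys()) != cols:
                raise SchemaError(f"row {i} key set differs from header")


def read_faers_table(
    path: str | Path,
    table_kind: TableKind | str,
    quarter_label: str = "",
) -> RawTable:
    """Read a dollar-delimited FAERS ASCII file.

    One row per non-header line; fields split on ``$``; trailing
    whitespace stripped from each field; empty fields kept as ``""``.
    Raises :class:`SchemaError` naming the column if a required column
    for ``table_kind`` is absent.
    """
    table_kind = TableKind(table_kind)
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, no header line")
        columns = [c.strip().upper() for c in header_line.rstrip("\n").split(DELIMITER)]
        rows: list[dict[str, str]] = []
        for line in fh:
            fields = [f.rstrip() for f in line.rstrip("\n").split(DELIMITER)]
            # Pad short lines so every row has the full key set.
            if len(fields) < len(columns):
                fields += [""] * (len(columns) - len(fields))
            rows.append(dict(zip(columns, fields)))
    table = RawTable(table_kind=table_kind, quarter_label=quarter_label, rows=rows)
    required = set(REQUIRED_COLUMNS[table_kind])
    missing = required - set(columns)
    if missing:
        raise SchemaError(
            f"{path}: {table_kind.value} table missing required column(s): "
            + ", ".join(sorted(missing))
        )
    return table


def write_faers_table(table: RawTable, path: str | Path) -> None:
    """Write ``table`` in the FAERS ASCII dialect (header + ``$`` rows).

    ``read_faers_table(write_faers_table(t)) == t`` for any schema-valid
    table: there is no quoting layer because ``$`` never occurs inside a
    FAERS field.
    """
    table.validate()
    path = Path(path)
    cols = table.columns
    with path.open("w", encoding="utf-8") as fh:
        fh.write(DELIMITER.join(cols) + "\n")
        for row in table.rows:
            fh.write(DELIMITER.join(row[c] for c in cols) + "\n")


def parse_partial_date(raw: str) -> PartialDate:
    """Parse a FAERS date string into a :class:`PartialDate`.

    Length 8 digits -> DAY, 6 -> MONTH, 4 -> YEAR; anything empty,
    non-numeric, of another length, or calendar-invalid maps to MISSING
    (logged, never raised).
    """
    raw = raw.strip()
    if not raw or not raw.isdigit():
        if raw:
            logger.debug("unparseable date %r -> MISSING", raw)
        return PartialDate.missing()
    try:
        if len(raw) == 8:
            d = datetime.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
            return PartialDate(d.year, d.month, d.day, DatePrecision.DAY)
        if len(raw) == 6:
            year, month = int(raw[:4]), int(raw[4:6])
            if not 1 <= month <= 12:
                raise ValueError(month)
            return PartialDate(year, month, None, DatePrecision.MONTH)
        if len(raw) == 4:
            return PartialDate(int(raw), None, None, DatePrecision.YEAR)
    except ValueError:
        pass
    logger.debug("invalid calendar value %r -> MISSING", raw)
    return PartialDate.missing()


def count_missing_dates(values: Iterable[str]) -> int:
    """How many of ``values`` parse to MISSING (for the run log)."""
    return sum(
        1 for v in values if parse_partial_date(v).precision is DatePrecision.MISSING
    )
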