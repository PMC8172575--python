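"""Sense-inventory records and delimited-text input/output.

A sense inventory is a flat table in which each row (record) maps one
abbreviation *short form* (SF, e.g. ``"O.C."``) to one spelled-out *long form*
(LF, e.g. ``"oral contraceptives"``) as found in a named source inventory.
The core table carries ten columns::

    GroupID RecordID SF SFUI NormSF LF LFUI NormLF Source Modified

Auxiliary columns unique to a single source (frequencies, UMLS identifiers,
...) can be appended after ``Modified`` in the "auxiliary" version of the
table.  Files are tab-separated UTF-8 with a header row; text is normalized
to Unicode NFC on read so that identifier assignment and string metrics are
stable across encodings.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: Serialized value for a normalized form the normalizer could not produce
#: (e.g. chemical names): the literal string "null".
NULL_MARKER = "null"

#: The ten core columns, in file order.
CORE_COLUMNS = (
    "GroupID",
    "RecordID",
    "SF",
    "SFUI",
    "NormSF",
    "LF",
    "LFUI",
    "NormLF",
    "Source",
    "Modified",
)

#: Columns that must be present in any readable file.
MANDATORY_COLUMNS = ("SF", "LF", "Source")

MODIFIED_FLAG = "modified"


class SchemaError(ValueError):
    """A mandatory column is missing from an inventory file."""


class RowValidationError(ValueError):
    """A data row violates the record contract (e.g. empty SF or LF)."""


class SourceConflictError(ValueError):
    """Two inventories being merged declare the same source name."""


@dataclass
class Record:
    """One (short form, long form, source) row of a sense inventory."""

    sf: str
    lf: str
    source: str
    group_id: str = ""
    record_id: str = ""
    sfui: str = ""
    norm_sf: str = ""
    lfui: str = ""
    norm_lf: str = ""
    modified: str = ""
    aux: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sf.strip():
            raise RowValidationError("short form must be non-empty")
        if not self.lf.strip():
            raise RowValidationError("long form must be non-empty")

    def copy(self) -> "Record":
        return replace(self, aux=dict(self.aux))


@dataclass
class SenseInventory:
    """An ordered collection of records plus source bookkeeping.

    ``source_order`` preserves the order in which sources were read or
    merged; ``aux_schema`` maps each source name to the auxiliary column
    names its records may carry.
    """

    records: list[Record] = field(default_factory=list)
    source_order: list[str] = field(default_factory=list)
    aux_schema: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.source_order)
        for rec in self.records:
            if rec.source not in known:
                self.source_order.append(rec.source)
                known.add(rec.source)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record_by_id(self, record_id: str) -> Record:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def copy(self) -> "SenseInventory":
        return SenseInventory(
            records=[r.copy() for r in self.records],
            source_order=list(self.source_order),
            aux_schema={s: list(c) for s, c in self.aux_schema.items()},
        )

    def aux_columns(self) -> list[str]:
        """Auxiliary column names, union over sources in source order."""
        cols: list[str] = []
        for source in self.source_order:
            for col in self.aux_schema.get(source, ()):
                if col not in cols:
                    cols.append(col)
        return cols


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def read_inventory(path: str | Path, delimiter: str = "\t") -> SenseInventory:
    """Read a delimited inventory file into a :class:`SenseInventory`.

    Unknown columns are captured into each record's ``aux`` mapping; missing
    optional core columns yield empty fields.  Raises :class:`SchemaError`
    when SF, LF or Source is absent from the header and
    :class:`RowValidationError` (with the 1-based row number) when a data
    row has an empty SF or LF cell.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = [_nfc(col).strip() for col in next(reader)]
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header row required") from None
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: mandatory column {col!r} missing")
        idx = {col: i for i, col in enumerate(header)}
        aux_cols = [c for c in header if c not in CORE_COLUMNS]

        def cell(row: Sequence[str], col: str) -> str:
            i = idx.get(col)
            if i is None or i >= len(row):
                return ""
            return _nfc(row[i])

        records: list[Record] = []
        aux_schema: dict[str, list[str]] = {}
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            sf, lf = cell(row, "SF"), cell(row, "LF")
            if not sf.strip():
                raise RowValidationError(f"{path}: row {rownum}: empty SF")
            if not lf.strip():
                raise RowValidationError(f"{path}: row {rownum}: empty LF")
            source = cell(row, "Source")
            aux = {c: cell(row, c) for c in aux_cols if cell(row, c) != ""}
            records.append(
                Record(
                    sf=sf,
                    lf=lf,
                    source=source,
                    group_id=cell(row, "GroupID"),
                    record_id=cell(row, "RecordID"),
                    sfui=cell(row, "SFUI"),
                    norm_sf=cell(row, "NormSF"),
                    lfui=cell(row, "LFUI"),
                    norm_lf=cell(row, "NormLF"),
                    modified=cell(row, "Modified"),
                    aux=aux,
                )
            )
            if source not in aux_schema:
                aux_schema[source] = list(aux_cols)
    source_order: list[str] = []
    for rec in records:
        if rec.source not in source_order:
            source_order.append(rec.source)
    return SenseInventory(records=records, source_order=source_order, aux_schema=aux_schema)


def write_inventory(
    inv: SenseInventory,
    path: str | Path,
    include_aux: bool = False,
    delimiter: str = "\t",
) -> Path:
    """Write an inventory as a delimited file; returns the path written.

    With ``include_aux`` the auxiliary columns are appended after
    ``Modified`` (the "auxiliary version" of the table); otherwise exactly
    the ten core columns are written.
    """
    path = Path(path)
    aux_cols = inv.aux_columns() if include_aux else []
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(list(CORE_COLUMNS) + aux_cols)
        for rec in inv.records:
            row = [
                rec.group_id,
                rec.record_id,
                rec.sf,
                rec.sfui,
                rec.norm_sf,
                rec.lf,
                rec.lfui,
                rec.norm_lf,
                rec.source,
                rec.modified,
            ]
            row.extend(rec.aux.get(c, "") for c in aux_cols)
            writer.writerow(row)
    return path


def merge_sources(inventories: Sequence[SenseInventory]) -> SenseInventory:
    """Concatenate inventories, preserving within-source and input order.

    Raises :class:`SourceConflictError` if the same source name appears in
    two different input inventories (records for one source must arrive
    together so that source-order identifier assignment stays meaningful).
    """
    if not inventories:
        raise ValueError("merge_sources requires at least one inventory")
    seen: set[str] = set()
    records: list[Record] = []
    source_order: list[str] = []
    aux_schema: dict[str, list[str]] = {}
    for inv in inventories:
        for source in inv.source_order:
            if source in seen:
                raise SourceConflictError(f"source {source!r} appears in more than one input")
        seen.update(inv.source_order)
        source_order.extend(inv.source_order)
        records.extend(rec.copy() for rec in inv.records)
        for source, cols in inv.aux_schema.items():
            merged = aux_schema.setdefault(source, [])
            for col in cols:
                if col not in merged:
                    merged.append(col)
    return SenseInventory(records=records, source_order=source_order, aux_schema=aux_schema)
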