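"""Sample metadata tables: data model, TSV I/O and typed value parsing.

Two interchangeable layouts are supported, both UTF-8 TSV with a header row:

* wide — ``sample_id  package  <term columns...>``, one row per sample; the
  ``relationship_to_other_samples`` cell holds ``;``-separated entries.
* long — ``sample_id  attribute  value``, one row per attribute; a ``package``
  row is mandatory per sample and ``relationship_to_other_samples`` rows may
  repeat (each repeat adds one relationship entry).

An optional leading comment line ``# bioproject=<token>`` carries the
Bioproject scope of the table through both layouts.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from .errors import (
    DuplicateAttributeError,
    DuplicateSampleError,
    TableFormatError,
    ValueSyntaxError,
)
from .registry import Registry, TermDefinition, canonical_key

__all__ = [
    "SampleRecord",
    "MetadataTable",
    "TypedValue",
    "read_table_wide",
    "read_table_long",
    "read_table",
    "write_table",
    "parse_value",
    "split_list_value",
    "RELATIONSHIP_TERM",
]

RELATIONSHIP_TERM = "relationship_to_other_samples"

_FORBIDDEN_IN_ID = ("\t", "\n", "\r", ";", ":")

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*:[A-Za-z0-9_.\-]+$")
_OBO_PURL_RE = re.compile(r"^https?://purl\.obolibrary\.org/obo/[A-Za-z0-9_]+$")
_DURATION_RE = re.compile(r"^([0-9]+(?:\.[0-9]+)?)\s*([A-Za-z]+)$")


@dataclass
class TypedValue:
    """A raw cell value parsed according to a term's expected syntax."""

    syntax_class: str
    value: object


@dataclass
class SampleRecord:
    """One sample: identifier, package assignment and attribute map.

    ``attributes`` keys are canonical term keys; insertion order is the column
    order of the source document. Relationship entries are kept raw here and
    interpreted by the graph module.
    """

    sample_id: str
    package: str
    attributes: dict[str, str] = field(default_factory=dict)
    relationship_entries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise TableFormatError("sample_id must be non-empty")
        for ch in _FORBIDDEN_IN_ID:
            if ch in self.sample_id:
                raise TableFormatError(
                    f"sample_id {self.sample_id!r} contains forbidden character {ch!r}"
                )


@dataclass
class MetadataTable:
    """All samples of one Bioproject."""

    records: list[SampleRecord] = field(default_factory=list)
    bioproject_id: str | None = None

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def get(self, sample_id: str) -> SampleRecord | None:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        return None


# -------------------------------------------------------------------- input

def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, Path):
        return open(source, encoding="utf-8", newline="")
    if isinstance(source, str):
        if "\t" in source or "\n" in source:
            return io.StringIO(source)
        return open(source, encoding="utf-8", newline="")
    return source


def _read_rows(source: str | Path | IO[str]) -> tuple[str | None, list[list[str]]]:
    """Read TSV rows, peeling an optional ``# bioproject=`` comment line."""
    handle = _open_text(source)
    text = handle.read()
    handle.close()
    bioproject = None
    lines = text.splitlines()
    if lines and lines[0].lstrip().startswith("#"):
        comment = lines.pop(0).lstrip("# ").strip()
        if comment.startswith("bioproject="):
            bioproject = comment.split("=", 1)[1].strip() or None
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter="\t")
    rows = [row for row in reader if any(cell.strip() for cell in row)]
    return bioproject, rows


def _canonical_header(registry: Registry | None, header: str) -> str:
    """Resolve a column header through the registry alias table when known;
    unknown headers are kept (canonicalized) for the validator to flag."""
    key = canonical_key(header)
    if registry is not None and registry.has_term(key):
        return registry.get_term(key).canonical_name
    return key


def _split_relationship_cell(raw: str) -> list[str]:
    return [entry.strip() for entry in raw.split(";") if entry.strip()]


def read_table_wide(
    source: str | Path | IO[str], registry: Registry | None = None
) -> MetadataTable:
    """Parse a wide-layout table (one row per sample)."""
    bioproject, rows = _read_rows(source)
    if not rows:
        return MetadataTable(bioproject_id=bioproject)
    header = [h.strip() for h in rows[0]]
    if len(header) < 2 or canonical_key(header[0]) != "sample_id" or canonical_key(header[1]) != "package":
        raise TableFormatError(
            "wide layout requires leading 'sample_id' and 'package' columns, "
            f"got {header[:2]}"
        )
    term_cols = [_canonical_header(registry, h) for h in header[2:]]
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for row in rows[1:]:
        row = list(row) + [""] * (len(header) - len(row))
        sample_id = row[0].strip()
        if sample_id in seen:
            raise DuplicateSampleError(f"sample_id {sample_id!r} appears twice")
        seen.add(sample_id)
        record = SampleRecord(sample_id=sample_id, package=row[1].strip())
        for col, cell in zip(term_cols, row[2:]):
            cell = cell.strip()
            if not cell:
                continue  # empty cell == attribute absent
            if col == RELATIONSHIP_TERM:
                record.relationship_entries.extend(_split_relationship_cell(cell))
            else:
                record.attributes[col] = cell
        records.append(record)
    return MetadataTable(records=records, bioproject_id=bioproject)


def read_table_long(
    source: str | Path | IO[str], registry: Registry | None = None
) -> MetadataTable:
    """Parse a long-layout table (one row per sample/attribute pair)."""
    bioproject, rows = _read_rows(source)
    if not rows:
        return MetadataTable(bioproject_id=bioproject)
    header = [canonical_key(h) for h in rows[0]]
    if header != ["sample_id", "attribute", "value"]:
        raise TableFormatError(
            f"long layout requires columns sample_id/attribute/value, got {rows[0]}"
        )
    order: list[str] = []
    by_id: dict[str, SampleRecord] = {}
    packages: dict[str, str] = {}
    for row in rows[1:]:
        row = list(row) + [""] * (3 - len(row))
        sample_id, attribute, value = (c.strip() for c in row[:3])
        attr_key = _canonical_header(registry, attribute)
        if sample_id not in by_id:
            # package patched in after the scan; placeholder keeps row order
            by_id[sample_id] = SampleRecord(sample_id=sample_id, package="?")
            order.append(sample_id)
        record = by_id[sample_id]
        if not value:
            continue
        if attr_key == "package":
            if sample_id in packages:
                raise DuplicateAttributeError(
                    f"sample {sample_id!r} has more than one package row"
                )
            packages[sample_id] = value
        elif attr_key == RELATIONSHIP_TERM:
            record.relationship_entries.extend(_split_relationship_cell(value))
        else:
            if attr_key in record.attributes:
                raise DuplicateAttributeError(
                    f"scalar attribute {attr_key!r} repeated for sample {sample_id!r}"
                )
            record.attributes[attr_key] = value
    missing = [sid for sid in order if sid not in packages]
    if missing:
        raise TableFormatError(f"samples without a package row: {missing}")
    for sid, record in by_id.items():
        record.package = packages[sid]
    return MetadataTable(records=[by_id[s] for s in order], bioproject_id=bioproject)


def read_table(
    source: str | Path | IO[str],
    layout: str = "wide",
    registry: Registry | None = None,
) -> MetadataTable:
    if layout == "wide":
        return read_table_wide(source, registry)
    if layout == "long":
        return read_table_long(source, registry)
    raise TableFormatError(f"unknown layout {layout!r}")


# ------------------------------------------------------------------- output

def write_table(table: MetadataTable, layout: str = "wide") -> str:
    """Serialize a table; re-reading the result reproduces the table."""
    out = io.StringIO()
    if table.bioproject_id:
        out.write(f"# bioproject={table.bioproject_id}\n")
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    if layout == "wide":
        columns: list[str] = []
        for record in table.records:
            for key in record.attributes:
                if key not in columns:
                    columns.append(key)
        has_rel = any(r.relationship_entries for r in table.records)
        if has_rel:
            columns.append(RELATIONSHIP_TERM)
        writer.writerow(["sample_id", "package", *columns])
        for record in table.records:
            row = [record.sample_id, record.package]
            for col in columns:
                if col == RELATIONSHIP_TERM and has_rel:
                    row.append(";".join(record.relationship_entries))
                else:
                    row.append(record.attributes.get(col, ""))
            writer.writerow(row)
    elif layout == "long":
        writer.writerow(["sample_id", "attribute", "value"])
        for record in table.records:
            writer.writerow([record.sample_id, "package", record.package])
            for key, value in record.attributes.items():
                writer.writerow([record.sample_id, key, value])
            for entry in record.relationship_entries:
                writer.writerow([record.sample_id, RELATIONSHIP_TERM, entry])
    else:
        raise TableFormatError(f"unknown layout {layout!r}")
    return out.getvalue()


# ----------------------------------------------------------- value parsing

def split_list_value(raw: str) -> list[str]:
    """Split a comma-separated list value, trimming and dropping empties."""
    return [item.strip() for item in raw.split(",") if item.strip()]


def parse_value(term: TermDefinition, raw: str) -> TypedValue:
    """Parse a raw cell against the term's expected value syntax.

    Checks are syntactic only: a taxon id must be a positive base-10 integer
    but is not resolved against a taxonomy; an ontology term must look like a
    CURIE (``PREFIX:ID``) or an OBO PURL but is not dereferenced.
    """
    raw = raw.strip()
    if not raw:
        raise ValueSyntaxError("empty value", term=term.canonical_name, raw=raw)
    syntax = term.value_syntax

    def fail(why: str) -> ValueSyntaxError:
        return ValueSyntaxError(
            f"{term.canonical_name}: {why}: {raw!r}",
            term=term.canonical_name,
            raw=raw,
        )

    if syntax == "free_text":
        return TypedValue(syntax, raw)
    if syntax == "taxon_id":
        if not raw.isdigit() or int(raw) <= 0:
            raise fail("expected a positive base-10 taxon id")
        return TypedValue(syntax, int(raw))
    if syntax == "integer_count":
        if not raw.isdigit():
            raise fail("expected a non-negative integer count")
        return TypedValue(syntax, int(raw))
    if syntax == "taxon_name_list":
        items = split_list_value(raw)
        if not items:
            raise fail("expected at least one taxon name")
        return TypedValue(syntax, items)
    if syntax == "ontology_term":
        if _OBO_PURL_RE.match(raw):
            prefix, local = raw.rsplit("/", 1)[1].split("_", 1)
            return TypedValue(syntax, {"prefix": prefix, "local_id": local})
        if _CURIE_RE.match(raw):
            prefix, local = raw.split(":", 1)
            return TypedValue(syntax, {"prefix": prefix, "local_id": local})
        raise fail("expected a PREFIX:ID ontology token or an OBO PURL")
    if syntax == "duration":
        m = _DURATION_RE.match(raw)
        if not m:
            raise fail("expected '<magnitude> <unit>' (e.g. '14 days')")
        return TypedValue(syntax, {"magnitude": float(m.group(1)), "unit": m.group(2)})
    if syntax == "relationship_list":
        entries = _split_relationship_cell(raw)
        if not entries:
            raise fail("expected at least one relationship entry")
        return TypedValue(syntax, entries)
    if syntax == "enumeration":
        return TypedValue(syntax, raw)
    raise fail(f"unhandled value syntax {syntax!r}")  # pragma: no cover
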