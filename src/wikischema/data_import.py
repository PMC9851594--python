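"""Turn tabular data into importable wiki pages.

A data TSV has one header row of property labels and one row per
entity.  Each row becomes a MAIN-namespace page whose entire text is a
call to the category's template, so annotations stay uniform.  Entities
are deliberately titled with progressive numbers ("Patients 1",
"Patients 2", ...) rather than personal details: the page title is a
stable surrogate key, and a display title can be layered on later.
Records of a child category (one with a connection to a parent
category) live on subpages of their parent ("Patients 1/Visits 2"),
which keeps titles unique and the one-to-many relation navigable.

The reserved column ``!parent`` holds the 1-based row index of the
record's parent in the companion parent table.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .schema_core import (
    CategorySpec,
    ConstraintKind,
    Diagnostic,
    PropertySpec,
    PropertyType,
    Schema,
    SchemaParseError,
    Severity,
)
from .xml_emitter import EmitOptions, Namespace, WikiPage, WikiXmlDocument


class _Missing:
    """Sentinel for an unentered cell.

    Distinct from the three-valued "NA", which is an explicitly recorded
    "not available" answer; MISSING means nobody has considered the
    field yet.
    """

    _instance: Optional["_Missing"] = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: A typed cell value: number, date, bool, string (text/enum/tristate/
#: page-title/url), or a (lat, lon) coordinate pair.
Value = Union[float, int, dt.date, bool, str, tuple[float, float]]

PARENT_COLUMN = "!parent"


@dataclass(frozen=True)
class Record:
    category: str
    index: int = 0
    title: str = ""
    parent_title: Optional[str] = None
    values: dict[str, Union[Value, _Missing]] = field(default_factory=dict)

    def value(self, label: str) -> Union[Value, _Missing]:
        return self.values.get(label, MISSING)


@dataclass
class RecordSet:
    schema: Schema
    records: list[Record] = field(default_factory=list)

    def of_category(self, name: str) -> list[Record]:
        return [r for r in self.records if r.category == name]

    def by_title(self, title: str) -> Optional[Record]:
        for r in self.records:
            if r.title == title:
                return r
        return None


# ---------------------------------------------------------------------------
# Cell parsing per type


_TRUE = {"yes", "true", "1"}
_FALSE = {"no", "false", "0"}


def parse_cell(cell: str, p: PropertySpec) -> Value:
    """Parse one non-empty cell according to its property type.

    Raises ``ValueError`` on unparseable input or constraint violation.
    """
    cell = cell.strip()
    t, k = p.type, p.constraint
    if t is PropertyType.NUMBER:
        v = float(cell)
        if k.kind is ConstraintKind.RANGE and not (k.min <= v <= k.max):
            raise ValueError(f"{v} outside range [{k.min}, {k.max}]")
        return int(v) if v.is_integer() and "." not in cell and "e" not in cell.lower() else v
    if t is PropertyType.DATE:
        return dt.date.fromisoformat(cell)
    if t is PropertyType.BOOLEAN:
        low = cell.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"not a boolean: {cell!r}")
    if t in (PropertyType.TRISTATE, PropertyType.ENUM):
        if k.kind is ConstraintKind.DOMAIN and cell not in k.values:
            raise ValueError(f"{cell!r} not in domain {list(k.values)}")
        return cell
    if t is PropertyType.COORDINATES:
        m = re.fullmatch(r"\s*(-?\d+(?:\.\d+)?)\s*,\s*(-?\d+(?:\.\d+)?)\s*", cell)
        if not m:
            raise ValueError(f"not a 'lat, lon' pair: {cell!r}")
        lat, lon = float(m.group(1)), float(m.group(2))
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinates out of bounds: {cell!r}")
        return (lat, lon)
    # TEXT, PAGE, URL: the raw string
    return cell


# ---------------------------------------------------------------------------
# Wikitext-safe value encoding

_ESCAPES = [
    ("&", "&amp;"),  # must come first; makes decoding unambiguous
    ("|", "&#124;"),
    ("{", "&#123;"),
    ("}", "&#125;"),
    ("=", "&#61;"),
]


def _escape(s: str) -> str:
    for ch, ent in _ESCAPES:
        s = s.replace(ch, ent)
    return s


def _unescape(s: str) -> str:
    for ch, ent in reversed(_ESCAPES):
        s = s.replace(ent, ch)
    return s


def format_number(v: float) -> str:
    """Locale-free decimal rendering; integers drop the trailing '.0'."""
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def encode_value(v: Value, p: PropertySpec) -> str:
    """Render a typed value as a template-argument string.

    Numbers use no locale separators, dates are ISO-8601, coordinates
    are decimal-degree "lat, lon", booleans are Yes/No, and wikitext
    metacharacters are escaped with their numeric entities so the
    encoding is inverse-decodable.
    """
    t = p.type
    if t is PropertyType.NUMBER:
        return format_number(v)
    if t is PropertyType.DATE:
        return v.isoformat()
    if t is PropertyType.BOOLEAN:
        return "Yes" if v else "No"
    if t is PropertyType.COORDINATES:
        lat, lon = v
        return f"{format_number(lat)}, {format_number(lon)}"
    return _escape(str(v))


def decode_value(s: str, p: PropertySpec) -> Value:
    """Inverse of :func:`encode_value` for every representable value."""
    t = p.type
    if t in (PropertyType.NUMBER, PropertyType.DATE, PropertyType.BOOLEAN,
             PropertyType.COORDINATES):
        return parse_cell(s, p)
    return _unescape(s)


# ---------------------------------------------------------------------------
# Data TSV parsing


def parse_data(
    tsv_text: str,
    schema: Schema,
    category: str,
    parents: Optional[RecordSet] = None,
) -> RecordSet:
    """Parse a data TSV whose columns are property labels of ``category``.

    Values are typed per the schema; empty cells become MISSING; a "NA"
    cell in a three-valued column is the NA value, never MISSING.
    Constraint violations, unknown columns and unparseable cells are
    ERROR diagnostics addressed by row and column; any ERROR raises
    :class:`~wikischema.schema_core.SchemaParseError`.

    ``parents`` supplies the records the reserved ``!parent`` column
    indexes into (required for child categories with a connection).
    """
    cat = schema.category(category)
    if cat is None:
        raise SchemaParseError(
            [Diagnostic(Severity.ERROR, 1, f"unknown category {category!r}")]
        )
    diags: list[Diagnostic] = []
    lines = tsv_text.lstrip("﻿").splitlines()
    if not lines or not lines[0].strip():
        raise SchemaParseError([Diagnostic(Severity.ERROR, 1, "missing header row")])
    header = [h.strip() for h in lines[0].split("\t")]
    columns: list[Optional[PropertySpec]] = []
    parent_col: Optional[int] = None
    for i, label in enumerate(header):
        if label == PARENT_COLUMN:
            parent_col = i
            columns.append(None)
            continue
        p = cat.property_by_label(label)
        if p is None:
            diags.append(
                Diagnostic(Severity.ERROR, 1, f"unknown column label {label!r}")
            )
        columns.append(p)
    if cat.connection is not None and parent_col is not None and parents is None:
        diags.append(
            Diagnostic(Severity.ERROR, 1, "!parent column given but no parent records")
        )

    records: list[Record] = []
    parent_records = parents.of_category(cat.connection[1]) if (
        parents is not None and cat.connection is not None
    ) else []
    # an empty line is an all-MISSING row, not a separator: newlines are
    # structural in this dialect
    for lineno, raw in enumerate(lines[1:], start=2):
        cells = raw.split("\t")
        cells += [""] * (len(header) - len(cells))
        values: dict[str, Union[Value, _Missing]] = {}
        parent_title: Optional[str] = None
        for i, cell in enumerate(cells[: len(header)]):
            cell = cell.strip()
            if i == parent_col:
                if not cell:
                    continue
                try:
                    idx = int(cell)
                    parent_title = parent_records[idx - 1].title
                except (ValueError, IndexError):
                    diags.append(
                        Diagnostic(
                            Severity.ERROR, lineno,
                            f"row {lineno - 1}: bad parent index {cell!r}",
                        )
                    )
                continue
            p = columns[i]
            if p is None:
                continue  # unknown column already reported on the header
            if cell == "":
                values[p.label] = MISSING
                continue
            try:
                values[p.label] = parse_cell(cell, p)
            except ValueError as exc:
                diags.append(
                    Diagnostic(
                        Severity.ERROR, lineno,
                        f"row {lineno - 1}, column {p.label!r}: {exc}",
                    )
                )
        records.append(Record(category=category, values=values, parent_title=parent_title))

    if any(d.severity is Severity.ERROR for d in diags):
        raise SchemaParseError(diags)
    rs = RecordSet(schema=schema, records=records)
    return assign_titles(rs)


def assign_titles(
    rs: RecordSet,
    start_index: int = 1,
    existing_titles: Optional[set[str]] = None,
) -> RecordSet:
    """Assign progressive-number titles.

    Top-level records become ``<Category> <i>`` with consecutive indices
    from ``start_index``; records of a connected (child) category become
    subpages ``<parent_title>/<Category> <k>`` with ``k`` counted per
    parent.  Title collisions — including against ``existing_titles``
    from an earlier import — are an error rather than a silent conflict.
    """
    if start_index < 1:
        raise ValueError("start_index must be >= 1")
    taken: set[str] = set(existing_titles or ())
    out: list[Record] = []
    counters: dict[str, int] = {}
    for r in rs.records:
        if r.parent_title is None:
            key = r.category
            counters.setdefault(key, start_index - 1)
            counters[key] += 1
            idx = counters[key]
            title = f"{r.category} {idx}"
        else:
            key = f"{r.parent_title}/{r.category}"
            counters.setdefault(key, 0)
            counters[key] += 1
            idx = counters[key]
            title = f"{key} {idx}"
        if title in taken:
            raise ValueError(f"title collision: {title!r}")
        taken.add(title)
        out.append(replace(r, index=idx, title=title))
    return RecordSet(schema=rs.schema, records=out)


# ---------------------------------------------------------------------------
# Page emission


def record_page(r: Record, schema: Schema) -> WikiPage:
    cat = schema.category(r.category)
    parts = [r.category]
    for p in cat.properties:
        v = r.values.get(p.label, MISSING)
        if v is MISSING:
            continue
        parts.append(f"{p.label}={encode_value(v, p)}")
    if cat.connection is not None and r.parent_title is not None:
        parts.append(f"{cat.connection[0]}={r.parent_title}")
    return WikiPage(r.title, Namespace.MAIN, "{{" + "|".join(parts) + "}}\n")


def emit_data_xml(rs: RecordSet) -> WikiXmlDocument:
    """One MAIN-namespace page per record, each a single template call
    with one named argument per non-MISSING value plus the connection
    argument linking to the parent record."""
    doc = WikiXmlDocument(language=rs.schema.language, site_title=rs.schema.site_title)
    for r in rs.records:
        if not r.title:
            raise ValueError("records need titles; run assign_titles first")
        doc.add(record_page(r, rs.schema))
    return doc


_TEMPLATE_CALL_RE = re.compile(r"^\{\{(.*)\}\}\s*$", re.S)


def extract_template_args(wikitext: str) -> tuple[str, dict[str, str]]:
    """Parse a page whose text is a single template call back into the
    template name and its named arguments (the inverse of
    :func:`record_page` for the pages this package emits)."""
    m = _TEMPLATE_CALL_RE.match(wikitext)
    if not m:
        raise ValueError("page text is not a single template call")
    parts = m.group(1).split("|")
    name = parts[0].strip()
    args: dict[str, str] = {}
    for chunk in parts[1:]:
        key, sep, value = chunk.partition("=")
        if not sep:
            raise ValueError(f"positional template argument {chunk!r}")
        args[key.strip()] = value.strip()
    return name, args


def record_set_values(rs: RecordSet, category: str) -> list[dict[str, Value]]:
    """Plain-dict view of the non-MISSING values per record (handy for
    comparisons and round-trip checks)."""
    out = []
    for r in rs.of_category(category):
        out.append({k: v for k, v in r.values.items() if v is not MISSING})
    return out
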