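"""Schema data model and parser for the enriched-TSV schema dialect.

A schema describes a small relational universe to be realised as a
semantic wiki: *categories* (the analogue of tables / OWL classes),
an optional subclass hierarchy, one-to-many *connections* between
categories (e.g. each visit page points at its patient page), and for
each category an ordered list of typed, constrained *properties*
arranged in named groups.

The input format is tab-separated text.  Directive lines start with
``!``; everything else is a property row attached to the most recently
declared category::

    !site<TAB>My clinic
    !language<TAB>en
    !category<TAB>Patients
    !group<TAB>Demographics
    Age<TAB>number<TAB>0:120<TAB>years<TAB>age at enrollment
    Sex<TAB>enum<TAB>F|M<TAB><TAB>
    !category<TAB>Visits<TAB>connection=Has Patient->Patients
    Temperature<TAB>number<TAB>30:45<TAB>°C<TAB>body temperature

Property rows are ``label<TAB>type<TAB>constraint<TAB>unit<TAB>note
[<TAB>aspects]``.  The constraint cell is ``min:max`` for numeric
ranges, ``v1|v2|v3`` for categorical domains and ``->Category`` for
page-valued links.  The aspects cell (``rel=value; rel=value``) attaches
relational decompositions of complex clinical labels to the property
(see :mod:`wikischema.prolog_export`).

Cells must not contain tabs or newlines; there is no quoting dialect.
Input is UTF-8; a leading byte-order mark is tolerated and stripped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "PropertyType",
    "ConstraintKind",
    "Constraint",
    "PropertySpec",
    "CategorySpec",
    "Schema",
    "Severity",
    "Diagnostic",
    "SchemaParseError",
    "CategoryGraph",
    "DEFAULT_ASPECT_RELATIONS",
    "TRISTATE_VALUES",
    "parse_schema",
    "try_parse_schema",
    "validate_schema",
    "property_page_name",
    "serialize_schema",
    "schema_graph",
]


class PropertyType(Enum):
    """Supported property types, each mapping to one SMW datatype."""

    TEXT = "text"
    NUMBER = "number"
    DATE = "date"
    BOOLEAN = "boolean"
    TRISTATE = "tristate"  # three-valued logic: Text with the fixed Yes/No/NA domain
    ENUM = "enum"  # categorical: Text with an Allows-value domain
    PAGE = "page"
    COORDINATES = "coordinates"
    URL = "url"

    @property
    def smw_type(self) -> str:
        """The Semantic MediaWiki datatype name for ``[[Has type::...]]``."""
        return _SMW_TYPE[self]


_SMW_TYPE: dict["PropertyType", str] = {
    PropertyType.TEXT: "Text",
    PropertyType.NUMBER: "Number",
    PropertyType.DATE: "Date",
    PropertyType.BOOLEAN: "Boolean",
    PropertyType.TRISTATE: "Text",
    PropertyType.ENUM: "Text",
    PropertyType.PAGE: "Page",
    PropertyType.COORDINATES: "Geographic coordinate",
    PropertyType.URL: "URL",
}


#: Canonical domain of three-valued ("tertium datur") boolean properties:
#: Yes, No, and NA for "not available" — an explicitly recorded unknown,
#: distinct from a cell that was never entered.
TRISTATE_VALUES: tuple[str, ...] = ("Yes", "No", "NA")

#: Default vocabulary of aspect relations usable in the aspects cell.
DEFAULT_ASPECT_RELATIONS: frozenset[str] = frozenset(
    {"measure", "exam", "device", "laterality", "organ", "time"}
)

_TYPE_KEYWORDS = {
    "text": PropertyType.TEXT,
    "number": PropertyType.NUMBER,
    "date": PropertyType.DATE,
    "boolean": PropertyType.BOOLEAN,
    "tristate": PropertyType.TRISTATE,
    "enum": PropertyType.ENUM,
    "page": PropertyType.PAGE,
    "coordinates": PropertyType.COORDINATES,
    "url": PropertyType.URL,
}


class ConstraintKind(Enum):
    NONE = "none"
    RANGE = "range"
    DOMAIN = "domain"
    TARGET = "target"


@dataclass(frozen=True)
class Constraint:
    """Value constraint attached to a property.

    ``RANGE`` bounds numbers to ``[min, max]``; ``DOMAIN`` restricts to an
    ordered list of allowed string values; ``TARGET`` restricts page links
    to members of one category.
    """

    kind: ConstraintKind = ConstraintKind.NONE
    min: Optional[float] = None
    max: Optional[float] = None
    values: tuple[str, ...] = ()
    target_category: Optional[str] = None

    @staticmethod
    def none() -> "Constraint":
        return Constraint()

    @staticmethod
    def range(lo: float, hi: float) -> "Constraint":
        return Constraint(kind=ConstraintKind.RANGE, min=lo, max=hi)

    @staticmethod
    def domain(values: Iterable[str]) -> "Constraint":
        return Constraint(kind=ConstraintKind.DOMAIN, values=tuple(values))

    @staticmethod
    def target(category: str) -> "Constraint":
        return Constraint(kind=ConstraintKind.TARGET, target_category=category)


@dataclass(frozen=True)
class PropertySpec:
    """One typed, constrained property of a category."""

    label: str
    page_name: str
    category: str
    type: PropertyType
    constraint: Constraint = Constraint()
    group: str = ""
    unit: str = ""
    note: str = ""
    aspects: tuple[tuple[str, str], ...] = ()
    line: int = 0  # 1-based source line, 0 when synthesised


@dataclass(frozen=True)
class CategorySpec:
    """One category: name, optional parent class, optional one-to-many
    connection ``(property name, target category)``, and ordered grouped
    properties."""

    name: str
    parent: Optional[str] = None
    connection: Optional[tuple[str, str]] = None
    groups: tuple[str, ...] = ()
    properties: tuple[PropertySpec, ...] = ()
    line: int = 0

    def property_by_label(self, label: str) -> Optional[PropertySpec]:
        for p in self.properties:
            if p.label == label:
                return p
        return None


@dataclass(frozen=True)
class Schema:
    """A parsed schema: ordered categories plus site metadata."""

    categories: tuple[CategorySpec, ...]
    site_title: str = "Wiki"
    language: str = "en"

    def category(self, name: str) -> Optional[CategorySpec]:
        for c in self.categories:
            if c.name == name:
                return c
        return None

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)


class Severity(Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class Diagnostic:
    severity: Severity
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.severity.value}: line {self.line}: {self.message}"


class SchemaParseError(ValueError):
    """Raised when a schema (or data) source contains ERROR diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        lines = "; ".join(str(d) for d in diagnostics if d.severity is Severity.ERROR)
        super().__init__(lines or "schema contains errors")


_FORBIDDEN_TITLE_CHARS = "#<>[]|{}"
_FORBIDDEN_RE = re.compile("[" + re.escape(_FORBIDDEN_TITLE_CHARS) + "]")


def property_page_name(label: str) -> str:
    """Normalise a human-readable label to a valid wiki page title.

    Strips characters MediaWiki forbids in titles, collapses runs of
    whitespace to single spaces, trims, and capitalises the first letter
    (the rest of the label is left untouched).  Idempotent.
    """
    cleaned = _FORBIDDEN_RE.sub("", label)
    cleaned = " ".join(cleaned.split())
    if not cleaned:
        raise ValueError(f"label {label!r} reduces to an empty title")
    return cleaned[0].upper() + cleaned[1:]


def is_valid_title(title: str) -> bool:
    if not title or _FORBIDDEN_RE.search(title):
        return False
    if title != " ".join(title.split()):
        return False
    return title[0] == title[0].upper()


# ---------------------------------------------------------------------------
# Parsing


_DIRECTIVE_KV_RE = re.compile(r"^(\w+)=(.*)$")


def _parse_constraint(
    cell: str, ptype: PropertyType, line: int, diags: list[Diagnostic]
) -> Constraint:
    cell = cell.strip()
    if ptype is PropertyType.TRISTATE:
        if cell and cell != "|".join(TRISTATE_VALUES):
            diags.append(
                Diagnostic(
                    Severity.ERROR,
                    line,
                    "tristate properties have the fixed domain "
                    + "|".join(TRISTATE_VALUES),
                )
            )
        return Constraint.domain(TRISTATE_VALUES)
    if not cell:
        return Constraint.none()
    if cell.startswith("->"):
        target = cell[2:].strip()
        if not target:
            diags.append(Diagnostic(Severity.ERROR, line, "empty target category in '->'"))
            return Constraint.none()
        return Constraint.target(target)
    if "|" in cell:
        values = [v.strip() for v in cell.split("|")]
        return Constraint.domain(values)
    if ":" in cell:
        lo_s, _, hi_s = cell.partition(":")
        try:
            lo, hi = float(lo_s), float(hi_s)
        except ValueError:
            diags.append(
                Diagnostic(Severity.ERROR, line, f"malformed range constraint {cell!r}")
            )
            return Constraint.none()
        return Constraint.range(lo, hi)
    if ptype is PropertyType.ENUM:
        # single-value domain
        return Constraint.domain([cell])
    diags.append(Diagnostic(Severity.ERROR, line, f"unrecognised constraint {cell!r}"))
    return Constraint.none()


def _parse_aspects(cell: str, line: int, diags: list[Diagnostic]) -> tuple[tuple[str, str], ...]:
    pairs: list[tuple[str, str]] = []
    for chunk in cell.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _DIRECTIVE_KV_RE.match(chunk)
        if not m:
            diags.append(
                Diagnostic(Severity.ERROR, line, f"malformed aspect {chunk!r} (want rel=value)")
            )
            continue
        pairs.append((m.group(1), m.group(2).strip()))
    return tuple(pairs)


class _CategoryBuilder:
    def __init__(self, name: str, line: int):
        self.name = name
        self.line = line
        self.parent: Optional[str] = None
        self.connection: Optional[tuple[str, str]] = None
        self.groups: list[str] = []
        self.current_group = ""
        self.properties: list[PropertySpec] = []

    def build(self) -> CategorySpec:
        return CategorySpec(
            name=self.name,
            parent=self.parent,
            connection=self.connection,
            groups=tuple(self.groups),
            properties=tuple(self.properties),
            line=self.line,
        )


def try_parse_schema(
    tsv_text: str,
    *,
    aspect_relations: frozenset[str] = DEFAULT_ASPECT_RELATIONS,
) -> tuple[Optional[Schema], list[Diagnostic]]:
    """Parse the enriched-TSV dialect; never raises.

    Returns ``(schema, diagnostics)``; ``schema`` is ``None`` when ERROR
    diagnostics were produced.  Line order is preserved as property and
    group order.
    """
    diags: list[Diagnostic] = []
    site_title = "Wiki"
    language = "en"
    builders: list[_CategoryBuilder] = []
    current: Optional[_CategoryBuilder] = None

    text = tsv_text.lstrip("﻿")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n\r")
        if not line.strip():
            continue
        cells = line.split("\t")
        first = cells[0].strip()
        if first.startswith("#"):
            continue  # comment line
        if first.startswith("!"):
            directive = first[1:].lower()
            args = [c.strip() for c in cells[1:]]
            if directive == "site":
                site_title = args[0] if args else site_title
            elif directive == "language":
                if args and re.fullmatch(r"[a-z]{2}", args[0]):
                    language = args[0]
                else:
                    diags.append(
                        Diagnostic(Severity.ERROR, lineno, "language wants a 2-letter code")
                    )
            elif directive == "category":
                if not args or not args[0]:
                    diags.append(Diagnostic(Severity.ERROR, lineno, "category wants a name"))
                    continue
                current = _CategoryBuilder(args[0], lineno)
                builders.append(current)
                for extra in args[1:]:
                    if not extra:
                        continue
                    m = _DIRECTIVE_KV_RE.match(extra)
                    key = m.group(1).lower() if m else None
                    if key == "parent":
                        current.parent = m.group(2).strip()
                    elif key == "connection":
                        conn = m.group(2)
                        prop, sep, target = conn.partition("->")
                        if not sep or not prop.strip() or not target.strip():
                            diags.append(
                                Diagnostic(
                                    Severity.ERROR,
                                    lineno,
                                    f"malformed connection {conn!r} (want Prop->Category)",
                                )
                            )
                        else:
                            current.connection = (prop.strip(), target.strip())
                    else:
                        diags.append(
                            Diagnostic(
                                Severity.ERROR, lineno, f"unknown category option {extra!r}"
                            )
                        )
            elif directive == "group":
                if current is None:
                    diags.append(
                        Diagnostic(Severity.ERROR, lineno, "group outside any category")
                    )
                    continue
                name = args[0] if args else ""
                if not name:
                    diags.append(Diagnostic(Severity.ERROR, lineno, "group wants a name"))
                    continue
                current.current_group = name
                if name not in current.groups:
                    current.groups.append(name)
            else:
                diags.append(
                    Diagnostic(Severity.ERROR, lineno, f"malformed directive {first!r}")
                )
            continue

        # Property row.  A literal header row is tolerated and skipped.
        if first.lower() == "label" and len(cells) > 1 and cells[1].strip().lower() == "type":
            continue
        if current is None:
            diags.append(
                Diagnostic(Severity.ERROR, lineno, "property row before any !category")
            )
            continue
        cells += [""] * (6 - len(cells))
        label, type_kw, constraint_cell, unit, note, aspects_cell = (
            c.strip() for c in cells[:6]
        )
        if not label:
            diags.append(Diagnostic(Severity.ERROR, lineno, "empty property label"))
            continue
        ptype = _TYPE_KEYWORDS.get(type_kw.lower())
        if ptype is None:
            diags.append(
                Diagnostic(Severity.ERROR, lineno, f"unknown type keyword {type_kw!r}")
            )
            continue
        constraint = _parse_constraint(constraint_cell, ptype, lineno, diags)
        aspects = _parse_aspects(aspects_cell, lineno, diags)
        try:
            page = property_page_name(label)
        except ValueError as exc:
            diags.append(Diagnostic(Severity.ERROR, lineno, str(exc)))
            continue
        current.properties.append(
            PropertySpec(
                label=label,
                page_name=page,
                category=current.name,
                type=ptype,
                constraint=constraint,
                group=current.current_group,
                unit=unit,
                note=note,
                aspects=aspects,
                line=lineno,
            )
        )

    schema = Schema(
        categories=tuple(b.build() for b in builders),
        site_title=site_title,
        language=language,
    )
    diags.extend(validate_schema(schema, aspect_relations=aspect_relations))
    if any(d.severity is Severity.ERROR for d in diags):
        return None, diags
    return schema, diags


def parse_schema(
    tsv_text: str,
    *,
    aspect_relations: frozenset[str] = DEFAULT_ASPECT_RELATIONS,
) -> Schema:
    """Parse the enriched-TSV dialect into a validated :class:`Schema`.

    Raises :class:`SchemaParseError` carrying the diagnostics when the
    source contains errors.
    """
    schema, diags = try_parse_schema(tsv_text, aspect_relations=aspect_relations)
    if schema is None:
        raise SchemaParseError(diags)
    return schema


# ---------------------------------------------------------------------------
# Validation


def validate_schema(
    schema: Schema,
    *,
    aspect_relations: frozenset[str] = DEFAULT_ASPECT_RELATIONS,
) -> list[Diagnostic]:
    """Check every schema invariant; returns diagnostics (empty iff valid)."""
    diags: list[Diagnostic] = []
    names = [c.name for c in schema.categories]
    declared = set(names)

    if not schema.categories:
        diags.append(Diagnostic(Severity.ERROR, 1, "schema declares at least one category"))
    seen: set[str] = set()
    for c in schema.categories:
        if c.name in seen:
            diags.append(
                Diagnostic(Severity.ERROR, c.line, f"duplicate category name {c.name!r}")
            )
        seen.add(c.name)

    # Acyclic parent hierarchy (iterative DFS with colouring).
    parent_of = {c.name: c.parent for c in schema.categories}
    state: dict[str, int] = {}
    for start in parent_of:
        node, trail = start, []
        while node is not None and state.get(node, 0) == 0:
            state[node] = 1
            trail.append(node)
            node = parent_of.get(node)
        if node is not None and state.get(node) == 1:
            diags.append(
                Diagnostic(
                    Severity.ERROR,
                    0,
                    f"category hierarchy cycle through {node!r}",
                )
            )
        for n in trail:
            state[n] = 2

    for c in schema.categories:
        if c.parent is not None and c.parent not in declared:
            diags.append(
                Diagnostic(
                    Severity.ERROR, c.line,
                    f"unresolved reference: parent category {c.parent!r}",
                )
            )
        if c.connection is not None:
            prop, target = c.connection
            if target == c.name:
                diags.append(
                    Diagnostic(
                        Severity.ERROR, c.line,
                        f"connection of {c.name!r} must target a different category",
                    )
                )
            if target not in declared:
                diags.append(
                    Diagnostic(
                        Severity.ERROR, c.line,
                        f"unresolved reference: connection target {target!r}",
                    )
                )
        labels: set[str] = set()
        for p in c.properties:
            if p.label in labels:
                diags.append(
                    Diagnostic(
                        Severity.ERROR, p.line,
                        f"duplicate property label {p.label!r} in category {c.name!r}",
                    )
                )
            labels.add(p.label)
            diags.extend(_validate_property(p, declared, aspect_relations))
    return diags


def _validate_property(
    p: PropertySpec, declared: set[str], aspect_relations: frozenset[str]
) -> list[Diagnostic]:
    diags: list[Diagnostic] = []
    if not is_valid_title(p.page_name):
        diags.append(
            Diagnostic(Severity.ERROR, p.line, f"invalid property page title {p.page_name!r}")
        )
    k = p.constraint
    if k.kind is ConstraintKind.RANGE and not (k.min <= k.max):
        diags.append(
            Diagnostic(
                Severity.ERROR, p.line,
                f"property {p.label!r}: range min {k.min} exceeds max {k.max}",
            )
        )
    if k.kind is ConstraintKind.DOMAIN:
        vals = [v for v in k.values if v]
        if not vals or len(set(vals)) != len(k.values):
            diags.append(
                Diagnostic(
                    Severity.ERROR, p.line,
                    f"property {p.label!r}: domain wants distinct non-empty values",
                )
            )
    if p.type is PropertyType.ENUM and k.kind is not ConstraintKind.DOMAIN:
        diags.append(
            Diagnostic(
                Severity.ERROR, p.line,
                f"enum property {p.label!r} wants a v1|v2|... domain constraint",
            )
        )
    if k.kind is ConstraintKind.TARGET and k.target_category not in declared:
        diags.append(
            Diagnostic(
                Severity.ERROR, p.line,
                f"unresolved reference: target category {k.target_category!r}",
            )
        )
    if p.type is PropertyType.TRISTATE and (
        k.kind is not ConstraintKind.DOMAIN or k.values != TRISTATE_VALUES
    ):
        diags.append(
            Diagnostic(
                Severity.ERROR, p.line,
                f"tristate property {p.label!r} wants the domain "
                + "|".join(TRISTATE_VALUES),
            )
        )
    for rel, _value in p.aspects:
        if rel not in aspect_relations:
            diags.append(
                Diagnostic(
                    Severity.ERROR, p.line,
                    f"property {p.label!r}: unknown aspect relation {rel!r}",
                )
            )
    return diags


# ---------------------------------------------------------------------------
# Serialization (canonical re-emission of the dialect)


def _constraint_cell(p: PropertySpec) -> str:
    k = p.constraint
    if p.type is PropertyType.TRISTATE:
        return ""  # the fixed domain is implied by the type
    if k.kind is ConstraintKind.RANGE:
        return f"{_num(k.min)}:{_num(k.max)}"
    if k.kind is ConstraintKind.DOMAIN:
        return "|".join(k.values)
    if k.kind is ConstraintKind.TARGET:
        return f"->{k.target_category}"
    return ""


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def serialize_schema(schema: Schema) -> str:
    """Emit a schema back to the TSV dialect such that re-parsing it
    yields an equal schema (modulo source line numbers)."""
    out: list[str] = [f"!site\t{schema.site_title}", f"!language\t{schema.language}"]
    for c in schema.categories:
        parts = [f"!category\t{c.name}"]
        if c.parent:
            parts.append(f"parent={c.parent}")
        if c.connection:
            parts.append(f"connection={c.connection[0]}->{c.connection[1]}")
        out.append("\t".join(parts))
        group = ""
        for p in c.properties:
            if p.group != group:
                group = p.group
                if group:
                    out.append(f"!group\t{group}")
            aspects = "; ".join(f"{r}={v}" for r, v in p.aspects)
            type_kw = p.type.name.lower()
            row = [p.label, type_kw, _constraint_cell(p), p.unit, p.note]
            if aspects:
                row.append(aspects)
            out.append("\t".join(row).rstrip("\t") if not aspects else "\t".join(row))
    return "\n".join(out) + "\n"


def strip_lines(schema: Schema) -> Schema:
    """Copy of the schema with all source line numbers zeroed (for
    order-sensitive structural equality across a serialise/parse trip)."""
    cats = tuple(
        replace(
            c,
            line=0,
            properties=tuple(replace(p, line=0) for p in c.properties),
        )
        for c in schema.categories
    )
    return replace(schema, categories=cats)


# ---------------------------------------------------------------------------
# Category graph


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    property: str  # property page name labelling the edge


class CategoryGraph:
    """Directed multigraph over categories.

    One node per category; one edge per one-to-many connection and per
    page-typed property with a target category, labelled with the
    property name.  Traversal is exposed both along edge direction
    (forward) and against it (inverse), which is what property chains in
    queries need.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[GraphEdge]):
        self.nodes: tuple[str, ...] = tuple(nodes)
        self.edges: tuple[GraphEdge, ...] = tuple(edges)
        self._fwd: dict[str, list[GraphEdge]] = {n: [] for n in self.nodes}
        self._rev: dict[str, list[GraphEdge]] = {n: [] for n in self.nodes}
        for e in self.edges:
            self._fwd[e.source].append(e)
            self._rev[e.target].append(e)

    def out_edges(self, node: str) -> list[GraphEdge]:
        return list(self._fwd[node])

    def in_edges(self, node: str) -> list[GraphEdge]:
        return list(self._rev[node])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CategoryGraph(nodes={len(self.nodes)}, edges={len(self.edges)})"


def schema_graph(schema: Schema) -> CategoryGraph:
    """Build the category graph of a valid schema."""
    edges: list[GraphEdge] = []
    for c in schema.categories:
        if c.connection is not None:
            prop, target = c.connection
            edges.append(GraphEdge(c.name, target, property_page_name(prop)))
        for p in c.properties:
            if (
                p.type is PropertyType.PAGE
                and p.constraint.kind is ConstraintKind.TARGET
            ):
                edges.append(GraphEdge(c.name, p.constraint.target_category, p.page_name))
    return CategoryGraph((c.name for c in schema.categories), edges)
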