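"""Export records as subject–property–object facts in Prolog syntax.

Each non-missing cell becomes one ground ternary term::

    fact('Patients 1/Visits 1', has_temperature, 38.5).

with the property reified as the second argument, so the whole database
keeps a single functor of fixed arity and facts read as triples.  Parent
links are exported the same way (``fact(Child, has_patient, Parent)``).
A convenience per-property mode emits ``has_temperature('Patients 1/
Visits 1', 38.5).`` instead.

Complex clinical property labels (e.g. "Pure tone average of vocal gain
during last control exam with intracochlear device on left ear") carry
their relational decomposition as aspect pairs on the property itself;
these are exported as ``property_aspect/3`` clauses, so a logic program
can select measurements by laterality or device instead of by matching
the unstructured label.

Output is UTF-8 with LF line endings; atoms follow ISO quoting (single
quotes, internal quotes doubled); dates are ``date(Y,M,D)`` compound
terms and coordinates ``coord(Lat,Lon)``, both comparable in standard
order of terms.
"""

from __future__ import annotations

import datetime as dt
import re
from typing import Optional

from .schema_core import Schema
from .data_import import MISSING, RecordSet, Value, format_number

__all__ = [
    "normalize_predicate",
    "predicate_map",
    "quote_atom",
    "prolog_term",
    "export_facts",
    "export_aspect_facts",
]

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize_predicate(label: str) -> str:
    """Normalise a property label to a lowercase Prolog atom.

    Lowercases, collapses runs of non-alphanumerics to single
    underscores, trims them at the ends, and prefixes ``p_`` when the
    result would start with a digit.  Idempotent.
    """
    if not label:
        raise ValueError("empty label")
    atom = _NON_ALNUM.sub("_", label.lower()).strip("_")
    if not atom:
        raise ValueError(f"label {label!r} normalises to an empty atom")
    if atom[0].isdigit():
        atom = "p_" + atom
    return atom


def predicate_map(schema: Schema) -> dict[str, str]:
    """Map every property label (and connection property) of a schema to
    its predicate atom, raising when two labels collide."""
    mapping: dict[str, str] = {}
    owners: dict[str, str] = {}
    for c in schema.categories:
        labels = [p.label for p in c.properties]
        if c.connection is not None:
            labels.append(c.connection[0])
        for label in labels:
            atom = normalize_predicate(label)
            if mapping.get(label) == atom:
                continue
            prior = owners.get(atom)
            if prior is not None and prior != label:
                raise ValueError(
                    f"labels {prior!r} and {label!r} both normalise to {atom!r}"
                )
            mapping[label] = atom
            owners[atom] = label
    return mapping


def quote_atom(s: str) -> str:
    """ISO-style quoted atom: single quotes, internal quotes doubled,
    backslashes escaped."""
    return "'" + s.replace("\\", "\\\\").replace("'", "''") + "'"


def prolog_term(v: Value) -> str:
    """Ground-term rendering of a typed value."""
    if isinstance(v, bool):
        return quote_atom("Yes" if v else "No")
    if isinstance(v, (int, float)):
        return format_number(v)
    if isinstance(v, dt.date):
        return f"date({v.year},{v.month},{v.day})"
    if isinstance(v, tuple):
        lat, lon = v
        return f"coord({format_number(lat)},{format_number(lon)})"
    return quote_atom(str(v))


def export_facts(
    rs: RecordSet,
    *,
    per_property: bool = False,
    seed: Optional[int] = None,
) -> str:
    """Serialise a record set as Prolog facts.

    One line per non-MISSING cell plus one line per parent link, ordered
    by entity title then by the schema's property order, so the export
    is deterministic.  The header comment records the schema (site)
    name and, when given, the generation seed of synthetic data.
    """
    mapping = predicate_map(rs.schema)
    lines = [f"% facts exported from schema {quote_atom(rs.schema.site_title)}"]
    if seed is not None:
        lines.append(f"% generation seed: {seed}")
    for r in sorted(rs.records, key=lambda r: r.title):
        cat = rs.schema.category(r.category)
        for p in cat.properties:
            v = r.values.get(p.label, MISSING)
            if v is MISSING:
                continue
            pred = mapping[p.label]
            obj = prolog_term(v)
            if per_property:
                lines.append(f"{pred}({quote_atom(r.title)}, {obj}).")
            else:
                lines.append(f"fact({quote_atom(r.title)}, {pred}, {obj}).")
        if cat.connection is not None and r.parent_title is not None:
            pred = mapping[cat.connection[0]]
            if per_property:
                lines.append(
                    f"{pred}({quote_atom(r.title)}, {quote_atom(r.parent_title)})."
                )
            else:
                lines.append(
                    f"fact({quote_atom(r.title)}, {pred}, {quote_atom(r.parent_title)})."
                )
    return "\n".join(lines) + "\n"


def export_aspect_facts(s: Schema) -> str:
    """One ``property_aspect(Predicate, Relation, Value)`` clause per
    aspect pair of each property: the relational decomposition of
    complex labels, queryable alongside the data facts."""
    mapping = predicate_map(s)
    lines = ["% property aspect decompositions"]
    for c in s.categories:
        for p in c.properties:
            pred = mapping[p.label]
            for rel, value in p.aspects:
                lines.append(
                    f"property_aspect({pred}, {normalize_predicate(rel)}, "
                    f"{quote_atom(value)})."
                )
    return "\n".join(lines) + "\n"
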