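"""ASK query construction with automatic property-chain resolution.

Semantic MediaWiki's inline queries select pages by category and
property conditions and project values with printouts (``?Property``).
When a condition or printout refers to a property of a *related*
category, the query must spell out the chain of connection properties
leading there — dotted steps, with a leading minus sign for a step
traversed against the connection's direction (e.g. from a patient to
their visits through the visits' ``Has Patient`` link).

Writing chains by hand is error-prone, so :func:`resolve_chain`
computes them: given the category a query starts from and a property
label, it finds the shortest chain (fewest steps) through the schema's
connection graph, in either direction, to the category owning that
property.  :func:`build_ask` then renders the full ``{{#ask: ...}}``
text, and :func:`evaluate_ask` executes the query against an in-memory
record set so query semantics are testable without a running wiki.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import pandas as pd

from .schema_core import (
    CategoryGraph,
    PropertySpec,
    PropertyType,
    Schema,
    property_page_name,
)
from .data_import import MISSING, Record, RecordSet, Value, decode_value, encode_value

__all__ = [
    "Comparator",
    "Condition",
    "Direction",
    "Chain",
    "AskQuery",
    "ChainError",
    "shortest_chain",
    "resolve_chain",
    "build_ask",
    "parse_ask",
    "evaluate_ask",
]


class Comparator(Enum):
    EQ = ""
    GT = ">"
    GE = ">="
    LT = "<"
    LE = "<="
    LIKE = "~"


_ORDERED = {Comparator.GT, Comparator.GE, Comparator.LT, Comparator.LE}


@dataclass(frozen=True)
class Condition:
    property: str  # property label
    comparator: Comparator
    operand: Value


class Direction(Enum):
    FORWARD = "forward"
    INVERSE = "inverse"


@dataclass(frozen=True)
class Chain:
    """A resolved path of connection properties; INVERSE steps render
    with the minus-sign prefix of SMW's inverse property syntax."""

    steps: tuple[tuple[str, Direction], ...] = ()

    def render(self) -> str:
        return ".".join(
            ("-" if d is Direction.INVERSE else "") + name for name, d in self.steps
        )

    def __bool__(self) -> bool:
        return bool(self.steps)


@dataclass(frozen=True)
class AskQuery:
    category: str
    conditions: tuple[tuple[Chain, Condition], ...] = ()
    printouts: tuple[tuple[Chain, str], ...] = ()


class ChainError(ValueError):
    """Property unreachable, or ambiguously owned by several categories
    at the same distance."""


# ---------------------------------------------------------------------------
# Chain resolution


def _owners(schema: Schema, label: str) -> list[str]:
    return [c.name for c in schema.categories if c.property_by_label(label)]


def shortest_chain(g: CategoryGraph, from_cat: str, owners: set[str]) -> Chain:
    """Shortest chain (fewest steps) from ``from_cat`` to any category in
    ``owners``, traversing edges forward or inverse.

    Among equally short chains to a single nearest owner the
    lexicographically smallest rendering wins; two *distinct* owners at
    the same minimal distance raise :class:`ChainError` listing them.
    """
    if from_cat in owners:
        return Chain()

    # BFS over the bidirected graph, keeping *all* shortest chains.
    frontier: dict[str, list[tuple[tuple[str, Direction], ...]]] = {from_cat: [()]}
    visited: set[str] = {from_cat}
    while frontier:
        reached = {n: chains for n, chains in frontier.items() if n in owners}
        if reached:
            if len(reached) > 1:
                raise ChainError(
                    "equally near candidate categories "
                    + ", ".join(sorted(reached))
                    + f" from {from_cat!r}"
                )
            ((_owner, chains),) = reached.items()
            best = min(chains, key=lambda st: Chain(st).render())
            return Chain(best)
        nxt: dict[str, list[tuple[tuple[str, Direction], ...]]] = {}
        for node, chains in frontier.items():
            for e in g.out_edges(node):
                if e.target not in visited:
                    nxt.setdefault(e.target, []).extend(
                        st + ((e.property, Direction.FORWARD),) for st in chains
                    )
            for e in g.in_edges(node):
                if e.source not in visited:
                    nxt.setdefault(e.source, []).extend(
                        st + ((e.property, Direction.INVERSE),) for st in chains
                    )
        visited.update(nxt)
        frontier = nxt
    raise ChainError(f"no candidate category reachable from {from_cat!r}")


def resolve_chain(
    g: CategoryGraph,
    schema: Schema,
    from_cat: str,
    prop: str,
) -> Chain:
    """Shortest chain from ``from_cat`` to the category owning ``prop``.

    Edges may be traversed forward (along the connection, child→parent)
    or inverse (parent→child, rendered with '-').  A local property
    resolves to the empty chain; an unreachable or ambiguously owned
    property raises :class:`ChainError`.
    """
    owners = set(_owners(schema, prop))
    if not owners:
        raise ChainError(f"no category declares property {prop!r}")
    try:
        return shortest_chain(g, from_cat, owners)
    except ChainError as exc:
        raise ChainError(f"property {prop!r}: {exc}") from None


# ---------------------------------------------------------------------------
# Query text


def _find_property(schema: Schema, label: str) -> PropertySpec:
    for c in schema.categories:
        p = c.property_by_label(label)
        if p is not None:
            return p
    raise ChainError(f"no category declares property {label!r}")


def _check_types(q: AskQuery, schema: Schema) -> None:
    for _chain, cond in q.conditions:
        p = _find_property(schema, cond.property)
        if cond.comparator in _ORDERED and p.type not in (
            PropertyType.NUMBER,
            PropertyType.DATE,
        ):
            raise ValueError(
                f"comparator {cond.comparator.name} needs a number or date "
                f"property, got {p.type.name} for {cond.property!r}"
            )


def build_ask(q: AskQuery, schema: Schema) -> str:
    """Render the ``{{#ask: ...}}`` query text.

    Conditions become ``[[<chain.>Prop::<op><value>]]`` (GT/LT/GE/LE use
    SMW's ``>``, ``<``, ``>=``, ``<=`` value prefixes; LIKE uses ``~``),
    printouts become ``|?<chain.>Prop``.  Deterministic: same query,
    same text.
    """
    _check_types(q, schema)
    parts = [f"[[Category:{q.category}]]"]
    for chain, cond in q.conditions:
        p = _find_property(schema, cond.property)
        path = (chain.render() + "." if chain else "") + p.page_name
        parts.append(f"[[{path}::{cond.comparator.value}{encode_value(cond.operand, p)}]]")
    printout_parts = []
    for chain, label in q.printouts:
        p = _find_property(schema, label)
        path = (chain.render() + "." if chain else "") + p.page_name
        printout_parts.append(f"|?{path}")
    body = " ".join(parts)
    if printout_parts:
        body += " " + " ".join(printout_parts)
    return "{{#ask: " + body + "}}"


def auto_query(
    schema: Schema,
    category: str,
    conditions: list[Condition] = (),
    printouts: list[str] = (),
) -> AskQuery:
    """Build an :class:`AskQuery` from bare property labels, resolving
    every needed chain automatically — the user states only the category
    and the properties of interest."""
    from .schema_core import schema_graph

    g = schema_graph(schema)
    conds = tuple(
        (resolve_chain(g, schema, category, c.property), c) for c in conditions
    )
    prints = tuple(
        (resolve_chain(g, schema, category, label), label) for label in printouts
    )
    return AskQuery(category=category, conditions=conds, printouts=prints)


_ASK_RE = re.compile(r"^\{\{#ask:\s*(.*)\}\}$", re.S)
_COND_RE = re.compile(r"\[\[([^\]:]+)::([^\]]*)\]\]")
_CAT_RE = re.compile(r"\[\[Category:([^\]]+)\]\]")


def _parse_path(path: str) -> tuple[Chain, str]:
    steps = path.split(".")
    chain_steps = []
    for s in steps[:-1]:
        if s.startswith("-"):
            chain_steps.append((s[1:], Direction.INVERSE))
        else:
            chain_steps.append((s, Direction.FORWARD))
    return Chain(tuple(chain_steps)), steps[-1]


def parse_ask(text: str, schema: Schema) -> AskQuery:
    """Parse query text produced by :func:`build_ask` back into an
    :class:`AskQuery` (printer/parser consistency is a tested property)."""
    m = _ASK_RE.match(text.strip())
    if not m:
        raise ValueError("not an #ask query")
    body = m.group(1)
    mcat = _CAT_RE.search(body)
    if not mcat:
        raise ValueError("query lacks a [[Category:...]] selector")
    category = mcat.group(1)
    conditions = []
    for path, rhs in _COND_RE.findall(body):
        if path.startswith("Category:"):
            continue
        chain, page = _parse_path(path)
        comparator = Comparator.EQ
        for comp in (Comparator.GE, Comparator.LE, Comparator.GT, Comparator.LT,
                     Comparator.LIKE):
            if rhs.startswith(comp.value):
                comparator = comp
                rhs = rhs[len(comp.value):]
                break
        label = _label_for_page(schema, page)
        p = _find_property(schema, label)
        conditions.append((chain, Condition(label, comparator, decode_value(rhs, p))))
    printouts = []
    for token in body.split("|?")[1:]:
        path = token.strip().rstrip("}").strip()
        chain, page = _parse_path(path)
        printouts.append((chain, _label_for_page(schema, page)))
    return AskQuery(category, tuple(conditions), tuple(printouts))


def _label_for_page(schema: Schema, page: str) -> str:
    for c in schema.categories:
        for p in c.properties:
            if p.page_name == page:
                return p.label
    raise ChainError(f"no property page {page!r} in schema")


# ---------------------------------------------------------------------------
# Reference evaluator


def _satisfies(v: Union[Value, object], cond: Condition) -> bool:
    if v is MISSING:
        return False
    c = cond.comparator
    if c is Comparator.EQ:
        return v == cond.operand
    if c is Comparator.LIKE:
        return str(cond.operand).lower() in str(v).lower()
    try:
        if c is Comparator.GT:
            return v > cond.operand
        if c is Comparator.GE:
            return v >= cond.operand
        if c is Comparator.LT:
            return v < cond.operand
        if c is Comparator.LE:
            return v <= cond.operand
    except TypeError:
        return False
    return False


def _follow(chain: Chain, start: Record, rs: RecordSet) -> list[Record]:
    """All records reached from ``start`` along the chain.  FORWARD steps
    follow the record's page-valued property (connections resolve via
    the parent link); INVERSE steps collect the records pointing back."""
    current = [start]
    for prop_page, direction in chain.steps:
        nxt: list[Record] = []
        for r in current:
            cat = rs.schema.category(r.category)
            if direction is Direction.FORWARD:
                title: Optional[str] = None
                if cat.connection and property_page_name(cat.connection[0]) == prop_page:
                    title = r.parent_title
                else:
                    for p in cat.properties:
                        if p.page_name == prop_page:
                            v = r.values.get(p.label, MISSING)
                            title = None if v is MISSING else str(v)
                if title:
                    hit = rs.by_title(title)
                    if hit:
                        nxt.append(hit)
            else:
                for other in rs.records:
                    ocat = rs.schema.category(other.category)
                    if (
                        ocat.connection
                        and property_page_name(ocat.connection[0]) == prop_page
                        and other.parent_title == r.title
                    ):
                        nxt.append(other)
                    else:
                        for p in ocat.properties:
                            if (
                                p.page_name == prop_page
                                and other.values.get(p.label) == r.title
                            ):
                                nxt.append(other)
        current = nxt
    return current


def evaluate_ask(q: AskQuery, rs: RecordSet) -> pd.DataFrame:
    """Execute a query against an in-memory record set.

    Rows are the entities of ``q.category`` satisfying *all* conditions
    (a chained condition holds when at least one related record
    satisfies it; MISSING never satisfies a comparator).  Columns are
    the page title plus one column per printout, holding lists when a
    chain reaches several records.
    """
    rows = []
    for r in rs.of_category(q.category):
        ok = True
        for chain, cond in q.conditions:
            targets = _follow(chain, r, rs)
            if not any(_satisfies(t.values.get(cond.property, MISSING), cond) for t in targets):
                ok = False
                break
        if not ok:
            continue
        row: dict[str, object] = {"Page": r.title}
        for chain, label in q.printouts:
            header = (chain.render() + "." if chain else "") + label
            vals = [
                t.values.get(label)
                for t in _follow(chain, r, rs)
                if t.values.get(label, MISSING) is not MISSING
            ]
            row[header] = vals[0] if len(vals) == 1 else vals
        rows.append(row)
    columns = ["Page"] + [
        (chain.render() + "." if chain else "") + label for chain, label in q.printouts
    ]
    return pd.DataFrame(rows, columns=columns)
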