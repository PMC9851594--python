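"""Shared test oracles, independent of the implementation paths they check.

* a small recursive-descent parser for ground Prolog terms (loadability
  oracle for the fact export, no external interpreter needed);
* brute-force shortest-path search by exhaustive simple-path enumeration
  (oracle for chain resolution);
* a random-schema generator used by the property tests.
"""

from __future__ import annotations

import re
import string

import numpy as np

from wikischema.schema_core import (
    CategoryGraph,
    CategorySpec,
    Constraint,
    GraphEdge,
    PropertySpec,
    PropertyType,
    Schema,
    TRISTATE_VALUES,
    property_page_name,
)

# ---------------------------------------------------------------------------
# Ground Prolog term parsing


class TermError(ValueError):
    pass


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<quoted>'(?:[^'\\]|\\.|'')*')
      | (?P<number>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
      | (?P<atom>[a-z][A-Za-z0-9_]*)
      | (?P<punct>[(),.])
    )""",
    re.X,
)


def _tokenize(line: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(line):
        if line[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(line, pos)
        if not m or m.start() != pos:
            raise TermError(f"bad token at {line[pos:pos + 20]!r}")
        for kind in ("quoted", "number", "atom", "punct"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
        pos = m.end()
    return tokens


def parse_fact_line(line: str):
    """Parse one ``functor(arg, ...).`` line into a (functor, args)
    tuple; args are atoms/strings, numbers, or nested (functor, args)
    tuples.  Raises TermError when the line is not a ground term."""
    tokens = _tokenize(line)
    if not tokens or tokens[-1] != ("punct", "."):
        raise TermError("line does not end with '.'")
    pos = 0

    def term():
        nonlocal pos
        kind, val = tokens[pos]
        pos += 1
        if kind == "number":
            return float(val) if ("." in val or "e" in val.lower()) else int(val)
        if kind == "quoted":
            return val[1:-1].replace("''", "'").replace("\\\\", "\\")
        if kind == "atom":
            if pos < len(tokens) and tokens[pos] == ("punct", "("):
                pos += 1
                args = [term()]
                while tokens[pos] == ("punct", ","):
                    pos += 1
                    args.append(term())
                if tokens[pos] != ("punct", ")"):
                    raise TermError("expected ')'")
                pos += 1
                return (val, tuple(args))
            return val
        raise TermError(f"unexpected token {val!r}")

    result = term()
    if tokens[pos] != ("punct", "."):
        raise TermError("trailing tokens before '.'")
    if not isinstance(result, tuple):
        raise TermError("fact line is not a compound term")
    return result


def parse_fact_file(text: str):
    """Every non-comment line must parse as a ground compound term."""
    facts = []
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("%"):
            continue
        facts.append(parse_fact_line(line))
    return facts


# ---------------------------------------------------------------------------
# Brute-force chain oracle


def all_simple_paths(g: CategoryGraph, start: str, goal: str):
    """All simple paths over the bidirected view of the graph, as lists
    of (property, is_inverse) steps."""
    paths = []

    def walk(node, seen, steps):
        if node == goal and steps:
            paths.append(list(steps))
            return
        if node == goal:
            paths.append([])
            return
        for e in g.out_edges(node):
            if e.target not in seen:
                walk(e.target, seen | {e.target}, steps + [(e.property, False)])
        for e in g.in_edges(node):
            if e.source not in seen:
                walk(e.source, seen | {e.source}, steps + [(e.property, True)])

    walk(start, {start}, [])
    return paths


def brute_shortest_length(g: CategoryGraph, start: str, goals: set[str]):
    """Minimal number of steps from start to any goal category, or None
    when unreachable; ties across distinct goals are reported too."""
    best = None
    best_goals = set()
    for goal in goals:
        paths = all_simple_paths(g, start, goal)
        if not paths:
            continue
        n = min(len(p) for p in paths)
        if best is None or n < best:
            best, best_goals = n, {goal}
        elif n == best:
            best_goals.add(goal)
    return best, best_goals


# ---------------------------------------------------------------------------
# Random schemas


_TYPES = list(PropertyType)


def random_property(rng: np.random.Generator, category: str, label: str,
                    categories: list[str]) -> PropertySpec:
    t = _TYPES[rng.integers(0, len(_TYPES))]
    constraint = Constraint.none()
    if t is PropertyType.NUMBER and rng.random() < 0.8:
        lo = float(rng.uniform(-100, 100))
        constraint = Constraint.range(round(lo, 3), round(lo + float(rng.uniform(0, 100)), 3))
    elif t is PropertyType.ENUM:
        k = int(rng.integers(2, 6))
        constraint = Constraint.domain([f"v{label}{i}" for i in range(k)])
    elif t is PropertyType.TRISTATE:
        constraint = Constraint.domain(TRISTATE_VALUES)
    elif t is PropertyType.PAGE:
        constraint = Constraint.target(str(categories[rng.integers(0, len(categories))]))
    return PropertySpec(
        label=label,
        page_name=property_page_name(label),
        category=category,
        type=t,
        constraint=constraint,
        group="G" + str(int(rng.integers(0, 3))),
        unit="u" if t is PropertyType.NUMBER and rng.random() < 0.5 else "",
    )


def random_schema(rng: np.random.Generator, n_categories: int = 3,
                  props_per_cat: int = 4) -> Schema:
    """A random valid schema: category 0 is the root, later categories
    connect to category 0 (a patient-visit star) or chain to the
    previous one, with random typed properties."""
    names = [f"Cat{string.ascii_uppercase[i]}" for i in range(n_categories)]
    cats = []
    for i, name in enumerate(names):
        connection = None
        if i > 0:
            target = names[0] if rng.random() < 0.5 else names[i - 1]
            connection = (f"Has {target}", target)
        props = tuple(
            random_property(rng, name, f"P{name}{j}", names)
            for j in range(int(rng.integers(1, props_per_cat + 1)))
        )
        groups = tuple(dict.fromkeys(p.group for p in props if p.group))
        cats.append(
            CategorySpec(name=name, connection=connection, groups=groups, properties=props)
        )
    return Schema(categories=tuple(cats), site_title="Random", language="en")


def random_graph(rng: np.random.Generator, n_nodes: int, n_edges: int) -> CategoryGraph:
    """A random labelled multigraph over categories (may be disconnected
    and may contain parallel edges), for chain-resolution stress tests."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = []
    for k in range(n_edges):
        a, b = rng.integers(0, n_nodes), rng.integers(0, n_nodes)
        if a == b:
            continue
        edges.append(GraphEdge(nodes[a], nodes[b], f"E{k}"))
    return CategoryGraph(nodes, edges)
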