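"""Constraint-driven synthetic data generation.

Given a schema, fabricate a plausible table of entities whose every
cell satisfies the declared constraint: ranged numbers uniform in
``[min, max]``, categorical and three-valued properties uniform over
their domain, dates uniform in a configurable window, coordinates
uniform in a bounding box, free text from a small word pool.  The
generator fills demo sites and doubles as the test-fixture engine:
its core contract is that whatever it emits re-parses under the same
schema with zero errors.

Determinism matters for reproducible fixtures: each column draws from
its own random stream derived from the root seed and the column name,
so adding a column never perturbs the values of the others.

Distributions are deliberately uniform — the generator demonstrates the
machinery, it does not simulate clinical reality (no correlated
comorbidities, no realistic marginals).  Per-property sampler hooks let
a demo plug in something fancier.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .schema_core import (
    CategorySpec,
    ConstraintKind,
    PropertySpec,
    PropertyType,
    Schema,
    Severity,
    validate_schema,
)
from .data_import import (
    MISSING,
    PARENT_COLUMN,
    Record,
    RecordSet,
    Value,
    assign_titles,
    encode_value,
)

__all__ = ["GenConfig", "sample_value", "generate_records", "records_to_tsv"]

#: Small neutral word pool for TEXT properties.
_WORDS = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi",
)


@dataclass(frozen=True)
class GenConfig:
    """Generation parameters.

    Defaults emulate a small demonstration registry: a few dozen
    subjects observed over a year (the window covers 2020, matching a
    COVID-style surveillance table), locations inside an Italy-sized
    bounding box, and an occasional unentered cell.
    """

    n_parents: int = 50
    visits_per_parent: tuple[int, int] = (1, 4)
    seed: int = 0
    missing_rate: float = 0.05
    date_window: tuple[str, str] = ("2020-01-01", "2020-12-31")
    coord_bbox: tuple[float, float, float, float] = (35.0, 47.0, 6.0, 19.0)
    samplers: dict[str, Callable[[np.random.Generator], Value]] = field(
        default_factory=dict, compare=False
    )

    def __post_init__(self) -> None:
        if self.n_parents < 0:
            raise ValueError("n_parents must be >= 0")
        lo, hi = self.visits_per_parent
        if lo > hi or lo < 0:
            raise ValueError("visits_per_parent range must be ordered and >= 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be a probability")
        start, end = (dt.date.fromisoformat(d) for d in self.date_window)
        if start > end:
            raise ValueError("date_window must be ordered")
        lat0, lat1, lon0, lon1 = self.coord_bbox
        if lat0 > lat1 or lon0 > lon1:
            raise ValueError("coord_bbox must be ordered")


def sample_value(
    p: PropertySpec,
    rng: np.random.Generator,
    cfg: GenConfig = GenConfig(),
) -> Value:
    """Draw one value satisfying ``p``'s constraint."""
    custom = cfg.samplers.get(p.label)
    if custom is not None:
        return custom(rng)
    t, k = p.type, p.constraint
    if t is PropertyType.NUMBER:
        lo, hi = (k.min, k.max) if k.kind is ConstraintKind.RANGE else (0.0, 100.0)
        v = float(rng.uniform(lo, hi))
        return round(v, 6)  # printable precision, still inside the closed range
    if t in (PropertyType.ENUM, PropertyType.TRISTATE):
        return str(k.values[rng.integers(0, len(k.values))])
    if t is PropertyType.BOOLEAN:
        return bool(rng.integers(0, 2))
    if t is PropertyType.DATE:
        start, end = (dt.date.fromisoformat(d) for d in cfg.date_window)
        span = (end - start).days
        return start + dt.timedelta(days=int(rng.integers(0, span + 1)))
    if t is PropertyType.COORDINATES:
        lat0, lat1, lon0, lon1 = cfg.coord_bbox
        return (round(float(rng.uniform(lat0, lat1)), 6),
                round(float(rng.uniform(lon0, lon1)), 6))
    if t is PropertyType.URL:
        return f"https://example.org/{_WORDS[rng.integers(0, len(_WORDS))]}"
    if t is PropertyType.PAGE:
        target = k.target_category or "Page"
        return f"{target} {int(rng.integers(1, 10))}"
    # TEXT
    n = int(rng.integers(1, 4))
    return " ".join(_WORDS[rng.integers(0, len(_WORDS))] for _ in range(n))


def _root_and_children(schema: Schema) -> tuple[CategorySpec, list[CategorySpec]]:
    roots = [c for c in schema.categories if c.connection is None]
    if not roots:
        raise ValueError("schema has no root category (one without a connection)")
    root = roots[0]
    children = [c for c in schema.categories if c.connection and c.connection[1] == root.name]
    return root, children


def _fill(
    cat: CategorySpec, cfg: GenConfig, row_index: int, parent_title: Optional[str]
) -> Record:
    values: dict[str, object] = {}
    for p in cat.properties:
        # per-(column, row) stream: row order and sibling columns are immaterial
        row_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(f"{cat.name}\t{p.label}".encode()), row_index])
        )
        if cfg.missing_rate > 0 and row_rng.random() < cfg.missing_rate:
            values[p.label] = MISSING
        else:
            values[p.label] = sample_value(p, row_rng, cfg)
    return Record(category=cat.name, values=values, parent_title=parent_title)


def generate_records(schema: Schema, cfg: GenConfig) -> RecordSet:
    """Generate ``cfg.n_parents`` records of the schema's root category
    and, for every child category connected to it, a per-parent number
    of child records drawn uniformly from ``cfg.visits_per_parent``.

    Output is deterministic in ``(schema, cfg)`` and always re-parses
    with zero error diagnostics.
    """
    problems = [d for d in validate_schema(schema) if d.severity is Severity.ERROR]
    if problems:
        raise ValueError("invalid schema: " + "; ".join(map(str, problems)))
    root, children = _root_and_children(schema)
    records: list[Record] = [
        _fill(root, cfg, i, None) for i in range(cfg.n_parents)
    ]
    rs = assign_titles(RecordSet(schema=schema, records=records))
    parent_titles = [r.title for r in rs.records]
    lo, hi = cfg.visits_per_parent
    for child in children:
        count_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(child.name.encode())])
        )
        row = 0
        child_records: list[Record] = []
        for title in parent_titles:
            n = int(count_rng.integers(lo, hi + 1))
            for _ in range(n):
                child_records.append(_fill(child, cfg, row, title))
                row += 1
        child_rs = assign_titles(
            RecordSet(schema=schema, records=child_records),
            existing_titles={r.title for r in rs.records},
        )
        rs.records.extend(child_rs.records)
    return rs


def records_to_tsv(rs: RecordSet, category: str) -> str:
    """Serialise the records of one category to a data TSV re-parseable
    by :func:`wikischema.data_import.parse_data` (with a ``!parent``
    column for connected categories)."""
    cat = rs.schema.category(category)
    if cat is None:
        raise ValueError(f"unknown category {category!r}")
    labels = [p.label for p in cat.properties]
    header = list(labels)
    child = cat.connection is not None
    parent_index: dict[str, int] = {}
    if child:
        parents = rs.of_category(cat.connection[1])
        parent_index = {r.title: i + 1 for i, r in enumerate(parents)}
        header.append(PARENT_COLUMN)
    lines = ["\t".join(header)]
    for r in rs.of_category(category):
        cells = []
        for p in cat.properties:
            v = r.values.get(p.label, MISSING)
            cells.append("" if v is MISSING else encode_value(v, p))
        if child:
            cells.append(str(parent_index[r.parent_title]) if r.parent_title else "")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
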