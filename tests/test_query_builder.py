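"""Chain resolution, ASK text rendering, and the reference evaluator."""

import itertools

import numpy as np
import pytest

from wikischema.data_import import Record, RecordSet, parse_data
from wikischema.query_builder import (
    AskQuery,
    Chain,
    ChainError,
    Comparator,
    Condition,
    Direction,
    auto_query,
    build_ask,
    evaluate_ask,
    parse_ask,
    resolve_chain,
    shortest_chain,
)
from wikischema.schema_core import CategoryGraph, GraphEdge, parse_schema, schema_graph

from helpers import brute_shortest_length, random_graph


class TestResolveChain:
    def test_inverse_step_from_parent_to_child_property(self, patients_visits_schema):
        g = schema_graph(patients_visits_schema)
        chain = resolve_chain(g, patients_visits_schema, "Patients", "Temperature")
        assert chain.steps == (("Has Patient", Direction.INVERSE),)
        assert chain.render() == "-Has Patient"

    def test_forward_step_from_child_to_parent_property(self, patients_visits_schema):
        g = schema_graph(patients_visits_schema)
        chain = resolve_chain(g, patients_visits_schema, "Visits", "Age")
        assert chain.steps == (("Has Patient", Direction.FORWARD),)
        assert chain.render() == "Has Patient"

    def test_local_property_resolves_to_empty_chain(self, patients_visits_schema):
        g = schema_graph(patients_visits_schema)
        chain = resolve_chain(g, patients_visits_schema, "Visits", "Temperature")
        assert chain.steps == () and not chain

    def test_unreachable_property_raises(self):
        s = parse_schema(
            "!category\tA\nX\ttext\t\n!category\tB\nY\ttext\t\n"
        )
        g = schema_graph(s)
        with pytest.raises(ChainError, match="reachable"):
            resolve_chain(g, s, "A", "Y")

    def test_ambiguous_owners_listed(self):
        # B and C both own "Z" and are both one step from A
        s = parse_schema(
            "!category\tA\nX\ttext\t\n"
            "!category\tB\tconnection=Has A->A\nZ\ttext\t\n"
            "!category\tC\tconnection=Also has A->A\nZ\ttext\t\n"
        )
        g = schema_graph(s)
        with pytest.raises(ChainError) as exc:
            resolve_chain(g, s, "A", "Z")
        assert "CatB" not in str(exc.value)  # names the real candidates
        assert "B" in str(exc.value) and "C" in str(exc.value)


class TestChainOracle:
    def _forests(self, n):
        """All labelled forests on n nodes, as parent vectors."""
        nodes = list(range(n))
        for parents in itertools.product([None] + nodes, repeat=n):
            if any(p == i for i, p in enumerate(parents)):
                continue
            # acyclicity
            ok = True
            for i in range(n):
                seen = set()
                j = i
                while parents[j] is not None:
                    if j in seen:
                        ok = False
                        break
                    seen.add(j)
                    j = parents[j]
                if not ok:
                    break
            if ok:
                yield parents

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_exhaustive_small_forests(self, n):
        names = [f"N{i}" for i in range(n)]
        for parents in self._forests(n):
            edges = [
                GraphEdge(names[i], names[p], f"Has {names[p]}")
                for i, p in enumerate(parents)
                if p is not None
            ]
            g = CategoryGraph(names, edges)
            for a, b in itertools.permutations(range(n), 2):
                expect, goals = brute_shortest_length(g, names[a], {names[b]})
                if expect is None:
                    with pytest.raises(ChainError):
                        shortest_chain(g, names[a], {names[b]})
                else:
                    chain = shortest_chain(g, names[a], {names[b]})
                    assert len(chain.steps) == expect

    @pytest.mark.parametrize("seed", range(30))
    def test_random_multigraphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(4, 9)), int(rng.integers(3, 12)))
        nodes = list(g.nodes)
        for a in nodes[:3]:
            for b in nodes[-3:]:
                if a == b:
                    continue
                expect, _goals = brute_shortest_length(g, a, {b})
                if expect is None:
                    with pytest.raises(ChainError):
                        shortest_chain(g, a, {b})
                else:
                    assert len(shortest_chain(g, a, {b}).steps) == expect

    def test_equal_length_chains_pick_lexicographically_smallest(self):
        # two parallel edges A->B: chains "P1" and "P2" both length 1
        g = CategoryGraph(["A", "B"], [GraphEdge("A", "B", "P2"), GraphEdge("A", "B", "P1")])
        assert shortest_chain(g, "A", {"B"}).render() == "P1"


class TestBuildAsk:
    def test_temperature_example(self, patients_visits_schema):
        q = auto_query(
            patients_visits_schema,
            "Visits",
            [Condition("Temperature", Comparator.GT, 37)],
            ["Temperature"],
        )
        assert build_ask(q, patients_visits_schema) == (
            "{{#ask: [[Category:Visits]] [[Temperature::>37]] |?Temperature}}"
        )

    def test_bare_category_query(self, patients_visits_schema):
        q = AskQuery(category="Visits")
        assert build_ask(q, patients_visits_schema) == "{{#ask: [[Category:Visits]]}}"

    def test_cross_category_printout_renders_inverse_chain(self, patients_visits_schema):
        q = auto_query(patients_visits_schema, "Patients", [], ["Temperature"])
        assert "|?-Has Patient.Temperature" in build_ask(q, patients_visits_schema)

    def test_ge_renders_two_character_form(self, patients_visits_schema):
        q = auto_query(
            patients_visits_schema, "Visits",
            [Condition("Temperature", Comparator.GE, 37.5)], [],
        )
        assert "[[Temperature::>=37.5]]" in build_ask(q, patients_visits_schema)

    def test_ordered_comparator_needs_number_or_date(self, covid_schema):
        q = AskQuery(
            category="Patients",
            conditions=((Chain(), Condition("Fever", Comparator.GT, "Yes")),),
        )
        with pytest.raises(ValueError, match="number or date"):
            build_ask(q, covid_schema)

    def test_build_parse_roundtrip(self, patients_visits_schema):
        q = auto_query(
            patients_visits_schema, "Patients",
            [Condition("Temperature", Comparator.LE, 39.0), Condition("Age", Comparator.GT, 18)],
            ["Age", "Temperature"],
        )
        text = build_ask(q, patients_visits_schema)
        assert parse_ask(text, patients_visits_schema) == q


def _covid_records(covid_schema, temps):
    parents = parse_data("Age\n" + "\n".join("40" for _ in temps) + "\n", covid_schema, "Patients")
    rows = "\n".join(f"{t}\t{i + 1}" for i, t in enumerate(temps))
    kids = parse_data(
        "Temperature\t!parent\n" + rows + "\n", covid_schema, "Samplings",
        parents=parents,
    )
    return RecordSet(covid_schema, parents.records + kids.records)


class TestEvaluate:
    def test_counts_match_direct_filter(self, covid_schema):
        temps = [36.5, 37.0, 38.2, 39.1, 36.9, 40.0]
        rs = _covid_records(covid_schema, temps)
        q = auto_query(
            covid_schema, "Samplings",
            [Condition("Temperature", Comparator.GT, 37)], ["Temperature"],
        )
        df = evaluate_ask(q, rs)
        assert len(df) == sum(1 for t in temps if t > 37)
        assert set(df["Temperature"]) == {t for t in temps if t > 37}

    def test_empty_recordset_empty_table(self, covid_schema):
        rs = RecordSet(covid_schema, [])
        q = AskQuery(category="Samplings")
        assert len(evaluate_ask(q, rs)) == 0

    def test_chained_condition_selects_parents_via_children(self, covid_schema):
        rs = _covid_records(covid_schema, [36.0, 39.0])
        q = auto_query(
            covid_schema, "Patients",
            [Condition("Temperature", Comparator.GT, 37)], ["Temperature"],
        )
        df = evaluate_ask(q, rs)
        assert list(df["Page"]) == ["Patients 2"]
        assert list(df["-Has Patient.Temperature"]) == [39.0]

    def test_missing_never_satisfies(self, covid_schema):
        parents = parse_data("Age\n\n40\n", covid_schema, "Patients")
        q = auto_query(covid_schema, "Patients", [Condition("Age", Comparator.LE, 200)], [])
        df = evaluate_ask(q, parents)
        assert list(df["Page"]) == ["Patients 2"]

    def test_tristate_eq_na_selects_na_not_missing(self, covid_schema):
        parents = parse_data("Fever\nNA\n\nYes\n", covid_schema, "Patients")
        q = auto_query(covid_schema, "Patients", [Condition("Fever", Comparator.EQ, "NA")], [])
        df = evaluate_ask(q, parents)
        assert list(df["Page"]) == ["Patients 1"]

    def test_reparsed_query_evaluates_identically(self, covid_schema):
        rs = _covid_records(covid_schema, [36.1, 37.9, 38.6])
        q = auto_query(
            covid_schema, "Samplings",
            [Condition("Temperature", Comparator.GE, 37.9)], ["Temperature"],
        )
        text = build_ask(q, covid_schema)
        q2 = parse_ask(text, covid_schema)
        assert evaluate_ask(q, rs).equals(evaluate_ask(q2, rs))
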