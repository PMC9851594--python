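"""Site compilation: support pages, page inventory, XML serialisation."""

import re

import numpy as np
import pytest
from lxml import etree

from wikischema.schema_core import parse_schema, validate_schema
from wikischema.xml_emitter import (
    EmitOptions,
    Namespace,
    emit_category_page,
    emit_form,
    emit_property_page,
    emit_site,
    emit_template,
    expected_page_count,
    serialize_xml,
    site_property_pages,
)

from helpers import random_schema

ANNOTATION_RE = re.compile(r"\[\[([^\]:|]+)::")
#: builtin SMW properties that need no generated page
BUILTIN = {"Has type", "Allows value"}


def _temperature(schema):
    return schema.category("Samplings").property_by_label("Temperature")


class TestPropertyPage:
    def test_number_type_annotation(self, covid_schema):
        page = emit_property_page(_temperature(covid_schema))
        assert page.namespace is Namespace.PROPERTY
        assert page.full_title == "Property:Temperature"
        assert page.text.count("[[Has type::") == 1
        assert "[[Has type::Number]]" in page.text
        assert "°C" in page.text

    def test_tristate_allows_exactly_yes_no_na(self, covid_schema):
        fever = covid_schema.category("Patients").property_by_label("Fever")
        page = emit_property_page(fever)
        assert "[[Has type::Text]]" in page.text
        allowed = re.findall(r"\[\[Allows value::([^\]]+)\]\]", page.text)
        assert allowed == ["Yes", "No", "NA"]

    def test_domain_values_in_declared_order(self, covid_schema):
        sev = covid_schema.category("Samplings").property_by_label("Severity")
        page = emit_property_page(sev)
        allowed = re.findall(r"\[\[Allows value::([^\]]+)\]\]", page.text)
        assert allowed == ["mild", "moderate", "severe"]

    def test_aspects_render_as_relation_annotations(self, audiology_schema):
        p = audiology_schema.category("Visits").properties[0]
        page = emit_property_page(p)
        assert "[[laterality::left]]" in page.text
        assert "[[device::intracochlear]]" in page.text


class TestTemplate:
    def test_patients_template_rows_and_category_tag(self, patients_visits_schema):
        c = patients_visits_schema.category("Patients")
        page = emit_template(c)
        assert page.namespace is Namespace.TEMPLATE
        assert page.text.count("! Age") == 1
        assert "[[Age::{{{Age|}}}]]" in page.text
        assert page.text.rstrip().endswith(
            "[[Category:Patients]]\n</includeonly>".rstrip()
        )

    def test_empty_parameter_produces_no_annotation(self, patients_visits_schema):
        c = patients_visits_schema.category("Patients")
        # the annotation is wrapped in a #if guard on the parameter
        assert "{{#if:{{{Age|}}}|[[Age::{{{Age|}}}]]|}}" in emit_template(c).text

    def test_empty_category_template_has_only_category_tag(self):
        s = parse_schema("!category\tEmpty\n")
        text = emit_template(s.categories[0]).text
        assert "[[Category:Empty]]" in text
        assert "::" not in text

    def test_connection_annotated(self, patients_visits_schema):
        c = patients_visits_schema.category("Visits")
        assert "[[Has Patient::{{{Has Patient|}}}]]" in emit_template(c).text


class TestForm:
    def test_number_field_carries_bounds(self, patients_visits_schema):
        c = patients_visits_schema.category("Visits")
        text = emit_form(c).text
        assert "min=30" in text and "max=45" in text

    def test_enum_dropdown_lists_domain_in_order(self, covid_schema):
        text = emit_form(covid_schema.category("Samplings")).text
        assert "input type=dropdown|values=mild,moderate,severe" in text

    def test_empty_category_form_keeps_save_controls(self):
        s = parse_schema("!category\tEmpty\n")
        text = emit_form(s.categories[0]).text
        assert "{{{standard input|save}}}" in text
        assert "field|" not in text

    def test_connection_field_autocompletes_on_target(self, covid_schema):
        text = emit_form(covid_schema.category("Samplings")).text
        assert "values from category=Patients" in text


class TestCategoryPage:
    def test_default_form_and_filters(self, covid_schema):
        c = covid_schema.category("Samplings")
        text = emit_category_page(c).text
        assert "{{#default_form:Samplings}}" in text
        for label in ("Result", "Severity"):  # every DOMAIN property filters
            assert f"{label} (property={label}" in text
        assert "Temperature (property=Temperature" in text  # RANGE filters too

    def test_root_category_has_no_parent_tag(self, covid_schema):
        text = emit_category_page(covid_schema.category("Patients")).text
        assert "[[Category:" not in text

    def test_subclass_category_links_parent(self):
        s = parse_schema(
            "!category\tPeople\nName\ttext\t\n"
            "!category\tPatients\tparent=People\nAge\tnumber\t\n"
        )
        assert "[[Category:People]]" in emit_category_page(s.categories[1]).text


class TestSite:
    def test_fixture_page_inventory(self, patients_visits_schema):
        doc = emit_site(patients_visits_schema)
        # 1 main + 2 categories x 3 + 3 property pages (Age, Temperature,
        # Has Patient)
        assert len(doc.pages) == 10
        assert len(doc.pages) == expected_page_count(patients_visits_schema)

    def test_refuses_invalid_schema(self):
        from wikischema.schema_core import CategorySpec, Schema

        bad = Schema(categories=(CategorySpec(name="A", connection=("Has B", "B")),))
        with pytest.raises(ValueError):
            emit_site(bad)

    def test_doubling_categories_doubles_category_pages(self):
        rng = np.random.default_rng(7)
        s1 = random_schema(rng, n_categories=3)
        s2 = random_schema(np.random.default_rng(7), n_categories=6)
        d1, d2 = emit_site(s1), emit_site(s2)
        count1 = sum(1 for p in d1.pages if p.namespace is Namespace.CATEGORY)
        count2 = sum(1 for p in d2.pages if p.namespace is Namespace.CATEGORY)
        assert (count1, count2) == (3, 6)

    def test_property_page_closure(self, covid_schema, audiology_schema):
        for s in (covid_schema, audiology_schema):
            doc = emit_site(s)
            have = {p.title for p in doc.pages if p.namespace is Namespace.PROPERTY}
            referenced = set()
            for p in doc.pages:
                referenced.update(ANNOTATION_RE.findall(p.text))
            # wiki titles are first-letter case-insensitive
            from wikischema.schema_core import property_page_name

            normalised = {property_page_name(r) for r in referenced - BUILTIN}
            assert normalised <= have

    @pytest.mark.parametrize("seed", range(6))
    def test_page_count_formula_on_random_schemas(self, seed):
        rng = np.random.default_rng(seed)
        s = random_schema(rng, n_categories=int(rng.integers(1, 5)))
        assert validate_schema(s) == []
        assert len(emit_site(s).pages) == expected_page_count(s)

    def test_titles_namespace_unique(self, covid_schema):
        doc = emit_site(covid_schema)
        keys = [(p.namespace, p.title) for p in doc.pages]
        assert len(keys) == len(set(keys))


class TestSerialize:
    def test_validates_against_export_schema(self, covid_schema, export_xsd):
        xml = serialize_xml(emit_site(covid_schema))
        doc = etree.fromstring(xml.encode("utf-8"))
        assert export_xsd.validate(doc), export_xsd.error_log

    def test_byte_deterministic(self, covid_schema):
        a = serialize_xml(emit_site(covid_schema))
        b = serialize_xml(emit_site(covid_schema))
        assert a == b

    def test_metacharacters_escaped_and_reparseable(self):
        from wikischema.xml_emitter import WikiPage, WikiXmlDocument

        doc = WikiXmlDocument()
        doc.add(WikiPage("T", Namespace.MAIN, "a < b & c > d"))
        xml = serialize_xml(doc)
        tree = etree.fromstring(xml.encode("utf-8"))
        ns = {"mw": "http://www.mediawiki.org/xml/export-0.10/"}
        text = tree.findtext(".//mw:revision/mw:text", namespaces=ns)
        assert text == "a < b & c > d"

    def test_main_page_template_override(self, patients_visits_schema):
        opts = EmitOptions(main_page_template="custom {site_title}\n{build_links}\n{query_links}\n{export_links}")
        doc = emit_site(patients_visits_schema, opts)
        assert doc.pages[0].text.startswith("custom ")
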