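"""Compile a schema into MediaWiki import XML.

A Semantic MediaWiki site needs, beyond the data pages themselves, a
constellation of support pages: one ``Property:`` page per typed
property, one ``Template:`` page per category (the uniform annotation
skeleton), one ``Form:`` page per category (the PageForms data-entry
form), one ``Category:`` page per category (default form, subclass link,
drilldown filters), and a main page.  This module builds those pages
from a :class:`~wikischema.schema_core.Schema` and serialises them in
the standard MediaWiki export XML dialect (export namespace version
0.10), which a wiki's Special:Import consumes.

Emission is deterministic: the same schema always yields byte-identical
XML, so generated sites can be diffed and version-controlled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Iterable, Optional

from lxml import etree

from .schema_core import (
    CategorySpec,
    Constraint,
    ConstraintKind,
    PropertySpec,
    PropertyType,
    Schema,
    Severity,
    property_page_name,
    validate_schema,
)

__all__ = [
    "Namespace",
    "WikiPage",
    "WikiXmlDocument",
    "EmitOptions",
    "emit_property_page",
    "emit_template",
    "emit_form",
    "emit_category_page",
    "emit_main_page",
    "emit_site",
    "serialize_xml",
    "expected_page_count",
    "site_property_pages",
]

MEDIAWIKI_EXPORT_NS = "http://www.mediawiki.org/xml/export-0.10/"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
SCHEMA_LOCATION = (
    "http://www.mediawiki.org/xml/export-0.10/ "
    "http://www.mediawiki.org/xml/export-0.10.xsd"
)

#: Fixed revision timestamp so that emission is reproducible.
DEFAULT_TIMESTAMP = "2023-01-01T00:00:00Z"
DEFAULT_CONTRIBUTOR = "WikiSchema"
GENERATOR_TAG = "wikischema 0.1.0"


class Namespace(IntEnum):
    """MediaWiki namespace numbers used by the generated pages."""

    MAIN = 0
    TEMPLATE = 10
    CATEGORY = 14
    PROPERTY = 102
    FORM = 106


_NS_PREFIX = {
    Namespace.MAIN: "",
    Namespace.TEMPLATE: "Template:",
    Namespace.CATEGORY: "Category:",
    Namespace.PROPERTY: "Property:",
    Namespace.FORM: "Form:",
}


@dataclass(frozen=True)
class WikiPage:
    title: str  # without namespace prefix
    namespace: Namespace
    text: str

    @property
    def full_title(self) -> str:
        return _NS_PREFIX[self.namespace] + self.title


@dataclass
class WikiXmlDocument:
    pages: list[WikiPage] = field(default_factory=list)
    generator_tag: str = GENERATOR_TAG
    language: str = "en"
    site_title: str = "Wiki"

    def add(self, page: WikiPage) -> None:
        if any(
            p.namespace == page.namespace and p.title == page.title for p in self.pages
        ):
            raise ValueError(f"duplicate page {page.full_title!r}")
        self.pages.append(page)


def _messages(language: str) -> dict[str, str]:
    name = f"{language}.json"
    base = resources.files("wikischema") / "locales"
    path = base / name
    if not path.is_file():
        path = base / "en.json"
    return json.loads(path.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class EmitOptions:
    """Options controlling site emission.

    ``main_page_template`` may override the generated home page; it is a
    ``str.format`` template receiving ``site_title`` and the three link
    sections as ``build_links``, ``query_links``, ``export_links``.
    """

    timestamp: str = DEFAULT_TIMESTAMP
    contributor: str = DEFAULT_CONTRIBUTOR
    main_page_template: Optional[str] = None


# ---------------------------------------------------------------------------
# Individual page emitters


def emit_property_page(p: PropertySpec, language: str = "en") -> WikiPage:
    """Emit the ``Property:`` page declaring a property's SMW datatype,
    its allowed values (for categorical and three-valued properties) and
    any aspect decomposition, with unit and help text as display prose."""
    msg = _messages(language)
    lines: list[str] = []
    if p.note:
        lines.append(p.note)
        lines.append("")
    lines.append(msg["property_of"].format(category=p.category))
    if p.unit:
        lines.append(msg["unit_suffix"].format(unit=p.unit))
    lines.append("")
    lines.append(f"* [[Has type::{p.type.smw_type}]]")
    if p.constraint.kind is ConstraintKind.DOMAIN:
        lines.append(msg["allowed_values"])
        for v in p.constraint.values:
            lines.append(f"* [[Allows value::{v}]]")
    for rel, value in p.aspects:
        lines.append(f"* [[{rel}::{value}]]")
    return WikiPage(p.page_name, Namespace.PROPERTY, "\n".join(lines) + "\n")


def _guarded_annotation(prop_page: str, param: str) -> str:
    # An empty template parameter must not produce a (dangling) annotation.
    return f"{{{{#if:{{{{{{{param}|}}}}}}|[[{prop_page}::{{{{{{{param}|}}}}}}]]|}}}}"


def _grouped(properties: Iterable[PropertySpec]) -> list[tuple[str, list[PropertySpec]]]:
    groups: list[tuple[str, list[PropertySpec]]] = []
    for p in properties:
        if groups and groups[-1][0] == p.group:
            groups[-1][1].append(p)
        else:
            groups.append((p.group, [p]))
    return groups


def emit_template(c: CategorySpec, language: str = "en") -> WikiPage:
    """Emit the per-category ``Template:`` page.

    The template renders a two-column (label, value) table grouped by
    property group, annotates every non-empty parameter with its
    semantic property, annotates the connection parameter when the
    category links to a parent category, and categorises the page.
    """
    msg = _messages(language)
    lines = [
        "<noinclude>",
        msg["template_doc"].format(name=c.name),
        "</noinclude><includeonly>",
        '{| class="wikitable"',
    ]
    for group, props in _grouped(c.properties):
        if group:
            lines.append(f'! colspan="2" | {group}')
            lines.append("|-")
        for p in props:
            lines.append(f"! {p.label}")
            value = _guarded_annotation(p.page_name, p.label)
            if p.unit:
                value += f" {p.unit}"
            lines.append(f"| {value}")
            lines.append("|-")
    if c.connection is not None:
        prop, target = c.connection
        prop_page = property_page_name(prop)
        lines.append(f"! {prop}")
        lines.append(f"| {_guarded_annotation(prop_page, prop)}")
        lines.append("|-")
    if lines[-1] == "|-":
        lines.pop()
    lines.append("|}")
    lines.append(f"[[Category:{c.name}]]")
    lines.append("</includeonly>")
    return WikiPage(c.name, Namespace.TEMPLATE, "\n".join(lines) + "\n")


def _form_field(p: PropertySpec) -> str:
    """PageForms field definition for one property, choosing the input
    control from the property type and constraint."""
    parts = [f"field|{p.label}"]
    t, k = p.type, p.constraint
    if t is PropertyType.NUMBER:
        parts.append("input type=text")
        parts.append("size=10")
        if k.kind is ConstraintKind.RANGE:
            parts.append(f"min={_fmt_num(k.min)}")
            parts.append(f"max={_fmt_num(k.max)}")
    elif t is PropertyType.DATE:
        parts.append("input type=datepicker")
    elif t in (PropertyType.ENUM, PropertyType.TRISTATE):
        parts.append("input type=dropdown")
        parts.append("values=" + ",".join(k.values))
    elif t is PropertyType.BOOLEAN:
        parts.append("input type=checkbox")
    elif t is PropertyType.PAGE and k.kind is ConstraintKind.TARGET:
        parts.append("input type=combobox")
        parts.append(f"values from category={k.target_category}")
    else:  # TEXT, COORDINATES, URL, untargeted PAGE
        parts.append("input type=text")
    return "{{{" + "|".join(parts) + "}}}"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def emit_form(c: CategorySpec, language: str = "en") -> WikiPage:
    """Emit the ``Form:`` page (PageForms syntax) for a category."""
    msg = _messages(language)
    lines = [
        "<noinclude>",
        msg["form_doc"].format(name=c.name),
        "",
        f"{{{{#forminput:form={c.name}}}}}",
        "</noinclude><includeonly>",
        f"{{{{{{for template|{c.name}}}}}}}",
    ]
    for group, props in _grouped(c.properties):
        if group:
            lines.append(f"=== {group} ===")
        lines.append('{| class="formtable"')
        for p in props:
            lines.append(f"! {p.label}:")
            lines.append(f"| {_form_field(p)}")
            lines.append("|-")
        if lines[-1] == "|-":
            lines.pop()
        lines.append("|}")
    if c.connection is not None:
        prop, target = c.connection
        lines.append(f"! {prop}:")
        lines.append(
            "{{{" + f"field|{prop}|input type=combobox|values from category={target}" + "}}}"
        )
    lines.append("{{{end template}}}")
    lines.append("{{{standard input|save}}} {{{standard input|cancel}}}")
    lines.append("</includeonly>")
    return WikiPage(c.name, Namespace.FORM, "\n".join(lines) + "\n")


_FILTERABLE = {
    PropertyType.ENUM,
    PropertyType.TRISTATE,
    PropertyType.BOOLEAN,
}


def _drilldown_filters(c: CategorySpec) -> list[str]:
    filters = []
    for p in c.properties:
        if p.type in _FILTERABLE or p.constraint.kind is ConstraintKind.RANGE:
            spec = f"{p.label} (property={p.page_name}"
            if p.group:
                spec += f",group={p.group}"
            spec += ")"
            filters.append(spec)
    return filters


def emit_category_page(c: CategorySpec, language: str = "en") -> WikiPage:
    """Emit the ``Category:`` page: default form declaration, subclass
    link when the category has a parent, and the drilldown filter
    declaration over categorical, three-valued, boolean and ranged
    properties, grouped by property group."""
    lines = [f"{{{{#default_form:{c.name}}}}}"]
    filters = _drilldown_filters(c)
    if filters:
        lines.append("{{#drilldowninfo:filters=" + ";\n  ".join(filters) + "}}")
    if c.parent:
        lines.append(f"[[Category:{c.parent}]]")
    return WikiPage(c.name, Namespace.CATEGORY, "\n".join(lines) + "\n")


def emit_main_page(s: Schema, opts: EmitOptions = EmitOptions()) -> WikiPage:
    """Emit the site's home page: a short guide with links grouped into
    three areas — building/modifying the database, querying, export."""
    msg = _messages(s.language)
    build_links = "\n".join(
        f"* [[Special:FormEdit/{c.name}|{msg['add_entry'].format(category=c.name)}]]"
        for c in s.categories
    )
    query_links = "\n".join(
        f"* [[Special:BrowseData/{c.name}|{msg['browse'].format(category=c.name)}]]"
        for c in s.categories
    ) + f"\n* [[Special:Ask|{msg['ask_page']}]]"
    export_links = f"* [[Special:Export|{msg['export_facts']}]]"
    template = opts.main_page_template or (
        "{site_title}\n\n"
        + msg["main_page_intro"]
        + "\n\n== "
        + msg["section_build"]
        + " ==\n{build_links}\n\n== "
        + msg["section_query"]
        + " ==\n{query_links}\n\n== "
        + msg["section_export"]
        + " ==\n{export_links}\n"
    )
    text = template.format(
        site_title=f"= {s.site_title} =",
        build_links=build_links,
        query_links=query_links,
        export_links=export_links,
    )
    return WikiPage("Main Page", Namespace.MAIN, text)


# ---------------------------------------------------------------------------
# Whole-site emission


def site_property_pages(s: Schema, language: str = "en") -> list[WikiPage]:
    """All ``Property:`` pages a schema needs, each emitted exactly once:
    the declared properties, the connection properties (Page-typed,
    pointing at the parent category) and the aspect relations (Text).
    Order is first appearance in the schema."""
    seen: set[str] = set()
    pages: list[WikiPage] = []

    def _add(spec: PropertySpec) -> None:
        if spec.page_name in seen:
            return
        seen.add(spec.page_name)
        pages.append(emit_property_page(spec, language))

    for c in s.categories:
        for p in c.properties:
            _add(p)
    for c in s.categories:
        if c.connection is not None:
            prop, target = c.connection
            _add(
                PropertySpec(
                    label=prop,
                    page_name=property_page_name(prop),
                    category=c.name,
                    type=PropertyType.PAGE,
                    constraint=Constraint.target(target),
                )
            )
    for c in s.categories:
        for p in c.properties:
            for rel, _value in p.aspects:
                _add(
                    PropertySpec(
                        label=rel,
                        page_name=property_page_name(rel),
                        category=c.name,
                        type=PropertyType.TEXT,
                    )
                )
    return pages


def expected_page_count(s: Schema) -> int:
    """Closed-form size of the emitted site: one main page, three pages
    per category, one page per distinct property ∪ connection ∪ aspect
    relation (distinct by normalised page title)."""
    names = set()
    for c in s.categories:
        for p in c.properties:
            names.add(p.page_name)
            for rel, _v in p.aspects:
                names.add(property_page_name(rel))
        if c.connection is not None:
            names.add(property_page_name(c.connection[0]))
    return 1 + 3 * len(s.categories) + len(names)


def emit_site(s: Schema, opts: EmitOptions = EmitOptions()) -> WikiXmlDocument:
    """Compile a valid schema to the full site document, in deterministic
    order: main page; per category its template, form and category page;
    then every property page exactly once."""
    problems = [d for d in validate_schema(s) if d.severity is Severity.ERROR]
    if problems:
        raise ValueError("refusing to emit an invalid schema: " + "; ".join(map(str, problems)))
    doc = WikiXmlDocument(language=s.language, site_title=s.site_title)
    doc.add(emit_main_page(s, opts))
    for c in s.categories:
        doc.add(emit_template(c, s.language))
        doc.add(emit_form(c, s.language))
        doc.add(emit_category_page(c, s.language))
    for page in site_property_pages(s, s.language):
        doc.add(page)
    return doc


# ---------------------------------------------------------------------------
# Serialization


def serialize_xml(d: WikiXmlDocument, opts: EmitOptions = EmitOptions()) -> str:
    """Serialise to MediaWiki export XML (namespace version 0.10).

    One ``<page>`` per wiki page with title (namespace-prefixed), ``ns``
    and a single revision with model ``wikitext`` and format
    ``text/x-wiki``.  Byte-deterministic for equal inputs: revision
    metadata is fixed, ids are sequential.
    """
    nsmap = {None: MEDIAWIKI_EXPORT_NS, "xsi": XSI_NS}
    root = etree.Element(
        f"{{{MEDIAWIKI_EXPORT_NS}}}mediawiki",
        nsmap=nsmap,
        attrib={
            f"{{{XSI_NS}}}schemaLocation": SCHEMA_LOCATION,
            "version": "0.10",
            f"{{{'http://www.w3.org/XML/1998/namespace'}}}lang": d.language,
        },
    )

    def el(parent: etree._Element, tag: str, text: Optional[str] = None) -> etree._Element:
        e = etree.SubElement(parent, f"{{{MEDIAWIKI_EXPORT_NS}}}{tag}")
        if text is not None:
            e.text = text
        return e

    siteinfo = el(root, "siteinfo")
    el(siteinfo, "sitename", d.site_title)
    el(siteinfo, "generator", d.generator_tag)

    for i, page in enumerate(d.pages, start=1):
        pe = el(root, "page")
        el(pe, "title", page.full_title)
        el(pe, "ns", str(int(page.namespace)))
        el(pe, "id", str(i))
        rev = el(pe, "revision")
        el(rev, "id", str(i))
        el(rev, "timestamp", opts.timestamp)
        contrib = el(rev, "contributor")
        el(contrib, "username", opts.contributor)
        el(rev, "model", "wikitext")
        el(rev, "format", "text/x-wiki")
        text_el = el(rev, "text")
        text_el.set(f"{{{'http://www.w3.org/XML/1998/namespace'}}}space", "preserve")
        text_el.text = page.text

    body = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return body.decode("utf-8")
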