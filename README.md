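# wikischema

Compile tabular (TSV) schema specifications into complete Semantic
MediaWiki site definitions, and tabular data into importable wiki pages.

## Who this is for

Clinical and biomedical research groups often design their databases in
spreadsheets: one row per field, with its type, unit, allowed values and
a short note.  Semantic MediaWiki (SMW) is a natural host for such
databases — every entity is a wiki page annotated with typed properties,
queryable with inline *ASK* queries and browsable with faceted drilldown
— but standing up an SMW site by hand means writing dozens to hundreds
of interlocking support pages (property declarations, templates, entry
forms, category pages).  `wikischema` generates all of them from a
single TSV file, so the people who own the data model can keep working
in a spreadsheet while the wiki stays consistent with it.

The package provides, as a library and a CLI:

* **Schema compiler** — an enriched TSV dialect describing categories,
  their subclass hierarchy, one-to-many connections (e.g. each visit
  links to its patient), grouped typed properties, numeric ranges and
  categorical domains, compiled to MediaWiki import XML (export-0.10
  dialect): per-property pages, per-category templates/forms/category
  pages with drilldown filters, and a main page.
* **Data importer** — a data TSV becomes one page per row, each a
  single template call; entities are titled with progressive numbers
  (`Patients 1`, `Patients 1/Visits 2`), with collisions rejected
  up front rather than merely flagged.
* **Synthetic data generator** — fills any schema with values that
  satisfy its constraints, deterministically per seed; useful for demo
  sites and for testing the pipeline end to end.
* **ASK query builder** — constructs `{{#ask: ...}}` queries and
  resolves *property chains* automatically: ask for `Temperature` from
  `Patients` and the builder finds the shortest path through the
  connection graph, rendering inverse steps with the `-` prefix
  (`?-Has Patient.Temperature`).  A reference evaluator executes
  queries against in-memory records so semantics are testable without
  a wiki.
* **Prolog fact export** — every subject–property–object triple becomes
  a ground term `fact('Patients 1', temperature, 38.5).`, and complex
  clinical property labels ("Pure tone average of vocal gain … on left
  ear") export their relational decomposition as
  `property_aspect(pred, laterality, 'left').` clauses for rule-based
  querying outside the wiki.

Boolean fields support a three-valued ("yes / no / not available")
logic: `NA` is an explicitly recorded answer, distinct from a cell that
was never filled in.

## Worked example

`examples/covid.tsv` describes a small COVID-style registry: a
`Patients` category (age, sex, residence coordinates, symptom onset
date, three-valued fever/cough flags, …) and a `Samplings` category
connected to it through the `Has Patient` property (sampling date,
temperature constrained to 30–45 °C, swab result, severity).

Compile the site definition:

```sh
wikischema schema examples/covid.tsv -o site.xml
```

`site.xml` contains 21 pages — 1 main page, 3 pages per category
(template, form, category page) and 15 property pages — ready for the
wiki's Special:Import.  Generate three synthetic patients:

```sh
wikischema gen examples/covid.tsv -n 3 --seed 42 --missing-rate 0 \
    --category Patients -o patients.tsv
```

```
Age	Sex	Residence	Symptom onset	Fever	Cough	...
37.801158	F	46.413764, 16.988067	2020-01-21	No	Yes	...
50.9813	M	41.044111, 8.848092	2020-11-09	Yes	Yes	...
85.057371	F	42.93526, 18.710202	2020-07-14	No	No	...
```

Build the classic query — feverish patients, reported with their
temperature — stating only the category and the properties; the chain
through `Has Patient` is resolved automatically and rendered inverse:

```sh
wikischema ask examples/covid.tsv --category Patients \
    --where "Temperature > 37" -p Temperature -p Age
```

```
{{#ask: [[Category:Patients]] [[-Has Patient.Temperature::>37]] |?-Has Patient.Temperature |?Age}}
```

Export the same data as Prolog facts:

```sh
wikischema prolog examples/covid.tsv patients.tsv --category Patients -o facts.pl
```

```
% facts exported from schema 'COVID cases'
fact('Patients 1', age, 37.801158).
fact('Patients 1', sex, 'F').
fact('Patients 1', residence, coord(46.413764,16.988067)).
fact('Patients 1', symptom_onset, date(2020,1,21)).
fact('Patients 1', fever, 'No').
...
```

A standard interpreter can then answer
`?- fact(P, temperature, T), T > 37.` directly.

The schema dialect itself is documented in
`src/wikischema/schema_core.py` and `docs/methods.md`; the two example
schemas under `examples/` exercise every feature, including aspect
decomposition of complex properties (`examples/audiology.tsv`).

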