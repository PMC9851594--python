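# Methods

## The model

`wikischema` treats a Semantic MediaWiki site as the realisation of a
small relational model:

* a **category** is a table / OWL class; its instances are wiki pages;
* a **property** is a typed column, declared on a `Property:` page via
  `[[Has type::...]]`; the supported types are Text, Number, Date,
  Boolean, three-valued Boolean (realised as Text with the fixed domain
  Yes/No/NA), categorical Text (with an `Allows value` domain), Page,
  Geographic coordinate, and URL;
* a **connection** is a one-to-many relation realised as a Page-typed
  property on the "many" side pointing at the "one" side — the
  patient–visit relation is the canonical instance;
* a **subclass hierarchy** is expressed by category pages carrying the
  parent's category tag.

Uniform annotation is delegated to one template per category: data
pages contain nothing but a template call, and the template performs
every semantic annotation.  Each annotation is guarded
(`{{#if:{{{P|}}}|[[P::{{{P|}}}]]|}}`) so an empty form field yields *no*
annotation rather than an annotation with an empty value.

## The schema dialect

The input is tab-separated text; directive lines begin with `!`
(`!site`, `!language`, `!category … parent=… connection=Prop->Target`,
`!group`), all other lines are property rows
`label / type / constraint / unit / note [/ aspects]` with constraints
`min:max`, `v1|v2|…` or `->Category`.  The dialect was designed to be
typeable in a spreadsheet and exported as TSV without quoting: tabs and
newlines are structural and forbidden in cells, encoding is UTF-8 with
an optional BOM, and an empty data line is an all-missing row.  A
canonical serialiser emits the same dialect back; serialise∘parse is
the identity (modulo source line numbers) and is tested as such.

Parsing is total: any byte string that decodes as UTF-8 yields either a
validated schema or a list of line-addressed diagnostics, never an
exception escape (fuzz-tested).  Validation checks reference
resolution, duplicate names, range ordering, domain well-formedness,
hierarchy acyclicity (DFS) and the aspect-relation vocabulary.

## Page inventory and XML

Site emission is deterministic and its size has a closed form:
`1 + 3·|categories| + |distinct properties ∪ connections ∪ aspect
relations|` (main page; template+form+category page per category; one
property page per distinct normalised property title).  This formula is
asserted on random schemas.  Serialisation targets the MediaWiki export
namespace, version 0.10, with fixed revision metadata (timestamp,
contributor) so equal schemas produce byte-equal XML.  The test suite
validates emitted documents against a structural reconstruction of the
export-0.10 XML schema (`tests/data/export-0.10-synthetic.xsd`, written
for offline use and labelled synthetic; it mirrors the element
ordering and optionality of the published schema).

Drilldown filters are declared on the category page with the
parser-function form (`{{#drilldowninfo:filters=…}}`), listing every
categorical, three-valued, boolean and ranged property, grouped by the
schema's property groups.  The main page is template-driven
(`EmitOptions.main_page_template`) with an English/Italian string
catalog under `locales/`.

## Entity naming

Entities are titled with progressive numbers (`Patients 1`, …); records
of a connected category become subpages of their parent
(`Patients 1/Visits 2`), counted per parent.  This keeps titles unique
by construction and the one-to-many relation navigable; since the
wiki's own uniqueness constraint only signals conflicts, the importer
*refuses* collisions (including against a caller-supplied set of
pre-existing titles, for incremental imports via `start_index`).  The
join key in data TSVs is the reserved `!parent` column holding the
1-based row index into the companion parent table — a deliberate
choice to keep the data files self-contained and spreadsheet-editable.

## Chain resolution

A query from category *C* may reference a property owned by another
category.  The resolver runs breadth-first search over the connection
graph treated as bidirected — forward steps follow a connection
(child→parent), inverse steps go against it and render with the SMW
minus prefix — and returns the chain with the fewest steps.  Numeric
ties are broken deterministically: among equally short chains to a
single owning category the lexicographically smallest rendering wins;
two *different* categories at the same minimal distance are reported as
an error listing the candidates, because silently picking one would
change the query's meaning.  Correctness is checked against exhaustive
simple-path enumeration on every labelled connection forest with up to
six categories and on random multigraphs.

Comparator rendering uses SMW's value prefixes: `>`, `>=`, `<`, `<=`,
`~` (LIKE), nothing for equality.  `>=` is emitted as the two-character
form rather than adjusting the operand, which would be wrong for
non-integer values.  Ordered comparators are restricted to Number and
Date properties.

## Reference evaluator

`evaluate_ask` executes a query against an in-memory record set:
conditions with chains hold when at least one record reached along the
chain satisfies the comparator; a missing value never satisfies any
comparator; the three-valued `NA` is an ordinary value and `EQ "NA"`
selects exactly the records where it was recorded.  The evaluator is
deliberately naive (it scans records) — it exists as an executable
semantics for tests and the acceptance script, not as a query engine.

## Synthetic data

The generator's defaults describe a small demonstration registry:
50 subjects, 1–4 child records each, a 5 % missing-cell rate, dates
uniform over calendar year 2020 and coordinates uniform over an
Italy-sized bounding box (35–47° N, 6–19° E) — the scale and flavour of
a COVID surveillance demo.  All distributions are uniform within their
constraint; per-property sampler hooks allow richer demos.  Every
(category, property, row) triple gets its own random stream derived
from the root seed and the column identity (CRC-32 into a
`SeedSequence`), so adding a column or reordering rows never perturbs
other values, and identical `(schema, config)` yields byte-identical
TSV.

What the generator does *not* emulate: correlated variables, realistic
marginal distributions, informative missingness, free-text resembling
clinical notes, or duplicate/near-duplicate entities.  Tests passing on
generated data therefore demonstrate the pipeline's mechanics
(constraint satisfaction, round-trips, query agreement), not robustness
to the messiness of real clinical tables.

## Prolog export

Facts are ternary, with the property reified:
`fact(Subject, predicate, Object).` — one functor, fixed arity, triple
semantics; a per-property mode (`has_temperature('Patients 1', 38.5).`)
is available for convenience.  Predicates are derived from labels by
lowercasing, collapsing non-alphanumerics to underscores and prefixing
`p_` to a leading digit, with collisions rejected per schema.  Dates
export as `date(Y,M,D)` and coordinates as `coord(Lat,Lon)` compound
terms so they compare in the standard order of terms; atoms use ISO
quoting with doubled internal quotes.  Aspect pairs attached to complex
properties export as `property_aspect(pred, relation, 'value').`
clauses.  Loadability is tested with a small ground-term grammar in the
test suite rather than an embedded interpreter.

The default aspect vocabulary is `measure, exam, device, laterality,
organ, time` (configurable at parse time); it covers the decomposition
of long audiological property labels and is a package convention, not
part of the dialect grammar.

## Numerical and formatting choices

* Numbers render locale-free; integral floats drop the trailing `.0`;
  generated ranged numbers are rounded to 6 decimals (still inside the
  closed interval).
* Dates are ISO-8601 on input and output; no locale parsing.
* Wikitext metacharacters in values (`| { } = &`) are escaped with
  numeric character entities; `&` is escaped first so decoding is
  unambiguous, making encode/decode an exact inverse pair.
* Page-title normalisation strips MediaWiki-forbidden characters,
  collapses whitespace and uppercases the first letter; it is
  idempotent, and validation treats titles case-sensitively except for
  the first letter (as the wiki does).

## Problem sizes in tests

The acceptance checks run at the scale of the largest real schema the
tool targets (194 properties over two linked categories) and verify
chain resolution exhaustively over all ~20 000 labelled connection
forests on ≤ 6 categories (≈ 530 000 source/goal pairs) plus 200 random
multigraphs; synthetic-data checks use 50 random schemas at 5 parents
each, and round-trip checks 1000 sampled values.  These sizes keep the
whole suite under a minute on one CPU while exercising every code path
at realistic scale.

## Known limitations

* One parent connection per category; deeper nesting (children of
  children) is supported by the titling scheme but untested against any
  real site.
* The ASK subset covers conjunctive conditions and printouts — no
  disjunctions, subqueries or result formats.
* The XML dialect is pinned to export-0.10; other versions are out of
  scope.
* No live wiki interaction (import, API upload, permissions): the
  artifact ends at files a wiki can import.
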