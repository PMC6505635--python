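# Methods

## The metadata model and database dialect

The package operates on a relational snapshot of SRA metadata in the SRAdb
tradition: one SQLite table per archive object type — `submission`,
`study`, `sample`, `experiment`, `run` — plus a `metaInfo` table holding
provenance as `(name, value)` rows (`schema version`,
`creation timestamp`). The real public snapshot carries dozens of columns
per table; `srakit` defines a minimal documented dialect containing only
the columns its queries touch:

| table | required columns |
|---|---|
| submission | submission_accession, study_accession |
| study | study_accession, study_alias, study_title, study_abstract, study_description |
| sample | sample_accession, sample_alias, sample_attribute |
| experiment | experiment_accession, experiment_alias, study_accession, sample_accession, experiment_title, library_strategy |
| run | run_accession, experiment_accession, run_alias |
| metaInfo | name, value |

Validation on open checks table/column *presence by name* only, so the
full snapshot (a superset) opens unchanged; every missing element is
reported at once rather than the first one found. Missing or NULL text
fields surface as empty strings everywhere, keeping TSV column counts
stable. The default database location is `./SRAmetadb.sqlite`, matching
the upstream convention; `--db` overrides it.

Accessions are classified by grammar alone:
`(SR|ER|DR)(A|P|X|S|R)[0-9]+` (archive from the first letter, object kind
from the second), `GSE[0-9]+`, and `GSM[0-9]+(_[0-9]+)?`. Classification
is total and unambiguous on valid input and raises on anything else, so
malformed user input fails before the database is touched.

## Query semantics

`metadata` emits one row per run reachable from the requested studies via
the experiment join (experiment → run, experiment → sample). Output rows
are sorted lexicographically by
`(study_accession, experiment_accession, run_accession)`; because
accession numbering is zero-padded within a prefix, this matches numeric
order in practice and makes piped workflows byte-reproducible. Options
only ever *append* columns: `--assay` adds `library_strategy` as the
fifth column, `--desc` adds the raw `sample_attribute` string, and
`--expand` replaces that string with one column per attribute key. A
requested study absent from the database contributes zero rows plus a
stderr warning — partial results are more useful than a hard failure in
multi-project scripts.

`search` performs a case-insensitive **literal substring** match of one
phrase against six descriptive fields: study title, abstract and
description, experiment title, library strategy, and the raw
sample-attribute text. A run's row is returned when any field on its join
path matches; output shape and ordering are identical to `metadata`'s
base output, so search results can feed the same downstream pipes. One
layer of surrounding double quotes is stripped, so the conventional
shell-quoted `'"ribosome profiling"'` behaves as expected. Literal
matching (rather than tokenized full-text search) was chosen because it
is deterministic, dependency-free, and monotone: narrowing the phrase can
only shrink the result set. The cost is that no stemming or prefix
matching occurs — `profile` will not find `profiling`.

## Attribute normalization

`sample_attribute` strings are split on the literal two-character `||`
delimiter (surrounding whitespace optional; a lone `|` inside a value is
preserved), then each segment on its *first* `": "`, so values may
themselves contain colons (`depth: 30x`). Keys are trimmed, lowercased,
and internal whitespace runs become a single underscore; values are
trimmed, lowercased, with whitespace collapsed to single spaces. Both
sides are lowercased because that is how the expanded values are
conventionally consumed (grep/group-by on `pc3`, `polya rna`). Segments
without a separator are skipped with a warning; duplicate normalized keys
keep the first value. Parsing is total — any string yields a (possibly
empty) mapping — and `parse(serialize(parse(x))) == parse(x)` is enforced
as a property.

Expansion appends the union of keys over all rows in alphabetical order
after the surviving original columns, filling gaps with empty strings; a
key colliding with an existing column name (e.g. an attribute literally
called `run_accession`) is suffixed `_attr`. Row count is invariant under
expansion.

## GEO ↔ SRA conversion

Conversions are exact equality joins on the alias columns — no fuzzy
matching. `gse-to-srp` matches `study_alias`; `gse-to-gsm` lists the
aliased study's experiments sorted by experiment alias; `gsm-to-srr`
matches an experiment whose stored alias equals the query exactly *or*
equals the query plus an `_<digits>` suffix, reporting the stored
(suffixed) alias. The suffix rule reflects archive practice of
disambiguating resubmitted GEO samples (`GSM1020640_1`); anchoring the
pattern as `query(_digits)?$` guarantees a bare `GSM102` can never match
the distinct id `GSM1020640_1`. Composing `gse-to-gsm` with `gsm-to-srr`
provably covers the same (series, run) pairs as `metadata` restricted to
aliased studies; this is asserted on every test fixture.

## Downloads

Planning and transfer are separated. A plan resolves inputs — whole
studies, or exact runs from a piped TSV whose header names
`study_accession` and `run_accession` columns (any order, extra columns
ignored) — into entries `(study, experiment, run, url, dest)` with
destinations laid out as `<study>/<experiment>/<run>/<run>.sra`,
mirroring the archive hierarchy. Source URLs come from a configurable
template with `{run}`, `{run6}` (first six characters) and `{prefix3}`
placeholders, defaulting to the NCBI by-run mirror layout. Execution
injects a fetcher (tests use `file://` or in-memory fetchers; production
uses urllib streaming), skips any destination already present with
nonzero size — making re-execution idempotent without checksums, which
the archive does not publish per-run — and records per-run failures
without aborting the remaining entries.

## Fixture databases

Because the real snapshot is a multi-gigabyte download, all behavior is
exercised offline against generated databases.

`demo_records()` freezes a curated set around eight real public studies
(DRP003075, ERP013565, SRP010679, and the GEO-linked GSE24355, GSE25842,
GSE100007, GSE41637) with their true experiment/sample/run accessions,
GEO aliases and sample-attribute strings. Fields the package's outputs
never expose — titles, most abstracts, and a few unexported ids for the
GSE41637 panel — carry deterministic placeholders that are explicitly
synthetic and never contain the phrases the search tests use, so search
results on the fixture are exact. The two ribosome-profiling studies'
abstracts contain the phrase "ribosome profiling"; the demo `metaInfo`
mirrors the 2019-01-25 snapshot provenance (schema 1.0).

`random_records(params)` generates seeded record sets: studies with
NCBI/EBI/DDBJ prefixes, a configurable experiments-per-study and
runs-per-experiment range, a `geo_linked_fraction` of studies given GSE
aliases (their experiments receiving `_1`-suffixed GSM aliases), and
attribute strings composed from a key vocabulary. Defaults (10 studies,
1–4 experiments each, 1–3 runs, 50 % GEO-linked, five-key vocabulary)
are sized like a small multi-project query workload. The generator
emulates the *relational structure* of archive metadata, not its content:
abstracts are placeholder text, attribute values are drawn from a small
word list, and pathological real-world quirks (non-UTF8 bytes, aliases
shared across series, attribute keys containing `||`) are out of scope —
so passing tests demonstrate correctness of joins, normalization and
ordering, not robustness to every artifact of twenty years of archive
submissions.

## Verification strategy and sizes

Every query path is checked two ways: against frozen rows of the
demonstration database, and for row-set equality with naive in-memory
oracles (plain dictionary joins and substring scans sharing no code with
the SQL implementation) across 100 seeded random fixtures of 1–50
studies. Attribute parsing is property-tested (hypothesis) plus a
1000-string fixed-point sweep; schema validation is tested over all six
single-table-deletion mutants. These sizes keep the whole suite around
four seconds while covering the combinatorial space that matters
(archive prefixes, GEO linkage, empty attributes, multi-run experiments).

## Known limitations

* Only the columns in the dialect above are queryable; instrument,
  platform, taxonomy and file-level metadata present in the full snapshot
  are not exposed.
* Search is literal substring, not tokenized full-text; no ranking.
* Downloads are sequential, unverified by checksum, and FASTQ conversion
  is delegated to the SRA toolkit.
* The snapshot itself is produced upstream; this package consumes it and
  cannot refresh stale metadata beyond re-downloading the published file.
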