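# srakit

Command-line and Python toolkit for querying next-generation-sequencing
metadata from a local SRAdb-style SQLite snapshot of the NCBI Sequence Read
Archive (SRA), converting between GEO and SRA accessions, and organizing
raw-data downloads.

Re-analyzing public sequencing data usually starts with three chores:
finding relevant studies in SRA's metadata, mapping GEO identifiers
(GSE series, GSM samples) to the SRA accessions that actually hold the
reads, and downloading runs in a sane directory layout. `srakit` does all
three against a local SQLite database, so queries are fast, scriptable and
reproducible — no web scraping, no programming required.

## Data model

SRA tracks five linked object types, each with its own accession grammar
(first letter: `S`/`E`/`D` for NCBI/EBI/DDBJ):

| object     | accession | example     |
|------------|-----------|-------------|
| submission | SRA/ERA/DRA | SRA010679 |
| study (project) | SRP/ERP/DRP | SRP010679 |
| experiment | SRX/ERX/DRX | SRX118285 |
| sample     | SRS/ERS/DRS | SRS290854 |
| run        | SRR/ERR/DRR | SRR403882 |

A study owns experiments; each experiment was performed on one biological
sample and sequenced as one or more runs. GEO series ids (`GSE…`) are
stored as study aliases and GEO sample ids (`GSM…`, usually with an `_1`
suffix) as experiment aliases, which is what makes exact GEO↔SRA
conversion a join rather than a web lookup. Per-sample annotations live in
a semi-structured `sample_attribute` string
(`"key: value || key: value"`), which `srakit` can expand into proper
columns.

## Usage

All subcommands read the database named by `--db`
(default `./SRAmetadb.sqlite`), print a tab-separated table on stdout and
keep diagnostics on stderr, so they compose with `head`, `grep` and each
other. The full public snapshot can be fetched with `srakit srametadb`;
the examples below use the small bundled demonstration database:

```console
$ python -m srakit.fixtures SRAmetadb.sqlite
```

Find ribosome-profiling studies and list their runs:

```console
$ srakit search '"ribosome profiling"' | head -4
study_accession	experiment_accession	sample_accession	run_accession
DRP003075	DRX019536	DRS026974	DRR021383
DRP003075	DRX019537	DRS026982	DRR021384
DRP003075	DRX019538	DRS026979	DRR021385
```

Get a project's run table with sample annotations expanded into columns —
each row is one sequencing run, and the trailing columns are the
normalized attribute keys found across the project's samples:

```console
$ srakit metadata SRP010679 --desc --expand | head -3
study_accession	experiment_accession	sample_accession	run_accession	cell_line	sample_type	source_name	treatment
SRP010679	SRX118285	SRS290854	SRR403882	pc3	polya rna	pc3 human prostate cancer cells	vehicle
SRP010679	SRX118286	SRS290855	SRR403883	pc3	ribosome protected rna	pc3 human prostate cancer cells	vehicle
```

Convert GEO identifiers:

```console
$ srakit gse-to-srp GSE24355 GSE25842
study_alias	study_accession
GSE24355	SRP003870
GSE25842	SRP005378

$ srakit gse-to-gsm --desc --expand GSE41637 | head -3
study_alias	experiment_alias	source_name	strain	tissue
GSE41637	GSM1020640_1	mouse_brain	dba/2j	brain
GSE41637	GSM1020641_1	mouse_colon	dba/2j	colon

$ srakit gsm-to-srr GSM1020640 GSM1020646
experiment_alias	run_accession
GSM1020640_1	SRR594393
GSM1020646_1	SRR594399
```

Download runs — whole projects with `-p`, or exactly the runs of a
filtered metadata table piped on stdin. Files land in the archive's
`<study>/<experiment>/<run>/<run>.sra` hierarchy, and re-running skips
anything already present:

```console
$ srakit download -p SRP010679 --out-dir data/
$ srakit metadata SRP000941 --assay | grep -E 'study|RNA-Seq' | srakit download
```

The same operations are available as Python functions
(`srakit.metadata`, `srakit.search`, `srakit.gse_to_srp`, …), returning
`MetadataTable` objects convertible to pandas DataFrames.

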