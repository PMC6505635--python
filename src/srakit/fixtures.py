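"""Schema-conformant fixture databases for offline testing.

The real metadata snapshot is a multi-gigabyte download, so everything in
this package is exercised against small databases built here:

* :func:`demo_records` — a fixed record set around eight real public
  studies (ribosome-profiling projects DRP003075 and ERP013565, the PC3
  prostate-cancer polysome study SRP010679, and the GEO-linked series
  GSE24355, GSE25842, GSE100007 and GSE41637).  Accessions, aliases and
  sample annotations are the real archive values; fields the archive does
  not expose through this package's queries (titles, most abstracts, and a
  handful of unexported experiment/sample ids) are filled with clearly
  synthetic deterministic placeholders.
* :func:`random_records` — parameterized, seeded random record sets for
  property tests.
* :func:`build_db` — materialize any :class:`RecordSet` as a SQLite file
  openable by :func:`srakit.metadb.open_metadb`.

Run ``python -m srakit.fixtures out.sqlite`` to write the demo database to
disk.
"""

from __future__ import annotations

import random
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

from .errors import UsageError
from .metadb import (
    ExperimentRecord,
    MetaInfo,
    RecordSet,
    RunRecord,
    SampleRecord,
    StudyRecord,
    SubmissionRecord,
)

# (experiment, sample, run) triples of the two ribosome-profiling studies
_DRP003075_ROWS = [
    ("DRX019536", "DRS026974", "DRR021383"),
    ("DRX019537", "DRS026982", "DRR021384"),
    ("DRX019538", "DRS026979", "DRR021385"),
    ("DRX019540", "DRS026984", "DRR021387"),
    ("DRX019541", "DRS026978", "DRR021388"),
    ("DRX019543", "DRS026980", "DRR021390"),
    ("DRX019544", "DRS026981", "DRR021391"),
]
_ERP013565_ROWS = [("ERX1264364", "ERS1016056", "ERR1190989")]

# GSE100007 <-> SRP109126: experiment/sample ids with their shared GSM alias
_GSE100007_ROWS = [
    ("SRX2916198", "SRS2282390", "GSM2667747"),
    ("SRX2916199", "SRS2282391", "GSM2667748"),
    ("SRX2916200", "SRS2282392", "GSM2667749"),
    ("SRX2916201", "SRS2282393", "GSM2667750"),
    ("SRX2916202", "SRS2282394", "GSM2667751"),
    ("SRX2916203", "SRS2282395", "GSM2667752"),
    ("SRX2916204", "SRS2282396", "GSM2667753"),
    ("SRX2916205", "SRS2282397", "GSM2667754"),
    ("SRX2916206", "SRS2282400", "GSM2667755"),
]

# GSE41637 mouse tissue panel: (GSM alias, source_name, tissue); runs are
# known for the brain and skeletal-muscle samples.
_GSE41637_TISSUES = [
    ("GSM1020640_1", "mouse_brain", "brain"),
    ("GSM1020641_1", "mouse_colon", "colon"),
    ("GSM1020642_1", "mouse_heart", "heart"),
    ("GSM1020643_1", "mouse_kidney", "kidney"),
    ("GSM1020644_1", "mouse_liver", "liver"),
    ("GSM1020645_1", "mouse_lung", "lung"),
    ("GSM1020646_1", "mouse_skm", "skeletal muscle"),
    ("GSM1020647_1", "mouse_spleen", "spleen"),
    ("GSM1020648_1", "mouse_testes", "testes"),
]
_GSE41637_RUNS = {"GSM1020640_1": "SRR594393", "GSM1020646_1": "SRR594399"}
#: synthetic stand-in study accession for GSE41637 (the true SRP id is not
#: part of the fixture's frozen outputs, which only print the GSE alias)
_GSE41637_STUDY = "SRP041637"

_RIBO_ABSTRACT = (
    "Genome-wide ribosome profiling of translating messenger RNA "
    "(synthetic fixture abstract)."
)


def _placeholder(kind: str, accession: str) -> str:
    """Deterministic filler text; never contains fixture search phrases."""
    return f"synthetic {kind} for {accession}"


def _submission_for(study_accession: str) -> SubmissionRecord:
    # turn the object letter P into the submission letter A: SRP -> SRA
    return SubmissionRecord(study_accession[:2] + "A" + study_accession[3:], study_accession)


def demo_records() -> RecordSet:
    """The fixed demonstration record set; constant across calls."""
    studies: list[StudyRecord] = []
    samples: list[SampleRecord] = []
    experiments: list[ExperimentRecord] = []
    runs: list[RunRecord] = []

    def add_study(acc: str, alias: str = "", abstract: str = "") -> None:
        studies.append(
            StudyRecord(
                study_accession=acc,
                study_alias=alias,
                study_title=_placeholder("study title", acc),
                study_abstract=abstract or _placeholder("abstract", acc),
                study_description=_placeholder("description", acc),
            )
        )

    # -- ribosome-profiling studies ------------------------------------
    for study, rows in (("DRP003075", _DRP003075_ROWS), ("ERP013565", _ERP013565_ROWS)):
        add_study(study, abstract=_RIBO_ABSTRACT)
        for exp, sam, run in rows:
            samples.append(SampleRecord(sam, sample_alias=""))
            experiments.append(
                ExperimentRecord(
                    experiment_accession=exp,
                    study_accession=study,
                    sample_accession=sam,
                    experiment_title=_placeholder("experiment title", exp),
                    library_strategy="RNA-Seq",
                )
            )
            runs.append(RunRecord(run, exp))

    # -- PC3 prostate-cancer polysome study ----------------------------
    add_study("SRP010679")
    treatments = ["vehicle", "vehicle", "rapamycin", "rapamycin", "PP242", "PP242"]
    for i in range(12):
        exp = f"SRX{118285 + i}"
        sam = f"SRS{290854 + i}"
        run = f"SRR{403882 + i}"
        sample_type = "polyA RNA" if i % 2 == 0 else "ribosome protected RNA"
        attr = (
            "source_name: PC3 human prostate cancer cells || cell line: PC3 || "
            f"sample type: {sample_type} || treatment: {treatments[i % 6]}"
        )
        samples.append(SampleRecord(sam, sample_attribute=attr))
        experiments.append(
            ExperimentRecord(
                experiment_accession=exp,
                study_accession="SRP010679",
                sample_accession=sam,
                experiment_title=_placeholder("experiment title", exp),
                library_strategy="RNA-Seq",
            )
        )
        runs.append(RunRecord(run, exp))

    # -- GEO-aliased studies with no exported experiments --------------
    add_study("SRP003870", alias="GSE24355")
    add_study("SRP005378", alias="GSE25842")

    # -- GSE100007 (no sample annotations exported) --------------------
    add_study("SRP109126", alias="GSE100007")
    for exp, sam, gsm in _GSE100007_ROWS:
        samples.append(SampleRecord(sam, sample_alias=gsm))
        experiments.append(
            ExperimentRecord(
                experiment_accession=exp,
                experiment_alias=gsm,
                study_accession="SRP109126",
                sample_accession=sam,
                experiment_title=_placeholder("experiment title", exp),
                library_strategy="RNA-Seq",
            )
        )

    # -- GSE41637 mouse tissue panel ------------------------------------
    add_study(_GSE41637_STUDY, alias="GSE41637")
    for i, (gsm, source_name, tissue) in enumerate(_GSE41637_TISSUES):
        exp = f"SRX{1020640 + i}"  # synthetic stand-in experiment ids
        sam = f"SRS{1020640 + i}"  # synthetic stand-in sample ids
        attr = f"source_name: {source_name} || strain: DBA/2J || tissue: {tissue}"
        samples.append(SampleRecord(sam, sample_alias=gsm, sample_attribute=attr))
        experiments.append(
            ExperimentRecord(
                experiment_accession=exp,
                experiment_alias=gsm,
                study_accession=_GSE41637_STUDY,
                sample_accession=sam,
                experiment_title=_placeholder("experiment title", exp),
                library_strategy="RNA-Seq",
            )
        )
        if gsm in _GSE41637_RUNS:
            runs.append(RunRecord(_GSE41637_RUNS[gsm], exp))

    records = RecordSet(
        studies=studies,
        samples=samples,
        experiments=experiments,
        runs=runs,
        submissions=[_submission_for(s.study_accession) for s in studies],
        meta=MetaInfo("1.0", "2019-01-25 00:38:19"),
    )
    records.validate()
    return records


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

_DEFAULT_VOCABULARY = ("source_name", "cell_line", "tissue", "strain", "treatment")
_STRATEGIES = ("RNA-Seq", "ChIP-Seq", "Bisulfite-Seq", "WGS", "OTHER")
_VALUE_WORDS = (
    "liver", "brain", "heart", "control", "treated", "mouse", "human",
    "wild type", "mutant", "rep1", "rep2",
)
_ARCHIVE_PREFIXES = ("SR", "ER", "DR")


@dataclass(frozen=True)
class FixtureParams:
    """Parameters of a random record set; identical params+seed give
    logically identical output."""

    n_studies: int = 10
    experiments_per_study: tuple[int, int] = (1, 4)
    runs_per_experiment: tuple[int, int] = (1, 3)
    geo_linked_fraction: float = 0.5
    attribute_vocabulary: tuple[str, ...] = _DEFAULT_VOCABULARY
    seed: int = 0
    library_strategies: tuple[str, ...] = _STRATEGIES

    def validate(self) -> None:
        if self.n_studies < 0:
            raise UsageError(f"n_studies must be >= 0, got {self.n_studies}")
        for name, (lo, hi) in (
            ("experiments_per_study", self.experiments_per_study),
            ("runs_per_experiment", self.runs_per_experiment),
        ):
            if lo < 1 or hi < lo:
                raise UsageError(f"{name} must satisfy 1 <= lo <= hi, got ({lo}, {hi})")
        if not 0.0 <= self.geo_linked_fraction <= 1.0:
            raise UsageError(
                f"geo_linked_fraction must lie in [0, 1], got {self.geo_linked_fraction}"
            )
        if not self.library_strategies:
            raise UsageError("library_strategies must be non-empty")
        for key in self.attribute_vocabulary:
            if not key or not key.strip():
                raise UsageError("attribute_vocabulary keys must be non-empty")


def random_records(params: FixtureParams) -> RecordSet:
    """Generate a seeded random :class:`RecordSet` conforming to ``params``."""
    params.validate()
    rng = random.Random(params.seed)
    studies: list[StudyRecord] = []
    samples: list[SampleRecord] = []
    experiments: list[ExperimentRecord] = []
    runs: list[RunRecord] = []
    submissions: list[SubmissionRecord] = []

    n = params.n_studies
    n_geo = round(params.geo_linked_fraction * n)
    geo_linked = set(rng.sample(range(n), n_geo)) if n else set()

    # fixed-width sequential numbering keeps ids unique and lexicographic
    # order equal to generation order
    counters = {"study": 0, "experiment": 0, "sample": 0, "run": 0, "gsm": 0}

    def next_id(kind: str) -> int:
        counters[kind] += 1
        return 100000 + counters[kind]

    for i in range(n):
        prefix = rng.choice(_ARCHIVE_PREFIXES)
        study_acc = f"{prefix}P{next_id('study')}"
        alias = f"GSE{600000 + i}" if i in geo_linked else ""
        studies.append(
            StudyRecord(
                study_accession=study_acc,
                study_alias=alias,
                study_title=_placeholder("study title", study_acc),
                study_abstract=_placeholder("abstract", study_acc),
                study_description=_placeholder("description", study_acc),
            )
        )
        submissions.append(_submission_for(study_acc))
        for _ in range(rng.randint(*params.experiments_per_study)):
            exp_acc = f"{prefix}X{next_id('experiment')}"
            sam_acc = f"{prefix}S{next_id('sample')}"
            gsm = f"GSM{700000 + counters['gsm']}_1" if alias else ""
            if alias:
                counters["gsm"] += 1
            vocab = params.attribute_vocabulary
            n_keys = rng.randint(0, len(vocab))
            keys = [k for k in vocab if k in set(rng.sample(vocab, n_keys))]
            attr = " || ".join(f"{k}: {rng.choice(_VALUE_WORDS)}" for k in keys)
            samples.append(SampleRecord(sam_acc, sample_alias=gsm, sample_attribute=attr))
            experiments.append(
                ExperimentRecord(
                    experiment_accession=exp_acc,
                    experiment_alias=gsm,
                    study_accession=study_acc,
                    sample_accession=sam_acc,
                    experiment_title=_placeholder("experiment title", exp_acc),
                    library_strategy=rng.choice(params.library_strategies),
                )
            )
            for _ in range(rng.randint(*params.runs_per_experiment)):
                runs.append(RunRecord(f"{prefix}R{next_id('run')}", exp_acc))

    stamp = datetime(2019, 1, 25, 0, 38, 19) + timedelta(seconds=params.seed % 10**6)
    records = RecordSet(
        studies=studies,
        samples=samples,
        experiments=experiments,
        runs=runs,
        submissions=submissions,
        meta=MetaInfo("1.0", stamp.strftime("%Y-%m-%d %H:%M:%S")),
    )
    records.validate()
    return records


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------

_CREATE_SQL = """
CREATE TABLE submission (submission_accession TEXT, study_accession TEXT);
CREATE TABLE study (study_accession TEXT, study_alias TEXT, study_title TEXT,
                    study_abstract TEXT, study_description TEXT);
CREATE TABLE sample (sample_accession TEXT, sample_alias TEXT, sample_attribute TEXT);
CREATE TABLE experiment (experiment_accession TEXT, experiment_alias TEXT,
                         study_accession TEXT, sample_accession TEXT,
                         experiment_title TEXT, library_strategy TEXT);
CREATE TABLE run (run_accession TEXT, experiment_accession TEXT, run_alias TEXT);
CREATE TABLE metaInfo (name TEXT, value TEXT);
"""


def build_db(records: RecordSet, path: str | Path) -> Path:
    """Write ``records`` to a SQLite metadata database at ``path``.

    Validates referential integrity first; an existing file is replaced.
    """
    records.validate()
    path = Path(path)
    path.unlink(missing_ok=True)
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_CREATE_SQL)
        conn.executemany(
            "INSERT INTO submission VALUES (?, ?)",
            [(s.submission_accession, s.study_accession) for s in records.submissions],
        )
        conn.executemany(
            "INSERT INTO study VALUES (?, ?, ?, ?, ?)",
            [
                (s.study_accession, s.study_alias, s.study_title, s.study_abstract,
                 s.study_description)
                for s in records.studies
            ],
        )
        conn.executemany(
            "INSERT INTO sample VALUES (?, ?, ?)",
            [(s.sample_accession, s.sample_alias, s.sample_attribute) for s in records.samples],
        )
        conn.executemany(
            "INSERT INTO experiment VALUES (?, ?, ?, ?, ?, ?)",
            [
                (e.experiment_accession, e.experiment_alias, e.study_accession,
                 e.sample_accession, e.experiment_title, e.library_strategy)
                for e in records.experiments
            ],
        )
        conn.executemany(
            "INSERT INTO run VALUES (?, ?, ?)",
            [(r.run_accession, r.experiment_accession, r.run_alias) for r in records.runs],
        )
        conn.executemany(
            "INSERT INTO metaInfo VALUES (?, ?)",
            [
                ("schema version", records.meta.schema_version),
                ("creation timestamp", records.meta.creation_timestamp),
            ],
        )
        conn.commit()
    finally:
        conn.close()
    return path


def main(argv: list[str] | None = None) -> int:
    """Materialize a fixture database to disk (``python -m srakit.fixtures``)."""
    import argparse

    parser = argparse.ArgumentParser(
        prog="python -m srakit.fixtures",
        description="Write a demonstration or random fixture metadata database.",
    )
    parser.add_argument("out", help="output SQLite path")
    parser.add_argument("--random", action="store_true", help="random instead of demo records")
    parser.add_argument("--n-studies", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args(argv)
    if args.random:
        records = random_records(FixtureParams(n_studies=args.n_studies, seed=args.seed))
    else:
        records = demo_records()
    build_db(records, args.out)
    print(args.out)
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
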