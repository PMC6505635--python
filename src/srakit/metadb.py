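"""SRAdb-dialect metadata database: schema, records, and file handling.

The Sequence Read Archive (SRA) models a submission as five linked object
types — submission, study, sample, experiment and run — and the SRAdb
project distributes a periodically regenerated SQLite snapshot of all SRA
metadata with one relational table per object type.  This module defines:

* a typed :class:`Accession` covering the NCBI/EBI/DDBJ accession grammars
  (``SRP``/``ERP``/``DRP`` studies, ``SRX`` experiments, ``SRS`` samples,
  ``SRR`` runs, ``SRA`` submissions) plus the GEO series (``GSE``) and GEO
  sample (``GSM``) identifiers used as cross-database aliases;
* plain record types and a :class:`RecordSet` container that enforces
  uniqueness and referential integrity;
* :func:`open_metadb` / :func:`read_metainfo` / :func:`read_records` for
  validated, read-only access to a database file, and
  :func:`fetch_srametadb` for obtaining the published full snapshot.

The on-disk dialect is a minimal subset of the real ``SRAmetadb.sqlite``:
only the columns the query layer needs are required, and databases carrying
extra tables or columns (the multi-gigabyte public snapshot) open without
complaint because all access selects columns by name.
"""

from __future__ import annotations

import gzip
import logging
import re
import shutil
import sqlite3
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterator

from .errors import (
    AccessionError,
    DatabaseNotFoundError,
    IntegrityError,
    ProvenanceError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Primary public location of the gzip-compressed full metadata snapshot.
DEFAULT_SRAMETADB_URL = "https://s3.amazonaws.com/starbuck1/sradb/SRAmetadb.sqlite.gz"
#: Documented fallback mirror of the same snapshot.
FALLBACK_SRAMETADB_URL = "https://gbnci-abcc.ncifcrf.gov/backup/SRAmetadb.sqlite.gz"

#: Default database filename, assumed to live in the working directory.
DEFAULT_DB_NAME = "SRAmetadb.sqlite"


class AccessionKind(Enum):
    SUBMISSION = "submission"
    STUDY = "study"
    EXPERIMENT = "experiment"
    SAMPLE = "sample"
    RUN = "run"
    GEO_SERIES = "geo_series"
    GEO_SAMPLE = "geo_sample"


class Archive(Enum):
    NCBI = "ncbi"
    EBI = "ebi"
    DDBJ = "ddbj"
    GEO = "geo"


_SRA_RE = re.compile(r"^(SR|ER|DR)(A|P|X|S|R)[0-9]+$")
_GSE_RE = re.compile(r"^GSE[0-9]+$")
_GSM_RE = re.compile(r"^GSM[0-9]+(_[0-9]+)?$")

_ARCHIVE_BY_PREFIX = {"SR": Archive.NCBI, "ER": Archive.EBI, "DR": Archive.DDBJ}
_KIND_BY_LETTER = {
    "A": AccessionKind.SUBMISSION,
    "P": AccessionKind.STUDY,
    "X": AccessionKind.EXPERIMENT,
    "S": AccessionKind.SAMPLE,
    "R": AccessionKind.RUN,
}


@dataclass(frozen=True)
class Accession:
    """A typed archive identifier.

    The first two letters of an SRA-style accession name the issuing archive
    (``SR`` NCBI, ``ER`` EBI, ``DR`` DDBJ) and the third letter the object
    kind (``A`` submission, ``P`` study, ``X`` experiment, ``S`` sample,
    ``R`` run).  GEO series ids are ``GSE<digits>``; GEO sample ids are
    ``GSM<digits>`` optionally carrying an archive-side ``_<digits>``
    disambiguating suffix (``GSM1020640_1``).
    """

    text: str
    kind: AccessionKind
    archive: Archive

    @classmethod
    def parse(cls, text: str) -> "Accession":
        """Classify ``text``; raise :class:`AccessionError` if it matches no grammar."""
        m = _SRA_RE.match(text)
        if m:
            return cls(text, _KIND_BY_LETTER[m.group(2)], _ARCHIVE_BY_PREFIX[m.group(1)])
        if _GSE_RE.match(text):
            return cls(text, AccessionKind.GEO_SERIES, Archive.GEO)
        if _GSM_RE.match(text):
            return cls(text, AccessionKind.GEO_SAMPLE, Archive.GEO)
        raise AccessionError(f"unrecognized accession: {text!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def _require_kind(text: str, kind: AccessionKind) -> str:
    acc = Accession.parse(text)
    if acc.kind is not kind:
        raise AccessionError(f"{text!r} is a {acc.kind.value} accession, expected {kind.value}")
    return text


@dataclass(frozen=True)
class MetaInfo:
    """Database provenance: schema version and creation timestamp."""

    schema_version: str
    creation_timestamp: str

    def validate(self) -> None:
        if not self.schema_version:
            raise IntegrityError("schema_version must be non-empty")
        if not self.creation_timestamp:
            raise IntegrityError("creation_timestamp must be non-empty")
        try:
            datetime.strptime(self.creation_timestamp, "%Y-%m-%d %H:%M:%S")
        except ValueError as exc:
            raise IntegrityError(
                f"creation_timestamp {self.creation_timestamp!r} is not a "
                "'YYYY-MM-DD HH:MM:SS' datetime"
            ) from exc


@dataclass(frozen=True)
class StudyRecord:
    study_accession: str
    study_alias: str = ""
    study_title: str = ""
    study_abstract: str = ""
    study_description: str = ""


@dataclass(frozen=True)
class SampleRecord:
    sample_accession: str
    sample_alias: str = ""
    #: raw ``"key: value || key: value"`` annotation text, possibly empty
    sample_attribute: str = ""


@dataclass(frozen=True)
class ExperimentRecord:
    experiment_accession: str
    study_accession: str
    sample_accession: str
    experiment_alias: str = ""
    experiment_title: str = ""
    library_strategy: str = ""


@dataclass(frozen=True)
class RunRecord:
    run_accession: str
    experiment_accession: str
    run_alias: str = ""


@dataclass(frozen=True)
class SubmissionRecord:
    submission_accession: str
    study_accession: str = ""


@dataclass
class RecordSet:
    """An in-memory metadata collection honoring referential integrity.

    Equality of two record sets is *logical*: same records regardless of
    ordering (see :meth:`logically_equal`).
    """

    studies: list[StudyRecord] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)
    experiments: list[ExperimentRecord] = field(default_factory=list)
    runs: list[RunRecord] = field(default_factory=list)
    submissions: list[SubmissionRecord] = field(default_factory=list)
    meta: MetaInfo = MetaInfo("1.0", "2019-01-25 00:38:19")

    def validate(self) -> None:
        """Raise :class:`IntegrityError` naming the first offending accession."""
        self.meta.validate()

        def check_unique(values: list[str], what: str) -> set[str]:
            seen: set[str] = set()
            for v in values:
                if v in seen:
                    raise IntegrityError(f"duplicate {what} accession: {v}")
                seen.add(v)
            return seen

        study_ids = check_unique([s.study_accession for s in self.studies], "study")
        sample_ids = check_unique([s.sample_accession for s in self.samples], "sample")
        exp_ids = check_unique([e.experiment_accession for e in self.experiments], "experiment")
        check_unique([r.run_accession for r in self.runs], "run")
        check_unique([s.submission_accession for s in self.submissions], "submission")

        for s in self.studies:
            _require_kind(s.study_accession, AccessionKind.STUDY)
        for s in self.samples:
            _require_kind(s.sample_accession, AccessionKind.SAMPLE)
        for e in self.experiments:
            _require_kind(e.experiment_accession, AccessionKind.EXPERIMENT)
            if e.study_accession not in study_ids:
                raise IntegrityError(
                    f"experiment {e.experiment_accession} references missing study "
                    f"{e.study_accession}"
                )
            if e.sample_accession not in sample_ids:
                raise IntegrityError(
                    f"experiment {e.experiment_accession} references missing sample "
                    f"{e.sample_accession}"
                )
        for r in self.runs:
            _require_kind(r.run_accession, AccessionKind.RUN)
            if r.experiment_accession not in exp_ids:
                raise IntegrityError(
                    f"run {r.run_accession} references missing experiment "
                    f"{r.experiment_accession}"
                )
        for sub in self.submissions:
            _require_kind(sub.submission_accession, AccessionKind.SUBMISSION)
            if sub.study_accession and sub.study_accession not in study_ids:
                raise IntegrityError(
                    f"submission {sub.submission_accession} references missing study "
                    f"{sub.study_accession}"
                )

    def _canonical(self):
        return (
            sorted(self.studies, key=lambda r: r.study_accession),
            sorted(self.samples, key=lambda r: r.sample_accession),
            sorted(self.experiments, key=lambda r: r.experiment_accession),
            sorted(self.runs, key=lambda r: r.run_accession),
            sorted(self.submissions, key=lambda r: r.submission_accession),
            self.meta,
        )

    def logically_equal(self, other: "RecordSet") -> bool:
        """Field-by-field equality, insensitive to record ordering."""
        return self._canonical() == other._canonical()


# ---------------------------------------------------------------------------
# On-disk schema
# ---------------------------------------------------------------------------

#: Required tables and the columns the query layer relies on.  Extra tables
#: and columns are tolerated; the full public snapshot carries dozens of both.
REQUIRED_SCHEMA: dict[str, tuple[str, ...]] = {
    "submission": ("submission_accession", "study_accession"),
    "study": (
        "study_accession",
        "study_alias",
        "study_title",
        "study_abstract",
        "study_description",
    ),
    "sample": ("sample_accession", "sample_alias", "sample_attribute"),
    "experiment": (
        "experiment_accession",
        "experiment_alias",
        "study_accession",
        "sample_accession",
        "experiment_title",
        "library_strategy",
    ),
    "run": ("run_accession", "experiment_accession", "run_alias"),
    "metaInfo": ("name", "value"),
}


@dataclass
class MetaDBHandle:
    """A validated, read-only handle on a metadata database file."""

    path: Path
    meta: MetaInfo

    def connect(self) -> sqlite3.Connection:
        """Open a fresh read-only connection to the underlying file."""
        uri = f"file:{self.path}?mode=ro"
        return sqlite3.connect(uri, uri=True)


def _table_columns(conn: sqlite3.Connection) -> dict[str, set[str]]:
    tables = {
        row[0]
        for row in conn.execute(
            "SELECT name FROM sqlite_master WHERE type IN ('table', 'view')"
        )
    }
    out: dict[str, set[str]] = {}
    for t in tables:
        cols = {row[1] for row in conn.execute(f'PRAGMA table_info("{t}")')}
        out[t] = cols
    return out


def _read_metainfo_rows(conn: sqlite3.Connection) -> MetaInfo:
    rows = dict(conn.execute('SELECT name, value FROM "metaInfo"'))
    if not rows:
        raise ProvenanceError("database provenance missing: metaInfo table is empty")
    version = rows.get("schema version", "")
    stamp = rows.get("creation timestamp", "")
    if not version or not stamp:
        raise ProvenanceError(
            "database provenance missing: metaInfo lacks 'schema version' or "
            "'creation timestamp'"
        )
    return MetaInfo(str(version), str(stamp))


def open_metadb(path: str | Path) -> MetaDBHandle:
    """Open and validate a metadata database file.

    Validation checks only that the six required tables exist and carry the
    required columns, by name and order-independently, so supersets such as
    the real public snapshot open successfully.

    Raises
    ------
    DatabaseNotFoundError
        If no file exists at ``path``.
    SchemaError
        Listing *every* missing table and column, if any.
    """
    path = Path(path)
    if not path.is_file():
        raise DatabaseNotFoundError(f"database not found: {path}")
    uri = f"file:{path}?mode=ro"
    conn = sqlite3.connect(uri, uri=True)
    try:
        try:
            present = _table_columns(conn)
        except sqlite3.DatabaseError as exc:
            raise SchemaError(f"{path} is not a SQLite database: {exc}") from exc
        violations: list[str] = []
        for table, columns in REQUIRED_SCHEMA.items():
            if table not in present:
                violations.append(f"missing table: {table}")
                continue
            for col in columns:
                if col not in present[table]:
                    violations.append(f"missing column: {table}.{col}")
        if violations:
            raise SchemaError(
                f"{path} does not match the metadata schema: " + "; ".join(violations)
            )
        meta = _read_metainfo_rows(conn)
    finally:
        conn.close()
    return MetaDBHandle(path=path, meta=meta)


def read_metainfo(handle: MetaDBHandle) -> MetaInfo:
    """Return the stored schema version and creation timestamp, verbatim."""
    with handle.connect() as conn:
        return _read_metainfo_rows(conn)


def read_records(handle: MetaDBHandle) -> RecordSet:
    """Materialize every row of the five object tables into a :class:`RecordSet`.

    Intended for fixtures and round-trip checks; the full public snapshot is
    far too large for this and is queried through :mod:`srakit.queries`
    instead.
    """

    def txt(v) -> str:
        return "" if v is None else str(v)

    with handle.connect() as conn:
        studies = [
            StudyRecord(*(txt(v) for v in row))
            for row in conn.execute(
                "SELECT study_accession, study_alias, study_title, study_abstract,"
                " study_description FROM study"
            )
        ]
        samples = [
            SampleRecord(*(txt(v) for v in row))
            for row in conn.execute(
                "SELECT sample_accession, sample_alias, sample_attribute FROM sample"
            )
        ]
        experiments = [
            ExperimentRecord(
                experiment_accession=txt(row[0]),
                experiment_alias=txt(row[1]),
                study_accession=txt(row[2]),
                sample_accession=txt(row[3]),
                experiment_title=txt(row[4]),
                library_strategy=txt(row[5]),
            )
            for row in conn.execute(
                "SELECT experiment_accession, experiment_alias, study_accession,"
                " sample_accession, experiment_title, library_strategy FROM experiment"
            )
        ]
        runs = [
            RunRecord(*(txt(v) for v in row))
            for row in conn.execute(
                "SELECT run_accession, experiment_accession, run_alias FROM run"
            )
        ]
        submissions = [
            SubmissionRecord(*(txt(v) for v in row))
            for row in conn.execute(
                "SELECT submission_accession, study_accession FROM submission"
            )
        ]
    return RecordSet(
        studies=studies,
        samples=samples,
        experiments=experiments,
        runs=runs,
        submissions=submissions,
        meta=read_metainfo(handle),
    )


# ---------------------------------------------------------------------------
# Snapshot download
# ---------------------------------------------------------------------------


def _stream_copy(response, out_fh, progress=None, chunk_size: int = 1 << 20) -> None:
    while True:
        chunk = response.read(chunk_size)
        if not chunk:
            break
        out_fh.write(chunk)
        if progress is not None:
            progress(len(chunk))


def fetch_srametadb(
    url: str = DEFAULT_SRAMETADB_URL,
    dest_dir: str | Path = ".",
    overwrite: bool = False,
    progress: bool = True,
) -> Path:
    """Download and decompress the gzip-compressed metadata snapshot.

    ``file://`` URLs are supported so the transfer path is testable offline.
    The decompressed file is validated with :func:`open_metadb` before the
    path is returned.

    Raises
    ------
    DownloadError
        If the destination exists and ``overwrite`` is unset, or on any
        network / IO failure (with the URL in the message).
    SchemaError
        If the decompressed file fails schema validation.
    """
    from .errors import DownloadError

    dest_dir = Path(dest_dir)
    dest = dest_dir / DEFAULT_DB_NAME
    if dest.exists() and not overwrite:
        raise DownloadError(
            f"destination exists: {dest} (pass overwrite to replace it)"
        )
    tmp_gz = dest.with_suffix(dest.suffix + ".gz.part")
    try:
        with urllib.request.urlopen(url) as response:
            total = response.headers.get("Content-Length")
            bar = None
            if progress:
                try:
                    from tqdm import tqdm

                    bar = tqdm(
                        total=int(total) if total else None,
                        unit="B",
                        unit_scale=True,
                        desc=dest.name,
                        disable=None,  # auto-disable when stderr is not a tty
                    )
                except ImportError:  # pragma: no cover
                    bar = None
            with open(tmp_gz, "wb") as fh:
                _stream_copy(response, fh, bar.update if bar else None)
            if bar:
                bar.close()
        with gzip.open(tmp_gz, "rb") as gz, open(dest, "wb") as out:
            shutil.copyfileobj(gz, out)
    except OSError as exc:
        raise DownloadError(f"failed to fetch {url}: {exc}") from exc
    finally:
        tmp_gz.unlink(missing_ok=True)
    open_metadb(dest)  # raises SchemaError if the payload is not a valid db
    logger.info("fetched %s -> %s", url, dest)
    return dest
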