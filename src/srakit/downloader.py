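"""Raw-data download planning and execution.

Archived runs are laid out on disk following the SRA hierarchy — each
project (``SRP``) owns experiments (``SRX``) which own runs (``SRR``) — so
a run lands at ``<study>/<experiment>/<run>/<run>.sra`` under the chosen
output root.  Planning is separated from execution: :func:`plan_downloads`
resolves accessions to ``(study, experiment, run, url, dest)`` entries
using the metadata database, and :func:`execute_plan` performs transfers
through an injected fetcher, skipping destinations that already exist with
nonzero size so re-running a plan is idempotent.

Pipe mode: the tool's TSV metadata output can be filtered with ordinary
Unix tools and fed back on standard input; :func:`parse_pipe_table` reads
such a table, locating the ``study_accession`` and ``run_accession``
columns by header name.
"""

from __future__ import annotations

import logging
import os
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Callable, Iterable, NamedTuple

from .errors import DownloadError, UsageError
from .metadb import Accession, AccessionKind, MetaDBHandle

logger = logging.getLogger(__name__)

#: Default per-run source layout (NCBI by-run mirror structure).  The
#: placeholders are the run accession, its first six characters and its
#: three-letter prefix.
DEFAULT_URL_TEMPLATE = (
    "ftp://ftp-trace.ncbi.nlm.nih.gov/sra/sra-instant/reads/ByRun/sra/"
    "{prefix3}/{run6}/{run}/{run}.sra"
)


class PipeRow(NamedTuple):
    study_accession: str
    run_accession: str


@dataclass(frozen=True)
class DownloadEntry:
    study: str
    experiment: str
    run: str
    source_url: str
    #: destination relative to the plan root: study/experiment/run/run.sra
    dest_path: str


@dataclass
class DownloadPlan:
    root: Path
    entries: list[DownloadEntry] = field(default_factory=list)


@dataclass
class DownloadReport:
    fetched: int = 0
    skipped: int = 0
    failed: list[tuple[str, str]] = field(default_factory=list)


def parse_pipe_table(text: str) -> list[PipeRow]:
    """Parse a TSV table whose header names the accession columns.

    The header must contain ``study_accession`` and ``run_accession`` (any
    order; extra columns are ignored).  Blank lines are skipped; a
    malformed accession raises with its line number.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise UsageError("pipe input is empty: expected a TSV header line")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in ("study_accession", "run_accession") if c not in header]
    if missing:
        raise UsageError(
            "pipe input header is missing required column(s): " + ", ".join(missing)
        )
    i_study = header.index("study_accession")
    i_run = header.index("run_accession")
    out: list[PipeRow] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= max(i_study, i_run):
            raise UsageError(f"line {lineno}: expected at least {len(header)} fields")
        study, run = fields[i_study], fields[i_run]
        for text_, kind in ((study, AccessionKind.STUDY), (run, AccessionKind.RUN)):
            try:
                acc = Accession.parse(text_)
            except UsageError as exc:
                raise UsageError(f"line {lineno}: {exc}") from exc
            if acc.kind is not kind:
                raise UsageError(
                    f"line {lineno}: {text_!r} is not a {kind.value} accession"
                )
        out.append(PipeRow(study, run))
    return out


def resolve_url(template: str, run: str) -> str:
    return template.format(run=run, run6=run[:6], prefix3=run[:3])


def _dest_for(study: str, experiment: str, run: str) -> str:
    return str(PurePosixPath(study) / experiment / run / f"{run}.sra")


def plan_downloads(
    handle: MetaDBHandle,
    inputs: Iterable[str] | Iterable[PipeRow],
    root: str | Path = ".",
    url_template: str = DEFAULT_URL_TEMPLATE,
) -> DownloadPlan:
    """Resolve studies or piped rows into a concrete download plan.

    Study accessions expand to every run of the study; :class:`PipeRow`
    inputs select exactly the listed runs (a run absent from the database
    is an error naming it).  Entries are unique by run and sorted by
    ``(study, experiment, run)``.
    """
    for ph in ("{run}", "{run6}", "{prefix3}"):
        if ph not in url_template:
            raise UsageError(f"url template must contain the {ph} placeholder")
    inputs = list(inputs)
    entries: dict[str, DownloadEntry] = {}
    with handle.connect() as conn:
        if inputs and isinstance(inputs[0], PipeRow):
            run_map = {
                row[0]: (row[1], row[2])
                for row in conn.execute(
                    "SELECT r.run_accession, e.study_accession, e.experiment_accession"
                    " FROM run r JOIN experiment e"
                    " ON e.experiment_accession = r.experiment_accession"
                )
            }
            for pipe_row in inputs:
                if pipe_row.run_accession not in run_map:
                    raise DownloadError(
                        f"run {pipe_row.run_accession} not found in database"
                    )
                study, experiment = run_map[pipe_row.run_accession]
                run = pipe_row.run_accession
                entries.setdefault(
                    run,
                    DownloadEntry(
                        study, experiment, run,
                        resolve_url(url_template, run), _dest_for(study, experiment, run),
                    ),
                )
        else:
            studies = [str(s) for s in inputs]
            for text in studies:
                acc = Accession.parse(text)
                if acc.kind is not AccessionKind.STUDY:
                    raise UsageError(f"{text!r} is not a study accession")
            placeholders = ",".join("?" for _ in studies) or "''"
            for study, experiment, run in conn.execute(
                "SELECT e.study_accession, e.experiment_accession, r.run_accession"
                " FROM experiment e JOIN run r"
                " ON r.experiment_accession = e.experiment_accession"
                f" WHERE e.study_accession IN ({placeholders})",
                studies,
            ):
                entries.setdefault(
                    run,
                    DownloadEntry(
                        study, experiment, run,
                        resolve_url(url_template, run), _dest_for(study, experiment, run),
                    ),
                )
    ordered = sorted(entries.values(), key=lambda e: (e.study, e.experiment, e.run))
    return DownloadPlan(root=Path(root), entries=ordered)


def url_fetcher(url: str) -> bytes:
    """Production fetcher: read a URL (http/ftp/file) fully into memory."""
    try:
        with urllib.request.urlopen(url) as response:
            return response.read()
    except OSError as exc:
        raise DownloadError(f"failed to fetch {url}: {exc}") from exc


def execute_plan(
    plan: DownloadPlan,
    fetcher: Callable[[str], bytes] = url_fetcher,
    progress: Callable[[DownloadEntry, str], None] | None = None,
) -> DownloadReport:
    """Execute a plan, skipping existing nonzero-size destinations.

    Per-entry failures are recorded without aborting the remaining
    entries; the progress callback is invoked once per entry with the
    outcome (``"fetched"``, ``"skipped"`` or ``"failed"``).  An unwritable
    root aborts before any transfer.
    """
    root = plan.root
    try:
        root.mkdir(parents=True, exist_ok=True)
        if not os.access(root, os.W_OK):
            raise PermissionError(f"not writable: {root}")
    except OSError as exc:
        raise DownloadError(f"output root {root} is not writable: {exc}") from exc

    report = DownloadReport()
    for entry in plan.entries:
        dest = root / entry.dest_path
        if dest.exists() and dest.stat().st_size > 0:
            report.skipped += 1
            status = "skipped"
        else:
            try:
                data = fetcher(entry.source_url)
                dest.parent.mkdir(parents=True, exist_ok=True)
                dest.write_bytes(data)
                report.fetched += 1
                status = "fetched"
            except Exception as exc:  # noqa: BLE001 - per-run fault isolation
                logger.warning("download failed for %s: %s", entry.run, exc)
                report.failed.append((entry.run, str(exc)))
                status = "failed"
        if progress is not None:
            progress(entry, status)
    return report
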