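"""Project-metadata retrieval and free-text search.

A study (project) owns experiments; each experiment was performed on one
biological sample and sequenced as one or more runs.  ``metadata`` walks
that hierarchy — one output row per run — and ``search`` returns the same
shape restricted to records whose descriptive fields contain a phrase.

Both return a :class:`~srakit.table.MetadataTable` with the canonical
column order ``study_accession, experiment_accession, sample_accession,
run_accession`` and rows sorted lexicographically by
``(study_accession, experiment_accession, run_accession)`` so piped
workflows are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import attributes
from .errors import UsageError
from .metadb import Accession, AccessionKind, MetaDBHandle
from .table import MetadataTable

logger = logging.getLogger(__name__)

BASE_COLUMNS = (
    "study_accession",
    "experiment_accession",
    "sample_accession",
    "run_accession",
)

#: descriptive fields scanned by :func:`search`
SEARCH_FIELDS = (
    "st.study_title",
    "st.study_abstract",
    "st.study_description",
    "e.experiment_title",
    "e.library_strategy",
    "s.sample_attribute",
)


@dataclass
class QueryOptions:
    """Output options for :func:`metadata`.

    ``expand`` implies ``desc`` (attribute columns are derived from the
    ``sample_attribute`` text), so requesting ``expand`` auto-enables
    ``desc``.
    """

    desc: bool = False
    expand: bool = False
    assay: bool = False

    def __post_init__(self) -> None:
        if self.expand:
            self.desc = True


def _validate_studies(studies: list[str]) -> list[str]:
    if not studies:
        raise UsageError("at least one study accession is required")
    for text in studies:
        acc = Accession.parse(text)  # raises AccessionError (a UsageError)
        if acc.kind is not AccessionKind.STUDY:
            raise UsageError(
                f"{text!r} is not a study accession (expected SRP/ERP/DRP prefix)"
            )
    return studies


_RUN_JOIN_SQL = """
SELECT e.study_accession, e.experiment_accession, e.sample_accession,
       r.run_accession,
       COALESCE(e.library_strategy, '') AS library_strategy,
       COALESCE(s.sample_attribute, '') AS sample_attribute
FROM experiment e
JOIN run r ON r.experiment_accession = e.experiment_accession
LEFT JOIN sample s ON s.sample_accession = e.sample_accession
JOIN study st ON st.study_accession = e.study_accession
"""


def _finish(rows, options: QueryOptions) -> MetadataTable:
    rows = sorted(rows, key=lambda row: (row[0], row[1], row[3]))
    columns = list(BASE_COLUMNS)
    width = 4
    if options.assay:
        columns.append("library_strategy")
    if options.desc:
        columns.append("sample_attribute")
    picked = []
    for row in rows:
        out = list(row[:width])
        if options.assay:
            out.append(row[4])
        if options.desc:
            out.append(row[5])
        picked.append(out)
    table = MetadataTable.build(columns, picked)
    if options.expand:
        table = attributes.expand_table(table, "sample_attribute")
    return table


def metadata(
    handle: MetaDBHandle,
    studies: list[str],
    options: QueryOptions | None = None,
) -> MetadataTable:
    """All experiment, sample and run accessions of the given studies.

    One row per run reachable from the listed studies.  ``options.assay``
    appends the ``library_strategy`` column; ``options.desc`` appends the
    raw ``sample_attribute`` string; ``options.expand`` replaces it with one
    column per attribute key.  Studies absent from the database contribute
    zero rows and a logged warning.
    """
    options = options or QueryOptions()
    _validate_studies(studies)
    placeholders = ",".join("?" for _ in studies)
    with handle.connect() as conn:
        known = {
            row[0]
            for row in conn.execute(
                f"SELECT study_accession FROM study WHERE study_accession IN ({placeholders})",
                studies,
            )
        }
        for text in studies:
            if text not in known:
                logger.warning("study %s not found in database", text)
        rows = conn.execute(
            _RUN_JOIN_SQL + f"WHERE e.study_accession IN ({placeholders})", studies
        ).fetchall()
    return _finish(rows, options)


def search(handle: MetaDBHandle, phrase: str) -> MetadataTable:
    """Case-insensitive literal substring search over descriptive fields.

    The phrase is matched against study title/abstract/description,
    experiment title, library strategy and the raw sample-attribute text;
    a run's row is returned when any field on its join path matches.  One
    layer of surrounding double quotes is stripped, so a shell-quoted
    ``'"ribosome profiling"'`` argument behaves as expected.
    """
    phrase = phrase.strip()
    if len(phrase) >= 2 and phrase[0] == '"' and phrase[-1] == '"':
        phrase = phrase[1:-1]
    if not phrase:
        raise UsageError("search phrase must be non-empty")
    needle = phrase.lower()
    predicate = " OR ".join(
        f"instr(lower(COALESCE({f}, '')), ?) > 0" for f in SEARCH_FIELDS
    )
    with handle.connect() as conn:
        rows = conn.execute(
            _RUN_JOIN_SQL + f"WHERE {predicate}", [needle] * len(SEARCH_FIELDS)
        ).fetchall()
    return _finish(rows, QueryOptions())
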