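"""GEO ↔ SRA accession interconversion.

Sequence-based GEO submissions are mirrored in SRA: the GEO series id
(``GSE``) is stored as the SRA study's alias, and each GEO sample id
(``GSM``) as an experiment alias, usually with an archive-side ``_1``
suffix.  The converters here are exact joins on those alias columns:

* :func:`gse_to_srp` — series → study accession (optionally per-experiment
  detail);
* :func:`gse_to_gsm` — series → its GEO experiment list (optionally with
  sample annotations);
* :func:`gsm_to_srr` — GEO experiment → sequencing runs, where a bare
  ``GSM123`` query also matches the stored suffixed alias ``GSM123_1`` (but
  never a different numeric id).
"""

from __future__ import annotations

import logging
import re

from . import attributes
from .errors import UsageError
from .metadb import Accession, AccessionKind, MetaDBHandle
from .table import MetadataTable

logger = logging.getLogger(__name__)


def classify_accession(text: str) -> Accession:
    """Classify an accession string; raises on unrecognized input."""
    return Accession.parse(text)


def _validate(texts: list[str], kind: AccessionKind, label: str) -> None:
    if not texts:
        raise UsageError(f"at least one {label} accession is required")
    for text in texts:
        acc = Accession.parse(text)
        if acc.kind is not kind:
            raise UsageError(f"{text!r} is not a {label} accession")


_DETAIL_SQL = """
SELECT st.study_alias, st.study_accession, e.experiment_accession,
       e.sample_accession, COALESCE(e.experiment_alias, ''),
       COALESCE(s.sample_alias, ''), COALESCE(s.sample_attribute, '')
FROM study st
JOIN experiment e ON e.study_accession = st.study_accession
LEFT JOIN sample s ON s.sample_accession = e.sample_accession
"""


def gse_to_srp(
    handle: MetaDBHandle,
    gses: list[str],
    detailed: bool = False,
    expand: bool = False,
) -> MetadataTable:
    """Convert GEO series ids to SRA study accessions via the study alias.

    Base output is ``(study_alias, study_accession)``, one row per matched
    study.  ``detailed`` adds per-experiment columns (experiment/sample
    accessions and aliases); ``expand`` additionally expands sample
    annotations into columns when any are present (and implies
    ``detailed``).  Unknown series contribute zero rows and a warning.
    """
    _validate(gses, AccessionKind.GEO_SERIES, "GSE")
    if expand:
        detailed = True
    placeholders = ",".join("?" for _ in gses)
    with handle.connect() as conn:
        known = {
            row[0]
            for row in conn.execute(
                f"SELECT study_alias FROM study WHERE study_alias IN ({placeholders})", gses
            )
        }
        for gse in gses:
            if gse not in known:
                logger.warning("series %s has no aliased study in database", gse)
        if not detailed:
            rows = conn.execute(
                "SELECT study_alias, study_accession FROM study"
                f" WHERE study_alias IN ({placeholders}) ORDER BY study_alias",
                gses,
            ).fetchall()
            return MetadataTable.build(("study_alias", "study_accession"), rows)
        rows = conn.execute(
            _DETAIL_SQL + f"WHERE st.study_alias IN ({placeholders})", gses
        ).fetchall()
    rows.sort(key=lambda row: (row[0], row[2]))
    columns = (
        "study_alias",
        "study_accession",
        "experiment_accession",
        "sample_accession",
        "experiment_alias",
        "sample_alias",
    )
    if not expand:
        return MetadataTable.build(columns, [row[:6] for row in rows])
    table = MetadataTable.build(columns + ("sample_attribute",), rows)
    return attributes.expand_table(table, "sample_attribute")


def gse_to_gsm(
    handle: MetaDBHandle,
    gses: list[str],
    desc: bool = False,
    expand: bool = False,
) -> MetadataTable:
    """List the GEO experiments (GSM aliases) of GEO series.

    One row per experiment of each aliased study, sorted by experiment
    alias.  ``desc`` appends the raw ``sample_attribute`` string through
    the experiment → sample join; ``expand`` replaces it with one column
    per attribute key (and implies ``desc``).
    """
    _validate(gses, AccessionKind.GEO_SERIES, "GSE")
    if expand:
        desc = True
    placeholders = ",".join("?" for _ in gses)
    with handle.connect() as conn:
        known = {
            row[0]
            for row in conn.execute(
                f"SELECT study_alias FROM study WHERE study_alias IN ({placeholders})", gses
            )
        }
        for gse in gses:
            if gse not in known:
                logger.warning("series %s has no aliased study in database", gse)
        rows = conn.execute(
            "SELECT st.study_alias, COALESCE(e.experiment_alias, ''),"
            "       COALESCE(s.sample_attribute, '')"
            " FROM study st"
            " JOIN experiment e ON e.study_accession = st.study_accession"
            " LEFT JOIN sample s ON s.sample_accession = e.sample_accession"
            f" WHERE st.study_alias IN ({placeholders})",
            gses,
        ).fetchall()
    rows.sort(key=lambda row: (row[1], row[0]))
    if not desc:
        return MetadataTable.build(("study_alias", "experiment_alias"), [r[:2] for r in rows])
    table = MetadataTable.build(("study_alias", "experiment_alias", "sample_attribute"), rows)
    if expand:
        table = attributes.expand_table(table, "sample_attribute")
    return table


def gsm_to_srr(handle: MetaDBHandle, gsms: list[str]) -> MetadataTable:
    """Map GEO experiment ids to SRA run accessions.

    An experiment matches when its stored alias equals the query exactly or
    equals the query plus an ``_<digits>`` suffix; the output reports the
    stored (suffixed) alias.  One row per run, sorted by
    ``(experiment_alias, run_accession)``.
    """
    _validate(gsms, AccessionKind.GEO_SAMPLE, "GSM")
    patterns = [
        re.compile(re.escape(q) + r"(_[0-9]+)?\Z") for q in gsms
    ]
    with handle.connect() as conn:
        rows = conn.execute(
            "SELECT COALESCE(e.experiment_alias, ''), r.run_accession"
            " FROM experiment e"
            " JOIN run r ON r.experiment_accession = e.experiment_accession"
            " WHERE e.experiment_alias IS NOT NULL AND e.experiment_alias != ''"
        ).fetchall()
    matched = [row for row in rows if any(p.fullmatch(row[0]) for p in patterns)]
    hit_queries = {
        q for q, p in zip(gsms, patterns) if any(p.fullmatch(row[0]) for row in rows)
    }
    for q in gsms:
        if q not in hit_queries:
            logger.warning("GSM %s matches no experiment alias in database", q)
    matched.sort(key=lambda row: (row[0], row[1]))
    return MetadataTable.build(("experiment_alias", "run_accession"), matched)
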