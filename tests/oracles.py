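"""Independent naive in-memory oracles for the query and linker operations.

Everything here works directly on a :class:`RecordSet` with plain Python
loops and dictionaries — no SQL, no shared code with the implementations
under test — so row-set agreement between the two routes is meaningful.
"""

from __future__ import annotations

import re

from srakit.metadb import RecordSet


def _index(records: RecordSet):
    studies = {s.study_accession: s for s in records.studies}
    samples = {s.sample_accession: s for s in records.samples}
    experiments = {e.experiment_accession: e for e in records.experiments}
    return studies, samples, experiments


def naive_metadata(records: RecordSet, study_accessions: list[str]):
    """(study, experiment, sample, run, strategy, attribute) rows, unsorted set."""
    studies, samples, experiments = _index(records)
    wanted = set(study_accessions)
    rows = set()
    for run in records.runs:
        exp = experiments[run.experiment_accession]
        if exp.study_accession not in wanted:
            continue
        sample = samples.get(exp.sample_accession)
        rows.add(
            (
                exp.study_accession,
                exp.experiment_accession,
                exp.sample_accession,
                run.run_accession,
                exp.library_strategy,
                sample.sample_attribute if sample else "",
            )
        )
    return rows


def naive_search(records: RecordSet, phrase: str):
    """Base (study, experiment, sample, run) rows whose join path matches."""
    studies, samples, experiments = _index(records)
    needle = phrase.lower()
    rows = set()
    for run in records.runs:
        exp = experiments[run.experiment_accession]
        study = studies[exp.study_accession]
        sample = samples.get(exp.sample_accession)
        fields = [
            study.study_title,
            study.study_abstract,
            study.study_description,
            exp.experiment_title,
            exp.library_strategy,
            sample.sample_attribute if sample else "",
        ]
        if any(needle in f.lower() for f in fields):
            rows.add(
                (
                    exp.study_accession,
                    exp.experiment_accession,
                    exp.sample_accession,
                    run.run_accession,
                )
            )
    return rows


def naive_gse_to_srp(records: RecordSet, gses: list[str]):
    wanted = set(gses)
    return {
        (s.study_alias, s.study_accession)
        for s in records.studies
        if s.study_alias in wanted
    }


def naive_gse_to_gsm(records: RecordSet, gses: list[str]):
    wanted = set(gses)
    by_study = {s.study_accession: s.study_alias for s in records.studies}
    return {
        (by_study[e.study_accession], e.experiment_alias)
        for e in records.experiments
        if by_study.get(e.study_accession, "") in wanted
    }


def naive_gsm_to_srr(records: RecordSet, gsms: list[str]):
    patterns = [re.compile(re.escape(q) + r"(_[0-9]+)?\Z") for q in gsms]
    experiments = {e.experiment_accession: e for e in records.experiments}
    rows = set()
    for run in records.runs:
        alias = experiments[run.experiment_accession].experiment_alias
        if alias and any(p.fullmatch(alias) for p in patterns):
            rows.add((alias, run.run_accession))
    return rows


def naive_study_alias_run_pairs(records: RecordSet):
    """All (study_alias, run) pairs of GEO-aliased studies."""
    experiments = {e.experiment_accession: e for e in records.experiments}
    by_study = {s.study_accession: s.study_alias for s in records.studies}
    return {
        (by_study[experiments[r.experiment_accession].study_accession], r.run_accession)
        for r in records.runs
        if by_study[experiments[r.experiment_accession].study_accession]
    }
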