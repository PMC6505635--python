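"""GEO ↔ SRA conversions: alias joins, suffix handling, composition."""

import pytest

import expected_outputs as expect
import oracles
from srakit import (
    AccessionError,
    AccessionKind,
    Archive,
    UsageError,
    classify_accession,
    fixtures,
    gse_to_gsm,
    gse_to_srp,
    gsm_to_srr,
    metadata,
)
from srakit.fixtures import FixtureParams
from srakit.metadb import ExperimentRecord, RunRecord, SampleRecord, StudyRecord


@pytest.mark.parametrize(
    ("text", "kind", "archive"),
    [
        ("DRR021383", AccessionKind.RUN, Archive.DDBJ),
        ("GSM1020640_1", AccessionKind.GEO_SAMPLE, Archive.GEO),
        ("GSE100007", AccessionKind.GEO_SERIES, Archive.GEO),
        ("ERX1264364", AccessionKind.EXPERIMENT, Archive.EBI),
    ],
)
def test_classification_of_linker_inputs(text, kind, archive):
    acc = classify_accession(text)
    assert (acc.kind, acc.archive) == (kind, archive)


def test_truncated_accession_is_a_classification_error():
    with pytest.raises(AccessionError, match="SRP"):
        classify_accession("SRP")


class TestGseToSrp:
    def test_series_convert_to_study_accessions(self, demo_handle):
        table = gse_to_srp(demo_handle, ["GSE24355", "GSE25842"])
        assert table.columns == ("study_alias", "study_accession")
        assert list(table.rows) == expect.GSE_TO_SRP

    def test_detailed_expand_lists_experiments_with_aliases(self, demo_handle):
        table = gse_to_srp(demo_handle, ["GSE100007"], detailed=True, expand=True)
        # no sample annotations exported for this series: expansion adds nothing
        assert table.columns == (
            "study_alias",
            "study_accession",
            "experiment_accession",
            "sample_accession",
            "experiment_alias",
            "sample_alias",
        )
        assert list(table.rows) == expect.GSE100007_DETAILED

    def test_unknown_series_warns_and_yields_zero_rows(self, demo_handle, caplog):
        with caplog.at_level("WARNING", logger="srakit.linker"):
            table = gse_to_srp(demo_handle, ["GSE999999"])
        assert len(table) == 0
        assert "GSE999999" in caplog.text

    def test_non_gse_input_is_a_usage_error(self, demo_handle):
        with pytest.raises(UsageError):
            gse_to_srp(demo_handle, ["SRP010679"])


class TestGseToGsm:
    def test_series_lists_its_geo_experiments(self, demo_handle):
        table = gse_to_gsm(demo_handle, ["GSE41637"])
        assert table.columns == ("study_alias", "experiment_alias")
        assert list(table.rows) == expect.GSE41637_GSMS

    def test_desc_carries_the_sample_annotation_text(self, demo_handle):
        table = gse_to_gsm(demo_handle, ["GSE41637"], desc=True)
        assert list(table.rows) == expect.GSE41637_DESC

    def test_desc_expand_structures_the_annotations(self, demo_handle):
        table = gse_to_gsm(demo_handle, ["GSE41637"], desc=True, expand=True)
        assert table.columns == (
            "study_alias",
            "experiment_alias",
            "source_name",
            "strain",
            "tissue",
        )
        assert list(table.rows) == expect.GSE41637_EXPANDED
        skm = dict(zip(table.columns, table.rows[6]))
        assert (skm["source_name"], skm["strain"], skm["tissue"]) == (
            "mouse_skm",
            "dba/2j",
            "skeletal muscle",
        )


class TestGsmToSrr:
    def test_bare_gsm_matches_suffixed_alias(self, demo_handle):
        table = gsm_to_srr(demo_handle, ["GSM1020640", "GSM1020646"])
        assert table.columns == ("experiment_alias", "run_accession")
        assert list(table.rows) == expect.GSM_TO_SRR

    def test_already_suffixed_query_gives_the_same_row(self, demo_handle):
        assert gsm_to_srr(demo_handle, ["GSM1020640_1"]).rows == (
            ("GSM1020640_1", "SRR594393"),
        )

    def test_non_gsm_input_is_a_usage_error(self, demo_handle):
        with pytest.raises(UsageError):
            gsm_to_srr(demo_handle, ["GSE41637"])

    def test_prefix_never_matches_a_longer_numeric_id(self, make_db):
        """GSM102 must match GSM102 and GSM102_1 but never GSM1020640_1."""
        records = fixtures.random_records(FixtureParams(n_studies=0, seed=0))
        records.studies = [StudyRecord("SRP100001", study_alias="GSE1")]
        aliases = ["GSM102", "GSM102_1", "GSM1020640_1", "GSM102_22", "GSM1021"]
        for i, alias in enumerate(aliases):
            records.samples.append(SampleRecord(f"SRS10000{i}", sample_alias=alias))
            records.experiments.append(
                ExperimentRecord(
                    experiment_accession=f"SRX10000{i}",
                    experiment_alias=alias,
                    study_accession="SRP100001",
                    sample_accession=f"SRS10000{i}",
                )
            )
            records.runs.append(RunRecord(f"SRR10000{i}", f"SRX10000{i}"))
        handle = make_db(records)
        table = gsm_to_srr(handle, ["GSM102"])
        assert set(table.column("experiment_alias")) == {"GSM102", "GSM102_1", "GSM102_22"}
        assert set(table.rows) == oracles.naive_gsm_to_srr(records, ["GSM102"])

    def test_multi_run_alias_returns_one_row_per_run(self, make_db):
        records = fixtures.random_records(
            FixtureParams(
                n_studies=6,
                geo_linked_fraction=1.0,
                runs_per_experiment=(3, 3),
                seed=13,
            )
        )
        handle = make_db(records)
        gsm = records.experiments[0].experiment_alias.split("_")[0]
        table = gsm_to_srr(handle, [gsm])
        assert len(table) == 3
        assert set(table.rows) == oracles.naive_gsm_to_srr(records, [gsm])


def test_conversion_composition_matches_metadata_join(demo_handle, demo_records, make_db):
    """gse-to-gsm composed with gsm-to-srr covers exactly the run set that
    metadata() reports for the aliased studies."""
    for records, handle in [
        (demo_records, demo_handle),
        *(
            (r, make_db(r, f"c{seed}.sqlite"))
            for seed in (1, 2)
            for r in [
                fixtures.random_records(
                    FixtureParams(n_studies=10, geo_linked_fraction=0.7, seed=seed)
                )
            ]
        ),
    ]:
        gses = sorted({s.study_alias for s in records.studies if s.study_alias})
        gsms = [row[1] for row in gse_to_gsm(handle, gses).rows if row[1]]
        composed = set()
        for gse in gses:
            study_gsms = [r[1] for r in gse_to_gsm(handle, [gse]).rows if r[1]]
            if not study_gsms:
                continue
            for alias, run in gsm_to_srr(handle, study_gsms).rows:
                composed.add((gse, run))
        assert composed == oracles.naive_study_alias_run_pairs(records)
        alias_by_study = {s.study_accession: s.study_alias for s in records.studies}
        aliased = [s.study_accession for s in records.studies if s.study_alias]
        direct = set()
        if aliased:
            for row in metadata(handle, aliased).rows:
                direct.add((alias_by_study[row[0]], row[3]))
        assert composed == direct
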