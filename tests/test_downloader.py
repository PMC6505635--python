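"""Pipe-table parsing, download planning and idempotent execution."""

import pytest

from srakit import (
    DownloadError,
    UsageError,
    execute_plan,
    fixtures,
    parse_pipe_table,
    plan_downloads,
)
from srakit.downloader import DEFAULT_URL_TEMPLATE, PipeRow, resolve_url
from srakit.fixtures import FixtureParams
from srakit.metadb import Accession, AccessionKind


class TestParsePipeTable:
    HEADER = "study_accession\texperiment_accession\tsample_accession\trun_accession"

    def test_rows_are_located_by_header_position(self):
        text = "\n".join(
            [
                self.HEADER,
                "SRP010679\tSRX118285\tSRS290854\tSRR403882",
                "SRP010679\tSRX118286\tSRS290855\tSRR403883",
                "",
                "SRP010679\tSRX118287\tSRS290856\tSRR403884",
                "SRP010679\tSRX118288\tSRS290857\tSRR403885",
            ]
        )
        rows = parse_pipe_table(text)
        assert len(rows) == 4
        assert rows[0] == PipeRow("SRP010679", "SRR403882")

    def test_column_order_does_not_matter(self):
        text = "run_accession\tstudy_accession\nSRR403882\tSRP010679\n"
        assert parse_pipe_table(text) == [PipeRow("SRP010679", "SRR403882")]

    def test_header_only_input_is_empty(self):
        assert parse_pipe_table(self.HEADER + "\n") == []

    def test_missing_header_columns_are_named(self):
        with pytest.raises(UsageError, match="run_accession"):
            parse_pipe_table("study_accession\tassay\nSRP1\tRNA-Seq\n")

    def test_malformed_accession_reports_line_number(self):
        text = self.HEADER + "\nSRP010679\tSRX1\tSRS1\tSRR403882\nSRP010679\tSRX1\tSRS1\tbogus\n"
        with pytest.raises(UsageError, match="line 3"):
            parse_pipe_table(text)

    def test_empty_input_is_an_error(self):
        with pytest.raises(UsageError):
            parse_pipe_table("")


def test_url_template_substitution():
    template = "x/{prefix3}/{run6}/{run}/{run}.sra"
    assert resolve_url(template, "SRR594393") == "x/SRR/SRR594/SRR594393/SRR594393.sra"


class TestPlanDownloads:
    def test_study_plan_covers_every_run_in_hierarchy_layout(self, demo_handle, tmp_path):
        plan = plan_downloads(demo_handle, ["SRP010679"], root=tmp_path)
        assert len(plan.entries) == 12
        entry = next(e for e in plan.entries if e.run == "SRR403882")
        assert entry.dest_path == "SRP010679/SRX118285/SRR403882/SRR403882.sra"
        assert entry.source_url == resolve_url(DEFAULT_URL_TEMPLATE, "SRR403882")

    def test_every_dest_path_follows_study_experiment_run_layout(self, demo_handle, tmp_path):
        plan = plan_downloads(
            demo_handle, ["SRP010679", "DRP003075", "ERP013565"], root=tmp_path
        )
        assert len({e.run for e in plan.entries}) == len(plan.entries)
        for e in plan.entries:
            parts = e.dest_path.split("/")
            assert len(parts) == 4
            kinds = [Accession.parse(p).kind for p in parts[:3]]
            assert kinds == [
                AccessionKind.STUDY,
                AccessionKind.EXPERIMENT,
                AccessionKind.RUN,
            ]
            assert parts[3] == parts[2] + ".sra"

    def test_pipe_rows_select_exactly_the_listed_runs(self, demo_handle, tmp_path):
        rows = [PipeRow("SRP010679", "SRR403882"), PipeRow("SRP010679", "SRR403885")]
        plan = plan_downloads(demo_handle, rows, root=tmp_path)
        assert [e.run for e in plan.entries] == ["SRR403882", "SRR403885"]

    def test_empty_pipe_input_gives_empty_plan(self, demo_handle, tmp_path):
        assert plan_downloads(demo_handle, [], root=tmp_path).entries == []

    def test_unknown_run_in_pipe_rows_is_named(self, demo_handle, tmp_path):
        with pytest.raises(DownloadError, match="SRR999999"):
            plan_downloads(demo_handle, [PipeRow("SRP010679", "SRR999999")], root=tmp_path)

    def test_template_without_placeholders_is_rejected(self, demo_handle, tmp_path):
        with pytest.raises(UsageError, match="placeholder"):
            plan_downloads(demo_handle, ["SRP010679"], root=tmp_path, url_template="x/{run}")


class TestExecutePlan:
    @pytest.fixture()
    def plan(self, demo_handle, tmp_path):
        return plan_downloads(demo_handle, ["DRP003075"], root=tmp_path / "data")

    def test_empty_plan_reports_zeroes(self, demo_handle, tmp_path):
        plan = plan_downloads(demo_handle, [], root=tmp_path)
        report = execute_plan(plan, fetcher=lambda url: b"x")
        assert (report.fetched, report.skipped, report.failed) == (0, 0, [])

    def test_fetches_create_hierarchy_and_invoke_progress(self, plan):
        seen = []
        report = execute_plan(
            plan, fetcher=lambda url: url.encode(), progress=lambda e, s: seen.append((e.run, s))
        )
        assert report.fetched == len(plan.entries) == 7
        assert report.skipped == 0 and report.failed == []
        assert len(seen) == len(plan.entries)
        for entry in plan.entries:
            dest = plan.root / entry.dest_path
            assert dest.read_bytes() == entry.source_url.encode()

    def test_second_execution_is_idempotent(self, plan):
        execute_plan(plan, fetcher=lambda url: b"payload")
        second = execute_plan(plan, fetcher=lambda url: b"payload")
        assert second.fetched == 0
        assert second.skipped == len(plan.entries)
        assert second.failed == []

    def test_preexisting_destination_is_skipped(self, plan):
        pre = plan.root / plan.entries[0].dest_path
        pre.parent.mkdir(parents=True)
        pre.write_bytes(b"already here")
        report = execute_plan(plan, fetcher=lambda url: b"x")
        assert (report.fetched, report.skipped) == (len(plan.entries) - 1, 1)
        assert pre.read_bytes() == b"already here"

    def test_one_failing_url_does_not_abort_the_rest(self, plan):
        bad_run = plan.entries[3].run

        def fetcher(url):
            if bad_run in url:
                raise DownloadError("boom")
            return b"ok"

        report = execute_plan(plan, fetcher=fetcher)
        assert [run for run, _ in report.failed] == [bad_run]
        assert report.fetched == len(plan.entries) - 1
        # failed run retried (and fetched) on a second pass
        second = execute_plan(plan, fetcher=lambda url: b"ok")
        assert (second.fetched, second.skipped) == (1, len(plan.entries) - 1)

    def test_unusable_root_aborts_before_any_fetch(self, demo_handle, tmp_path):
        blocker = tmp_path / "blocker"
        blocker.write_text("a plain file where the root directory should go")
        plan = plan_downloads(demo_handle, ["DRP003075"], root=blocker / "sub")
        calls = []

        def fetcher(url):
            calls.append(url)
            return b"x"

        with pytest.raises(DownloadError):
            execute_plan(plan, fetcher=fetcher)
        assert calls == []
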