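import sys
from pathlib import Path

import pytest

from srakit import fixtures, open_metadb

sys.path.insert(0, str(Path(__file__).parent))  # expected_outputs / oracles


@pytest.fixture(scope="session")
def demo_records():
    return fixtures.demo_records()


@pytest.fixture(scope="session")
def demo_db(tmp_path_factory, demo_records):
    """The demonstration database, built once per session."""
    path = tmp_path_factory.mktemp("demo") / "SRAmetadb.sqlite"
    return fixtures.build_db(demo_records, path)


@pytest.fixture(scope="session")
def demo_handle(demo_db):
    return open_metadb(demo_db)


@pytest.fixture()
def make_db(tmp_path):
    """Build an arbitrary RecordSet into a fresh temporary database."""

    def _make(records, name="meta.sqlite"):
        return open_metadb(fixtures.build_db(records, tmp_path / name))

    return _make
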