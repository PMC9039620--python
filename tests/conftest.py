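import pytest

from pagkit.synthetic_data import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle, seed 1, shared across tests."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture
def de_table_file(tmp_path):
    def _write(rows, header="gene\tlog2fc\tpvalue"):
        path = tmp_path / "de.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture
def gmt_file(tmp_path):
    def _write(lines):
        path = tmp_path / "sets.gmt"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
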