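import pytest

from cgbuild.fixtures import default_fixtures, make_fixtures


@pytest.fixture(scope="session")
def fx():
    """In-memory synthetic templates (lipids, solvents, ions, proteins)."""
    return default_fixtures()


@pytest.fixture()
def fx_files(tmp_path):
    """Fixture file set written to a temp dir (structures + itp tree)."""
    return make_fixtures(seed=1, outdir=str(tmp_path / "fx"))
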