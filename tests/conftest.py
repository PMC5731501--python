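import pytest

from recdf.fixtures import make_default_fixture, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """The default end-to-end fixture (2 x 50 kb, 12 genes, ~260 PM probes)."""
    return make_default_fixture(seed=11)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The same fixture written to disk as its file bundle."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_bundle(bundle, outdir)
    return paths
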