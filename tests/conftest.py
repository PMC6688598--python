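import pytest
from hypothesis import settings

from rspnet import load_bundle

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from rspnet.synth import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic dataset bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    manifest = generate_fixture(FixtureSpec(seed=11), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def bundle(fixture_dir):
    outdir, _ = fixture_dir
    return load_bundle(outdir / "config.yaml")


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return fixture_dir[1]


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small, fast bundle for exhaustive (brute-force) checks."""
    outdir = tmp_path_factory.mktemp("small_fixture")
    spec = FixtureSpec(
        seed=5, n_genes=60, n_terms_bp=40, n_terms_mf=30, n_pathways=6,
        ppi_density=0.05, n_diseases=2, mirnas_per_disease=2, targets_per_mirna=2,
    )
    manifest = generate_fixture(spec, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def small_bundle(small_fixture_dir):
    outdir, _ = small_fixture_dir
    return load_bundle(outdir / "config.yaml")
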