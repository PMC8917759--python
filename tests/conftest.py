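import pytest

from oysteriap import synth
from oysteriap.config import RunConfig
from oysteriap.pipeline import run_characterize


@pytest.fixture(scope="session")
def family_bundle():
    """A 40-gene synthetic family with planted curation features."""
    return synth.gen_family(n_genes=40, seed=3)


@pytest.fixture(scope="session")
def family_dir(family_bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("family") / "in"
    family_bundle.write(path)
    return path


@pytest.fixture(scope="session")
def characterized(family_bundle, family_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("characterized")
    cfg = RunConfig(input_dir=family_dir, output_dir=out, seed=3)
    return run_characterize(cfg)
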