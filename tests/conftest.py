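import numpy as np
import pytest

from adipocomp.config import default_config
from adipocomp.pipeline import run_pipeline
from adipocomp.protocol import DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full small-scale pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    config = default_config(seed=3, out_dir=str(out))
    manifest = run_pipeline(config, out)
    return config, out, manifest
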