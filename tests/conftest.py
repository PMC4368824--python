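import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_workspace(tmp_path_factory):
    """The bundled end-to-end synthetic input set plus its config."""
    from egtcensus.pipeline import build_synthetic_workspace

    d = tmp_path_factory.mktemp("workspace")
    return build_synthetic_workspace(d, seed=42)
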