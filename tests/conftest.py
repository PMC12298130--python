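import pytest

from sedrisk import load_default_params
from sedrisk.config import RunConfig


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def conc_means(params):
    """Per-element mean concentrations from the packaged summary table."""
    return {el: t.mean for el, t in params.concentration_summary.items()}


@pytest.fixture()
def config():
    return RunConfig(iterations=10_000, seed=1)
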