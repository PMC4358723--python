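import pytest

from hgtscan.core import HGTThresholds
from hgtscan.synthetic import SimParams, generate_study


@pytest.fixture(scope="session")
def thresholds() -> HGTThresholds:
    return HGTThresholds()


@pytest.fixture(scope="session")
def small_study():
    """A compact 4-species study shared by the pipeline-level tests."""
    return generate_study(SimParams(n_species=4, genes_per_species=200, seed=7))
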