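import pytest

from memstretch import MembraneModel


@pytest.fixture(scope="session")
def calibrated_results():
    """Default membrane model calibrated to 10 % average strain (shared)."""
    return MembraneModel().fit(target_avg_strain=0.10)
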