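import pytest

from mouthwash_cea import load_parameter_set


@pytest.fixture(scope="session")
def params():
    """Bundled base-case parameter set at the default RRR of 0.3."""
    return load_parameter_set()
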