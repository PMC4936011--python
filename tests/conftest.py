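import pytest

from markovcea import bph_reference_model, evaluate_strategy


@pytest.fixture(scope="session")
def bph_spec():
    return bph_reference_model()


@pytest.fixture(scope="session")
def bph_outcomes(bph_spec):
    """Deterministic 10-year outcomes for both strategies on the bundled model."""
    return {
        strategy: evaluate_strategy(bph_spec, strategy)
        for strategy in bph_spec.strategies
    }
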