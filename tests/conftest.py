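import numpy as np
import pytest

from eegfsel import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Small, fast generator spec: 12 features, 2 informative, short sessions."""
    return synthetic.SyntheticSpec(
        n_features=12,
        informative=(3, 7),
        effect_size=3.0,
        block_seconds=5,
        session_minutes=0.25,
        seed=7,
    )


@pytest.fixture
def tiny_sessions(tiny_spec):
    return synthetic.generate_sessions(tiny_spec, 3)


@pytest.fixture
def default_sessions():
    """Three 45 s sessions with 96 features and 4 informative ones."""
    spec = synthetic.SyntheticSpec(
        informative=(2, 14, 38, 61),
        effect_size=3.0,
        session_minutes=0.75,
        seed=11,
    )
    return synthetic.generate_sessions(spec, 3)
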