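import numpy as np
import pytest

from ternadock.decoder import DecoderConfig
from ternadock.encoder import EncoderConfig
from ternadock.featurize import FeaturizerConfig
from ternadock.synthetic import SyntheticComplexSpec, make_ternary_complex
from ternadock.training import TernaryModel


@pytest.fixture(scope="session")
def complex_and_truth():
    """One deterministic synthetic ternary complex with ground truth."""
    rng = np.random.default_rng(0)
    return make_ternary_complex(SyntheticComplexSpec(), rng)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained model (hidden 16, M=2, N=1) for contract tests."""
    return TernaryModel.build(EncoderConfig(n_layers=2, hidden_dim=16),
                              DecoderConfig(n_layers=1, hidden_dim=16), seed=1)


@pytest.fixture
def feat_config():
    return FeaturizerConfig()
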