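import numpy as np
import pytest
from hypothesis import settings

from gatmda import AssociationMatrix, Bundle, SimilarityMatrix
from gatmda.synthetic import SynthConfig, generate_bundle

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """A small but non-trivial aligned dataset for fast end-to-end tests."""
    cfg = SynthConfig(m=30, n=20, l=8, n_blocks=2, p_in=0.35, p_out=0.02,
                      lnc_signal=0.5, lnc_noise=0.05, sim_noise_frac=0.1,
                      propensity_sigma=0.5, seed=7)
    bundle, _ = generate_bundle(cfg)
    return bundle


@pytest.fixture(scope="session")
def default_bundle() -> Bundle:
    """One instance of the full-size benchmark bundle."""
    bundle, _ = generate_bundle(SynthConfig(seed=0))
    return bundle


@pytest.fixture
def tiny_association() -> AssociationMatrix:
    values = np.array([[1, 0, 1], [0, 1, 0]])
    return AssociationMatrix(values, ["m1", "m2"], ["d1", "d2", "d3"])


@pytest.fixture
def identity_similarity() -> SimilarityMatrix:
    return SimilarityMatrix(np.eye(3), ["a", "b", "c"])
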