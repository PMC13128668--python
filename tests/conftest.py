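import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from protlife.model import HalfLifeModel
from protlife.synthetic import SyntheticSpec, generate, make_embedder


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-signal dataset shared by model-level tests."""
    spec = SyntheticSpec(
        n_long=45, n_short=15, length_range=(50, 110), p_motif=1.0,
        effect_size=2.5, seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    emb = make_embedder(tiny_dataset.spec, d_local=24, d_global=24, L_padded=112)
    return HalfLifeModel(tiny_dataset.records, emb)
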