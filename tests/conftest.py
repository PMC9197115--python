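import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-scale phantom cohort shared across tests."""
    from petmvcc.synthetic import PhantomConfig, generate

    cfg = PhantomConfig.small(seed=11)
    gt, volumes, sheet = generate(cfg)
    return cfg, gt, volumes, sheet


@pytest.fixture()
def toy_mixture():
    """Noiseless 4-subject mixture of 2 disjoint block sources."""
    rng = np.random.default_rng(7)
    V = 400
    S = np.zeros((2, V))
    S[0, :12] = 1.0
    S[1, 100:118] = 1.0
    S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    A = rng.normal(size=(4, 2)) + np.array([[2, -1], [-1, 2], [1, 1], [-2, -2]])
    X = A @ S
    return X, A, S
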