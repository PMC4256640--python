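import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    from wardmap.graph import WardGraph

    return WardGraph(("A", "B", "C"), (("A", "B"), ("B", "C")))


@pytest.fixture
def small_dataset():
    """Three wards with simple counts and one covariate."""
    from wardmap.io import WardDataset, WardRecord

    return WardDataset(
        (
            WardRecord("A", 0, 1000, {"nox": 0.3}),
            WardRecord("B", 5, 2000, {"nox": 0.5}),
            WardRecord("C", 2, 1500, {"nox": 0.4}),
        )
    )
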