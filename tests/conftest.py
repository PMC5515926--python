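import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmptl.encoders import EncodingResources, encode_dataset
from mmptl.synthetic import MotifSpec, ScenarioSpec, SHARED_PREFERENCES, generate_scenario

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def resources():
    return EncodingResources()


def small_scenario_spec(seed=0, strength=0.8):
    """A scenario small enough for unit tests (two sources + target)."""
    return ScenarioSpec(
        n_source_domains=2,
        substrates_per_domain=(4, 6),
        sites_per_domain=(12, 20),
        substrate_length=(80, 140),
        shared_motif=MotifSpec(
            preferences={k: dict(v) for k, v in SHARED_PREFERENCES.items()},
            strength=strength,
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_scenario():
    return generate_scenario(small_scenario_spec(seed=3))


@pytest.fixture(scope="session")
def tiny_matrices(tiny_scenario, resources):
    """Encoded domain matrices of the tiny scenario (fast schemes only)."""
    datasets = tiny_scenario.domain_datasets(seed=3)
    return {
        name: encode_dataset(ds.windows, resources, schemes=("AAPair", "Binary"))
        for name, ds in datasets.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
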