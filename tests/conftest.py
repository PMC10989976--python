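import pytest
from hypothesis import HealthCheck, settings

from cobin.pipeline import classify_with_fixture
from cobin.simulate import (
    CommunitySpec,
    LibrarySpec,
    SharedRepeat,
    SpeciesSpec,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Realistic miniature community: divergence, insertions, repeat block,
    barcode collisions and sequencing errors all present."""
    spec = CommunitySpec(
        species=[
            SpeciesSpec("alpha", 20_000, 25, 0.002, 0.05, 1_000),
            SpeciesSpec("beta", 20_000, 18, 0.002, 0.05, 1_000),
            SpeciesSpec("gamma", 20_000, 15, 0.0, 0.0),
        ],
        shared_repeats=[SharedRepeat("alpha", "beta", 1_500)],
        library=LibrarySpec(collision_rate=0.01, error_rate=0.0005),
        seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free, divergence-0, collision-0 community with a shared repeat
    and unique insertions: the regime where classifier behaviour is exact."""
    spec = CommunitySpec(
        species=[
            SpeciesSpec("alpha", 15_000, 20, 0.0, 0.03, 800),
            SpeciesSpec("beta", 15_000, 15, 0.0, 0.03, 800),
            SpeciesSpec("gamma", 15_000, 12, 0.0, 0.0),
        ],
        shared_repeats=[SharedRepeat("alpha", "beta", 1_200)],
        library=LibrarySpec(collision_rate=0.0, error_rate=0.0),
        seed=5,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def clean_classifications(clean_dataset):
    return classify_with_fixture(
        clean_dataset.reads,
        clean_dataset.reference_records(),
        clean_dataset.community.taxonomy,
    )
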