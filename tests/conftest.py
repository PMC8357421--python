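import pytest

from gridcan import (
    Arena,
    NetworkSpec,
    HeterogeneitySpec,
    build_preference_map,
    build_weight_matrix,
    apply_heterogeneities,
    generate_virtual_trajectory,
)


@pytest.fixture(scope="session")
def circle_arena():
    return Arena(shape="circle")


@pytest.fixture(scope="session")
def square_arena():
    return Arena(shape="square")


@pytest.fixture(scope="session")
def small_spec():
    """A 12x12 lattice: big enough for structure, cheap enough for loops."""
    return NetworkSpec(n=12)


@pytest.fixture(scope="session")
def small_weights(small_spec):
    return build_weight_matrix(small_spec, build_preference_map(small_spec.n))


@pytest.fixture(scope="session")
def short_trajectory(circle_arena):
    return generate_virtual_trajectory(circle_arena, duration=2.0, seed=5)
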