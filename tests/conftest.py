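import pytest

from ecinet import (
    GeneratorConfig,
    cycle_instance,
    cycle_network,
    fig1_instance,
    fig1_network,
    generate_random_network,
)


@pytest.fixture
def fig1():
    return fig1_network()


@pytest.fixture
def fig1_eci():
    return fig1_instance()


@pytest.fixture
def cycle_net():
    return cycle_network()


@pytest.fixture
def cycle_eci():
    return cycle_instance()


def random_network(seed, m=9, n=5, l=3, cycle_probability=0.0, **kw):
    """Shared helper: a deterministic small generator network."""
    return generate_random_network(
        GeneratorConfig(
            m=m, n=n, l=l, cycle_probability=cycle_probability, seed=seed, **kw
        )
    )
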