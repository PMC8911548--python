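import numpy as np
import pytest

from phasorseg import (
    AcquisitionConfig,
    PopulationSpec,
    simulate_interface_map,
)

# Ground-truth lifetimes of the cerulean-blue interface experiment:
# rabbit-skin glue 3.7 ns vs linseed oil 1.7 ns.
TAU_LONG_NS = 3.7
TAU_SHORT_NS = 1.7


@pytest.fixture(scope="session")
def config():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def pop_long():
    return PopulationSpec(lifetimes=(TAU_LONG_NS,), target_peak=500.0, label=1)


@pytest.fixture(scope="session")
def pop_short():
    return PopulationSpec(lifetimes=(TAU_SHORT_NS,), target_peak=500.0, label=2)


@pytest.fixture(scope="session")
def noiseless_interface_map(config, pop_long, pop_short):
    """10x10 two-population map without counting noise."""
    return simulate_interface_map(
        pop_long, pop_short, (10, 10), 5, config, seed=0, noise="none"
    )


@pytest.fixture(scope="session")
def poisson_interface_map(config, pop_long, pop_short):
    """20x20 two-population map with Poisson noise, fixed seed."""
    return simulate_interface_map(
        pop_long, pop_short, (20, 20), 10, config, seed=7, noise="poisson"
    )
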