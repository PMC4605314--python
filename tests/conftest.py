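import numpy as np
import pytest

from threadkin import fixtures
from threadkin.kinetics import ElementaryRates
from threadkin.synthetic import SimulationConfig, simulate_trace

KBT = 4.05


@pytest.fixture(scope="session")
def zero_force_rates() -> ElementaryRates:
    """Published zero-force elementary rates (kinetic parameter set)."""
    return fixtures.zero_force_rates()


@pytest.fixture(scope="session")
def kinetic_truth():
    """The four zero-force Bell laws used as simulation truth."""
    return fixtures.kinetic_truth()


@pytest.fixture(scope="session")
def flex_polymer():
    return fixtures.WLC_PARAMS["dsDNA_flexRu2"].params


@pytest.fixture(scope="session")
def ds_polymer():
    return fixtures.WLC_PARAMS["dsDNA"].params


def make_experiment(noise_sd: float, seed: int, duration: float = 600.0):
    """One full study-grid experiment: 3 forces x 4 concentrations."""
    traces = []
    index = 0
    for force in fixtures.FORCES_PN:
        for conc in fixtures.CONCENTRATIONS_NM:
            cfg = SimulationConfig(
                force=force, concentration=conc, duration=duration,
                noise_sd=noise_sd, seed=seed * 1000 + index,
            )
            traces.append(simulate_trace(cfg))
            index += 1
    return traces


@pytest.fixture(scope="session")
def noiseless_experiment():
    return make_experiment(0.0, seed=0)


def random_rates(rng: np.random.Generator) -> ElementaryRates:
    """Random positive rate set spanning a few orders of magnitude."""
    vals = 10.0 ** rng.uniform(-4, 0, size=4)
    return ElementaryRates(*vals)
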