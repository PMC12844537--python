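import numpy as np
import pytest

from mslesion import SimulationConfig, build_region_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A desk-scale domain: 28 x 30 lattice, 24 oligodendrocyte blocks.

    Spawn and conversion rates are raised so short runs show full dynamics
    (relapse influx, reactivation, damage, stress transitions).
    """
    return SimulationConfig(
        lattice_width=28, lattice_height=30,
        blood_width=3, pvs_width=5, parenchyma_width=20,
        n_steps=400, rho_R=0.02, rho_NR=0.002,
        pvm_count=10, omega=4, lambda_=6,
        repair_delay=3, seed=7,
    )


@pytest.fixture
def small_region(small_config):
    return build_region_map(small_config)
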