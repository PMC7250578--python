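import numpy as np
import pytest

from centroevo import PRESETS, PartitionSpec, build_matrix, initial_state


@pytest.fixture(scope="session")
def dld1():
    return PRESETS["dld1"]


@pytest.fixture(scope="session")
def rpe1():
    return PRESETS["rpe1_p53ko"]


@pytest.fixture(scope="session")
def tetraploid_tripolar():
    return PartitionSpec(n_chromosome_types=23, ploidy=4, n_poles=3)


@pytest.fixture
def dld1_model2(dld1):
    """Coefficient matrix and day-0 state for the DLD-1 Model II setup."""
    return build_matrix(dld1, "II"), initial_state(0.10, 1.0, dld1, "II")


@pytest.fixture
def rpe1_model2(rpe1):
    return build_matrix(rpe1, "II"), initial_state(0.127, 1.0, rpe1, "II")


def random_valid_params(rng: np.random.Generator):
    """Draw a random valid parameter set (used by steady-state consistency checks)."""
    from centroevo import PopulationParams

    return PopulationParams(
        b_C2=rng.uniform(0.8, 1.2),
        b_C4=rng.uniform(0.6, 1.0),
        q=rng.uniform(0.95, 1.0),
        p_bipolar=rng.uniform(0.2, 0.5),
        r=rng.uniform(0.3, 0.8),
        fs=rng.uniform(0.2, 0.8),
        d_C2=rng.uniform(0.0, 0.1),
        d_C4=rng.uniform(0.1, 0.6),
        d_C6=rng.uniform(1.0, 2.0),
        v=rng.uniform(0.05, 0.6),
        r_S=rng.uniform(0.6, 0.99),
    )
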