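import numpy as np
import pytest

import brainpv as bp


@pytest.fixture(scope="session")
def model():
    return bp.default_model_params()


@pytest.fixture(scope="session")
def hard_seq():
    return bp.hard_pulse_sequence()


@pytest.fixture(scope="session")
def shaped_seq():
    return bp.default_sequence()


@pytest.fixture(scope="session")
def grid(model, hard_seq):
    """Full-resolution lookup grid (5% simulated, 1% interpolated)."""
    return bp.build_grid(model, hard_seq, step=1.0, sim_step=5.0)


@pytest.fixture(scope="session")
def manifold_points(model, hard_seq):
    """The 141 calibration-composition fitted triples."""
    return bp.model_manifold_points(model, hard_seq)


@pytest.fixture(scope="session")
def a_scale(model, hard_seq):
    return bp.csf_amplitude_scale(model, hard_seq)


@pytest.fixture(scope="session")
def small_phantom():
    return bp.make_phantom(bp.small_phantom_spec(lesions=bp.ms_lesions()))


@pytest.fixture(scope="session")
def healthy_phantom():
    return bp.make_phantom(bp.small_phantom_spec())


def random_compositions(rng, n, v_my_cap=0.40):
    """Uniform random valid compositions with the myelin cap."""
    out = np.empty((n, 4))
    for i in range(n):
        while True:
            v_my = rng.uniform(0, v_my_cap)
            rest = rng.dirichlet([1.0, 1.0, 1.0]) * (1 - v_my)
            comp = np.array([v_my, rest[0], rest[1], rest[2]])
            if comp[1] >= 0:
                out[i] = comp
                break
    return out
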