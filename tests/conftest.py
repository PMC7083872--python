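import numpy as np
import pytest

import intervalkinetics as ik
from intervalkinetics.reference import REFERENCE_MEASUREMENTS, reference_protocol


@pytest.fixture(scope="session")
def protocol8():
    """Standard 8-point time-lapse protocol (0.1 s frames, 50 + 100)."""
    return reference_protocol()


@pytest.fixture(scope="session")
def row1():
    """Two-population reference measurement (1.6 s / 24 s, k_b = 5.5)."""
    return REFERENCE_MEASUREMENTS["uvrA_no_uvrB_no_mfd_plasmid"]


@pytest.fixture(scope="session")
def single_pop_model():
    return ik.KineticModel(amplitudes=(1.0,), off_rates=(1 / 10.0,), k_b=5.5)


@pytest.fixture(scope="session")
def small_movie():
    """Small two-phase movie with ground truth for detection benchmarks."""
    protocol = ik.AcquisitionProtocol(
        tau_tl_grid=(0.1,), frame_shape=(256, 256), n_bleach_frames=8,
        n_sm_frames=80,
    )
    model = ik.KineticModel(amplitudes=(1.0,), off_rates=(1 / 4.0,), k_b=1.5)
    return ik.simulate_movie(
        model, protocol, cells=4, emitters_per_cell=6, psf_sigma=1.2,
        background_mean=100.0, noise_sd=3.0, seed=42,
    )
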