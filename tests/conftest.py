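import numpy as np
import pytest

from emgcancel.common_input import (CommonInputSpec, generate_common_input,
                                    generate_noise_bank)
from emgcancel.emg import VolumeGeometry, build_muap_library, synthesize_emg
from emgcancel.motoneuron import build_pool, simulate_pool

FS = 2048.0


@pytest.fixture(scope="session")
def pool100():
    return build_pool(100)


@pytest.fixture(scope="session")
def short_run(pool100):
    """One 4 s simulation of a mid-level condition (shared across tests)."""
    dur = 4.0
    spec = CommonInputSpec(g2=1.5e-4, offset=4.0e-3, duration=dur, fs=FS)
    common = generate_common_input(spec, seed=101)
    noise = generate_noise_bank(100, dur, FS, 2.2e-4, seed=102)
    spikes = simulate_pool(pool100, common, noise)
    lib = build_muap_library(VolumeGeometry(), 100, library_id=1, seed=103)
    pair = synthesize_emg(spikes, lib)
    return {"spikes": spikes, "lib": lib, "pair": pair, "fs": FS,
            "common": common, "noise": noise}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def acceptance_grid():
    """Reduced study grid shared by the acceptance tests.

    100-unit pool, 11 conditions, 25 repetitions of 6 s, with the noise
    gain calibrated at run time.
    """
    from emgcancel.experiment import run_grid

    return run_grid(n_reps=25, duration=6.0, master_seed=0)
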