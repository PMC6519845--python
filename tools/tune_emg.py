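"""Pilot tuning of the surface-EMG kernel.

Calibrates the depth-dependent temporal broadening of the fibre
potentials so that the interference-EMG median frequency of low/medium
common-input conditions falls in the physiological 72 +/- 15 Hz band,
and checks the resulting amplitude-cancellation range across the grid
extremes.  Run from the repository root: python tools/tune_emg.py
"""
import numpy as np

from emgcancel.common_input import (CommonInputSpec, generate_common_input,
                                    generate_noise_bank)
from emgcancel.emg import (VolumeGeometry, build_muap_library,
                           cancellation_index, synthesize_emg)
from emgcancel.motoneuron import build_pool, simulate_pool
from emgcancel.params import load_parameters
from emgcancel.spectral import median_frequency

FS = 2048.0
NOISE_GAIN = 2.24e-4


def run_case(g2, offset, emg_overrides, seed=5, dur=10.0):
    params = load_parameters()
    params["emg"].update(emg_overrides)
    pool = build_pool(100)
    spec = CommonInputSpec(g2=g2, offset=offset, duration=dur, fs=FS)
    common = generate_common_input(spec, seed=[seed, 0])
    noise = generate_noise_bank(100, dur, FS, NOISE_GAIN, seed=[seed, 1])
    spikes = simulate_pool(pool, common, noise)
    lib = build_muap_library(VolumeGeometry(), 100, library_id=seed % 15 + 1,
                             seed=seed, params=params)
    pair = synthesize_emg(spikes, lib)
    return median_frequency(pair.emg), cancellation_index(pair)


def evaluate(ov, label=""):
    print(f"=== {label} {ov}")
    mdfs = []
    for seed, (g2, off) in enumerate([(5.7e-5, 3.8e-3), (5.7e-5, 4.0e-3),
                                      (1.5e-4, 3.8e-3)]):
        m, c = run_case(g2, off, ov, seed=seed + 3)
        mdfs.append(m)
        print(f"  g2={g2:g} off={off:g}: MDF={m:.1f} Hz  CI={c*100:.1f}%")
    # grid extremes for the cancellation range
    m, c_min = run_case(2.4e-4, 3.5e-3, ov, seed=11)     # low drive, high G2
    print(f"  CI extreme low (high G2, low offset): {c_min*100:.1f}%")
    m, c_max = run_case(5.7e-5, 4.3e-3, ov, seed=12)     # high drive, low G2
    print(f"  CI extreme high (low G2, high offset): {c_max*100:.1f}%")
    print(f"  mean MDF {np.mean(mdfs):.1f} (72.0 +/- 14.8)  CI range "
          f"{c_min*100:.0f}-{c_max*100:.0f} (37-71)")


if __name__ == "__main__":
    evaluate({}, "frozen defaults")
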