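"""Pilot tuning of the motoneuron pool parameters.

Measures, for one or more candidate parameter sets, the population
statistics the pool is calibrated against:

* per-unit f-I curves (units at the low, quarter and half pool index);
* recruited fraction and mean discharge rate at the lowest offset with
  low common-input variability, and at the highest offset (low+medium);
* the recruitment gain (percentage points) from low to high G2 at the
  three offsets shared by all G2 levels;
* the median ISI CoV at the calibrated noise gain (common input off).

Run from the repository root:  python tools/tune_pool.py
The chosen values are frozen into src/emgcancel/parameters.yaml.
"""
import sys
import time

import numpy as np

from emgcancel.common_input import (CommonInputSpec, calibrate_noise_gain,
                                    generate_common_input,
                                    generate_noise_bank, _isi_cov)
from emgcancel.motoneuron import (build_pool, recruitment_summary,
                                  simulate_pool)
from emgcancel.params import load_parameters

FS = 2048.0


def fi_curves(pool, units=(0, 25, 50), offsets=(3.5e-3, 3.8e-3, 4.0e-3, 4.3e-3, 4.8e-3, 5.5e-3)):
    dur = 5.0
    noise = generate_noise_bank(pool.n_units, dur, FS, 0.0, seed=0)
    out = {}
    for off in offsets:
        spec = CommonInputSpec(g2=0.0, offset=off, duration=dur, fs=FS)
        common = generate_common_input(spec, seed=1)
        spikes = simulate_pool(pool, common, noise)
        out[off] = [spikes.trains[u].size / dur for u in units]
    return out


def condition_stats(pool, noise_gain, g2, offset, n_reps=2, dur=10.0, seed=7):
    fracs, rates = [], []
    for rep in range(n_reps):
        spec = CommonInputSpec(g2=g2, offset=offset, duration=dur, fs=FS)
        common = generate_common_input(spec, seed=[seed, rep, 0])
        noise = generate_noise_bank(pool.n_units, dur, FS, noise_gain,
                                    seed=[seed, rep, 1])
        spikes = simulate_pool(pool, common, noise)
        f, r = recruitment_summary(spikes)
        fracs.append(f)
        rates.append(r)
    return np.mean(fracs), np.mean(rates)


def evaluate(overrides, label=""):
    params = load_parameters()
    params["pool"].update(overrides)
    pool = build_pool(100, params=params)
    g_in = pool.input_conductance
    print(f"=== {label} {overrides}")
    print(f"  G_in uS: {g_in[0]:.3f}..{g_in[-1]:.3f}  "
          f"rheo@Vth nA: {params['pool']['v_thresh_mV']*g_in[0]:.2f}.."
          f"{params['pool']['v_thresh_mV']*g_in[-1]:.2f}")
    fi = fi_curves(pool)
    for off, rates in fi.items():
        print(f"  f-I off={off*1e3:.1f}nA: u0={rates[0]:.1f} u25={rates[1]:.1f} u50={rates[2]:.1f}")
    t0 = time.time()
    log = []
    try:
        gain = calibrate_noise_gain(pool, offset=3.9e-3, seed=3, duration=8.0,
                                    log=log)
    except Exception as e:
        print("  calibration failed:", e)
        for entry in log:
            print("   ", entry)
        return
    print(f"  noise gain {gain:.2e} ({time.time()-t0:.0f}s), log tail {log[-2:]}")
    g2 = {"low": 5.7e-5, "med": 1.5e-4, "high": 2.4e-4}
    f_low, r_low = condition_stats(pool, gain, g2["low"], 3.5e-3)
    f_hi_lo, r_hi_lo = condition_stats(pool, gain, g2["low"], 4.3e-3)
    f_hi_med, r_hi_med = condition_stats(pool, gain, g2["med"], 4.3e-3)
    print(f"  lowest offset/low G2: recruited {f_low*100:.1f}% (ref 18) "
          f"rate {r_low:.1f} (ref 5.9)")
    print(f"  highest offset: recruited {(f_hi_lo+f_hi_med)/2*100:.1f}% (ref 53) "
          f"rate {(r_hi_lo+r_hi_med)/2:.1f} (ref 27.7)")
    gains = []
    for off in (3.5e-3, 3.8e-3, 4.0e-3):
        fl, _ = condition_stats(pool, gain, g2["low"], off, n_reps=1)
        fh, _ = condition_stats(pool, gain, g2["high"], off, n_reps=1)
        gains.append((fh - fl) * 100)
    print(f"  G2 recruitment gain: +{np.mean(gains):.1f} pts (ref 22)  "
          f"per-offset {np.round(gains,1)}")
    # CoV at the calibrated gain, fresh seed
    spec = CommonInputSpec(g2=0.0, offset=3.9e-3, duration=8.0, fs=FS)
    common = generate_common_input(spec, seed=99)
    noise = generate_noise_bank(100, 8.0, FS, gain, seed=98)
    cov, n_act = _isi_cov(simulate_pool(pool, common, noise).trains, 8.0)
    print(f"  CoV check: median {cov:.2f} over {n_act} active units (0.10-0.30)")


if __name__ == "__main__":
    candidates = [
        ({}, "baseline"),
    ]
    for ov, label in candidates:
        evaluate(ov, label)
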