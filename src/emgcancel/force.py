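"""Isometric muscle force from motor unit spike trains.

Each unit's twitch is a critically damped second-order impulse response
``h_i(t) = P_i (t/T_i) exp(1 - t/T_i)`` whose peak amplitude ``P_i``
spans a 100-fold range across the pool and whose contraction time
``T_i`` spans 30-90 ms, both exponentially distributed and
rank-inverse-associated so the pool contains many low-amplitude,
slow-twitch units.  The gain of each twitch depends nonlinearly on the
instantaneous discharge rate (sigmoidal rise of fused force above a
normalized-rate knee of 0.4), after the standard twitch-summation model
used for motor-unit pool simulations.  Muscle force is the sum over
units, reported as percent of the maximum voluntary contraction (MVC)
force, itself estimated as the force with every unit discharging at its
peak rate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .common_input import SignalTrace
from .motoneuron import SpikeTrainSet
from .params import interp_exp, load_parameters

__all__ = [
    "TwitchBank",
    "MvcReference",
    "build_twitch_bank",
    "twitch_kernel",
    "simulate_force",
    "estimate_mvc",
]


@dataclass
class TwitchBank:
    """Per-unit twitch parameters."""

    peak: np.ndarray             # P_i, arbitrary force units
    contraction_time: np.ndarray  # T_i, seconds
    gain_knee: float = 0.4

    @property
    def n_units(self) -> int:
        return self.peak.size


@dataclass
class MvcReference:
    """Normalization reference: force at peak discharge rates."""

    mvc_force: float
    peak_rates: np.ndarray


def build_twitch_bank(n_units: int, seed=None,
                      params: dict | None = None) -> TwitchBank:
    """Exponential twitch profiles; unit 0 is smallest and slowest.

    Deterministic given ``n_units`` (``seed`` kept for interface
    symmetry).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    p = (params or load_parameters())["force"]
    x = np.zeros(1) if n_units == 1 else np.linspace(0.0, 1.0, n_units)
    peak = interp_exp(1.0, p["twitch_peak_ratio"], x)
    t_lo, t_hi = p["contraction_time_ms"]
    ct = interp_exp(t_lo, t_hi, x) * 1e-3
    return TwitchBank(peak=peak, contraction_time=ct,
                      gain_knee=p["gain_rate_knee"])


def twitch_kernel(peak: float, t_contr: float, fs: float) -> np.ndarray:
    """Critically damped impulse response sampled at ``fs`` (peak at T)."""
    n = int(round(7.0 * t_contr * fs)) + 1
    t = np.arange(n) / fs
    return peak * (t / t_contr) * np.exp(1.0 - t / t_contr)


def _rate_gains(st: np.ndarray, t_contr: float, knee: float) -> np.ndarray:
    """Fuglevand-type nonlinear gain per spike from the instantaneous rate.

    The normalized stimulus rate is T_i/ISI; at or below the knee the
    twitch sums linearly (gain 1); above it the gain follows the
    sigmoidal fusion curve ``(1 - exp(-2 r^3)) / r`` normalized to 1 at
    the knee.
    """
    gains = np.ones(st.size)
    if st.size < 2:
        return gains
    isi = np.maximum(np.diff(st), 1e-6)       # guard coincident spikes
    r = t_contr / isi                         # normalized rate per spike
    s_knee = (1.0 - np.exp(-2.0 * knee ** 3)) / knee
    above = r > knee
    rv = r[above]
    gains[1:][above] = ((1.0 - np.exp(-2.0 * rv ** 3)) / rv) / s_knee
    return gains


def simulate_force(spikes: SpikeTrainSet, bank: TwitchBank, fs: float,
                   mvc: MvcReference | None = None) -> SignalTrace:
    """Sum of gain-modulated twitch trains; %MVC when ``mvc`` is given."""
    if bank.n_units != spikes.n_units:
        raise ValueError("twitch bank and spike trains disagree on n_units")
    n = int(round(spikes.duration * fs))
    force = np.zeros(n)
    for i, st in enumerate(spikes.trains):
        if not st.size:
            continue
        gains = _rate_gains(st, bank.contraction_time[i], bank.gain_knee)
        train = np.zeros(n)
        b = np.minimum((st * fs).astype(int), n - 1)
        np.add.at(train, b, gains)
        k = twitch_kernel(bank.peak[i], bank.contraction_time[i], fs)
        force += sps.fftconvolve(train, k)[:n]
    if mvc is not None:
        if mvc.mvc_force <= 0:
            raise ValueError("MVC reference force must be positive")
        return SignalTrace(force / mvc.mvc_force * 100.0, fs, units="%MVC")
    return SignalTrace(force, fs, units="force-units")


def estimate_mvc(bank: TwitchBank, peak_rates=None, fs: float = 2048.0,
                 params: dict | None = None) -> MvcReference:
    """Force with all units active at their peak discharge rates.

    Regular trains at the per-unit peak rates (35 pps for the smallest
    unit declining to 25 pps for the largest, unless given) are summed
    through the same gain-modulated twitch model; the MVC force is the
    mean of the fused plateau.
    """
    p = (params or load_parameters())["force"]
    n_units = bank.n_units
    if peak_rates is None:
        x = np.zeros(1) if n_units == 1 else np.linspace(0.0, 1.0, n_units)
        peak_rates = interp_exp(*p["peak_rate_pps"], x)
    peak_rates = np.asarray(peak_rates, dtype=float)
    if np.all(peak_rates <= 0):
        raise ValueError("MVC undefined: all peak rates are zero")
    dur, settle = p["mvc_duration_s"], p["mvc_settle_s"]
    trains = [np.arange(0.0, dur, 1.0 / r) if r > 0 else np.empty(0)
              for r in peak_rates]
    spikes = SpikeTrainSet(trains=trains, duration=dur)
    f = simulate_force(spikes, bank, fs)
    mvc = float(f.samples[int(settle * fs):].mean())
    return MvcReference(mvc_force=mvc, peak_rates=peak_rates)
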