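"""Common synaptic input and per-neuron independent noise.

The drive to every motoneuron of the pool is the sum of a *common* term —
an offset plus 30 unit-spaced sinusoids (1..30 Hz) whose amplitudes
``G1_f`` are redrawn uniformly on [0, 1] for every repetition and scaled
by a global variability gain ``G2`` — and an *independent* term, white
Gaussian noise low-pass filtered below 100 Hz.  The noise gain is
calibrated so that, with the common variability switched off, the
inter-spike-interval coefficient of variation of active units falls in
the 10-30 % range typical of steady voluntary contractions.

Drive values are interpreted as currents in uA injected into the soma.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .params import load_parameters

__all__ = [
    "SignalTrace",
    "CommonInputSpec",
    "NoiseBank",
    "draw_sine_parameters",
    "generate_common_input",
    "generate_noise_bank",
    "calibrate_noise_gain",
    "CalibrationError",
]


class ConfigurationError(ValueError):
    """Invalid signal/run configuration."""


class CalibrationError(RuntimeError):
    """Noise-gain calibration failed to bracket the target ISI CoV."""


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled real-valued time series with units metadata."""

    samples: np.ndarray
    fs: float
    units: str = "drive-units"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def to_text(self, path) -> None:
        """Write (time, value) pairs as delimited text."""
        np.savetxt(path, np.column_stack([self.time, self.samples]),
                   header=f"fs={self.fs} units={self.units}", delimiter="\t")

    def save(self, path) -> None:
        """Write to a binary array container with fs/units metadata."""
        np.savez_compressed(path, samples=self.samples,
                            fs=np.float64(self.fs),
                            units=np.array(self.units))

    @classmethod
    def load(cls, path) -> "SignalTrace":
        with np.load(path, allow_pickle=False) as d:
            return cls(d["samples"], float(d["fs"]), str(d["units"]))


@dataclass
class CommonInputSpec:
    """Parameterization of the common synaptic input.

    ``gains``/``phases`` may be given explicitly (30 values each) or left
    None, in which case :func:`generate_common_input` draws them from its
    seed: gains uniform on [0, 1], phases uniform on [0, 2*pi).
    """

    g2: float
    offset: float
    duration: float = 30.0
    fs: float = 2048.0
    frequencies: np.ndarray = field(
        default_factory=lambda: np.arange(1, 31, dtype=float))
    gains: np.ndarray | None = None
    phases: np.ndarray | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size != 30 or not np.allclose(
                self.frequencies, np.arange(1, 31)):
            raise ConfigurationError(
                "common input uses exactly the 30 integer frequencies 1..30 Hz")
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigurationError("duration and fs must be positive")
        if self.g2 < 0:
            raise ConfigurationError("G2 must be non-negative")
        if self.offset < 0:
            raise ConfigurationError("offset must be non-negative")
        for name in ("gains", "phases"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (30,):
                    raise ConfigurationError(f"{name} must have 30 entries")
                setattr(self, name, v)
        if self.gains is not None and (
                np.any(self.gains < 0) or np.any(self.gains > 1)):
            raise ConfigurationError("sine gains must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class NoiseBank:
    """One independent filtered-Gaussian trace per motoneuron."""

    traces: np.ndarray  # shape (n_neurons, n_samples), drive units
    fs: float
    noise_gain: float
    cutoff: float = 100.0

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]


def draw_sine_parameters(rng: np.random.Generator):
    """Draw per-repetition sine gains (uniform [0,1]) and phases [0, 2*pi)."""
    gains = rng.uniform(0.0, 1.0, size=30)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=30)
    return gains, phases


def generate_common_input(spec: CommonInputSpec, seed=None) -> SignalTrace:
    """Realize the common input ``offset + G2 * sum_f G1_f sin(2 pi f t + phi_f)``.

    Deterministic given ``seed``; gains/phases fixed in ``spec`` override
    the draw.
    """
    rng = np.random.default_rng(seed)
    gains, phases = spec.gains, spec.phases
    if gains is None or phases is None:
        g, p = draw_sine_parameters(rng)
        gains = g if gains is None else gains
        phases = p if phases is None else phases
    t = np.arange(spec.n_samples) / spec.fs
    x = np.full(spec.n_samples, float(spec.offset))
    if spec.g2 > 0:
        # (n_samples,) accumulated over the 30 components
        arg = 2.0 * np.pi * np.outer(spec.frequencies, t)
        arg += phases[:, None]
        x = x + spec.g2 * (gains @ np.sin(arg))
    return SignalTrace(x, spec.fs, units="drive-units")


def generate_noise_bank(n_neurons: int, duration: float, fs: float,
                        noise_gain: float, seed=None,
                        cutoff: float | None = None,
                        order: int | None = None) -> NoiseBank:
    """Generate ``n_neurons`` independent low-pass-filtered Gaussian traces.

    White Gaussian noise is filtered below ``cutoff`` (zero-phase
    Butterworth) and rescaled so each trace has standard deviation
    ``noise_gain`` in drive units.
    """
    if n_neurons < 1:
        raise ConfigurationError("n_neurons must be >= 1")
    if duration <= 0 or fs <= 0:
        raise ConfigurationError("duration and fs must be positive")
    p = load_parameters()["input"]
    cutoff = p["noise_cutoff_hz"] if cutoff is None else cutoff
    order = p["noise_filter_order"] if order is None else order
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal((n_neurons, n))
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    traces = sps.sosfiltfilt(sos, white, axis=1)
    if noise_gain == 0.0:
        traces = np.zeros_like(traces)
    else:
        sd = traces.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        traces = traces / sd * noise_gain
    return NoiseBank(traces=traces, fs=fs, noise_gain=noise_gain, cutoff=cutoff)


def _isi_cov(spike_times, duration: float, min_rate: float = 8.0):
    """Median ISI CoV across steadily discharging units.

    Only units firing at ``min_rate`` or more contribute: the CoV
    statistic characterizes sustained discharge, and barely recruited
    units would dominate the median with threshold-crossing artifacts.
    """
    covs = []
    for st in spike_times:
        if st.size >= min_rate * duration:
            isi = np.diff(st)
            m = isi.mean()
            if m > 0:
                covs.append(isi.std() / m)
    return (float(np.median(covs)), len(covs)) if covs else (0.0, 0)


def calibrate_noise_gain(pool, offset: float,
                         target_cov_range=(0.10, 0.30),
                         seed=0, duration: float = 10.0,
                         gain_bounds=(1e-5, 5e-3),
                         max_iter: int = 12,
                         log: list | None = None) -> float:
    """Find a noise gain giving 10-30 % ISI CoV with common input off.

    Runs pilot simulations of ``pool`` driven by the constant ``offset``
    (G2 = 0) plus noise, and bisects the noise gain until the median ISI
    CoV of active units hits the midpoint of ``target_cov_range``.  The
    search is seeded and every trial is appended to ``log`` when given.
    """
    from .motoneuron import simulate_pool  # local import: avoid cycle

    prm = load_parameters()["input"]
    fs = prm["fs_hz"]
    target = 0.5 * (target_cov_range[0] + target_cov_range[1])
    spec = CommonInputSpec(g2=0.0, offset=offset, duration=duration, fs=fs)
    common = generate_common_input(spec, seed=seed)

    def cov_at(gain, trial):
        noise = generate_noise_bank(pool.n_units, duration, fs, gain,
                                    seed=(seed, 1000 + trial))
        spikes = simulate_pool(pool, common, noise)
        cov, n_active = _isi_cov(spikes.trains, duration)
        if log is not None:
            log.append({"gain": gain, "cov": cov, "n_active": n_active})
        return cov

    lo, hi = gain_bounds
    cov_lo, cov_hi = cov_at(lo, 0), cov_at(hi, 1)
    if not (cov_lo < target < cov_hi):
        raise CalibrationError(
            f"target CoV {target:.2f} not bracketed: "
            f"CoV({lo:g})={cov_lo:.3f}, CoV({hi:g})={cov_hi:.3f}")
    gain = lo
    for it in range(max_iter):
        gain = np.sqrt(lo * hi)  # geometric bisection, gain spans decades
        cov = cov_at(gain, 2 + it)
        if target_cov_range[0] + 0.03 <= cov <= target_cov_range[1] - 0.03:
            break
        if cov < target:
            lo = gain
        else:
            hi = gain
    return float(gain)
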