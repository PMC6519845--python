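"""Surface EMG synthesis: MUAP libraries, interference EMG and EMG_nc.

Each motor unit contributes a surface action-potential template built
from an analytic line-source description of its fibres: an intracellular
action potential propagates at 4 m/s from the innervation zone towards
the tendons and is detected by a bipolar electrode pair (10 mm
inter-electrode distance) placed midway between the innervation zone and
the fibre end.  The template of a fibre is the difference of the
potentials seen at the two electrodes; tissue filtering is modelled as a
depth-dependent exponential amplitude decay and temporal broadening of
the fibre potential.  All printed geometry/conductivity values of the
cylindrical volume conductor are retained on :class:`VolumeGeometry`
even where this simplified kernel uses only a subset of them.

Two signals are synthesized from the spike trains: the interference EMG
(sum of the motor unit action potential trains) and the no-cancellation
EMG, obtained by rectifying each template *before* the convolution, so
that positive and negative phases of different units can no longer
cancel.  Their difference is the amplitude-cancellation signal
``c(t) = EMG_nc(t) - |EMG(t)| >= 0``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .common_input import SignalTrace
from .motoneuron import SpikeTrainSet
from .params import interp_exp, load_parameters

__all__ = [
    "VolumeGeometry",
    "MUAPLibrary",
    "EMGPair",
    "build_muap_library",
    "synthesize_emg",
    "cancellation_signal",
    "cancellation_index",
    "GeometryError",
    "SilentRecordError",
]


class GeometryError(ValueError):
    """Motor unit territory incompatible with the conductor geometry."""


class SilentRecordError(RuntimeError):
    """Cancellation index undefined on a record without spikes."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Printed geometry/conductivity of the cylindrical volume conductor.

    Distances in mm, conductivities in S/m.
    """

    bone_radius: float = 7.5
    bone_conductivity: float = 0.02
    muscle_thickness: float = 27.5
    muscle_conductivity_radial: float = 0.1
    muscle_conductivity_longitudinal: float = 0.5
    subcutaneous_thickness: float = 1.0
    subcutaneous_conductivity: float = 0.05
    skin_thickness: float = 2.0
    skin_conductivity: float = 1.0
    fiber_length: float = 100.0
    iz_scatter: float = 10.0
    n_electrode_pairs: int = 15
    electrode_radius: float = 2.0
    inter_electrode_distance: float = 10.0

    @property
    def muscle_top(self) -> float:
        """Depth of the skin/fat-muscle interface below the surface (mm)."""
        return self.skin_thickness + self.subcutaneous_thickness

    @property
    def muscle_bottom(self) -> float:
        return self.muscle_top + self.muscle_thickness


@dataclass
class MUAPLibrary:
    """Per-unit surface action potential templates for one electrode pair."""

    templates: list                 # per-unit waveform arrays, mV
    fs: float
    innervation: np.ndarray
    depths: np.ndarray              # unit-centre distance from electrode, mm
    library_id: int
    rect_templates: list = field(default_factory=list)

    def __post_init__(self):
        if not self.rect_templates:
            self.rect_templates = [np.abs(p) for p in self.templates]

    @property
    def n_units(self) -> int:
        return len(self.templates)


@dataclass
class EMGPair:
    """Interference EMG and the paired no-cancellation EMG."""

    emg: SignalTrace
    emg_nc: SignalTrace

    @property
    def fs(self) -> float:
        return self.emg.fs


def _fiber_wave(u):
    # zero-mean biphasic base shape of a propagating fibre potential
    return u * np.exp(-u * u)


def build_muap_library(geom: VolumeGeometry, n_units: int, library_id: int,
                       seed=None, fs: float | None = None,
                       params: dict | None = None) -> MUAPLibrary:
    """Build the action-potential templates of one electrode pair.

    ``library_id`` (1..15) selects one of the electrode pairs around the
    limb; together with ``seed`` it determines the unit placement, so 15
    ids yield 15 distinct but reproducible libraries.  Innervation
    numbers are exponentially distributed over the printed 6-69 range
    (low-threshold units innervate fewest fibres); template amplitude
    decays exponentially with territory depth and the waveform broadens
    with depth (tissue low-pass filtering).
    """
    p = (params or load_parameters())["emg"]
    fs = p["fs_hz"] if fs is None else fs
    n_pairs = geom.n_electrode_pairs
    if not 1 <= library_id <= n_pairs:
        raise ValueError(f"library_id must be in 1..{n_pairs}")
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None
                                                        else seed, library_id]))

    key = 400 if n_units >= 250 else 100
    terr_r = p["territory_radius_mm"][key]
    terr_d = p["territory_depth_mm"][key]
    # anatomical variation between the 15 electrode sites around the limb:
    # each library sees the territory at a slightly different depth and
    # with a different effective tissue filtering
    jit = p["library_depth_jitter_mm"]
    terr_d = terr_d + rng.uniform(-jit, jit)
    width_factor = rng.uniform(*p["library_width_jitter"])
    if terr_d - terr_r >= geom.muscle_bottom or terr_d + terr_r <= geom.muscle_top:
        raise GeometryError("unit selection disc lies outside the muscle layer")

    x = np.zeros(1) if n_units == 1 else np.linspace(0.0, 1.0, n_units)
    lo, hi = p["innervation_range"]
    innerv = np.maximum(np.round(interp_exp(lo, hi, x)), 1).astype(int)
    # each action-potential set pairs units and innervation numbers anew
    # through a noisy rank: the marginal distribution (exponential over
    # 6-69) is preserved and innervation still grows with unit size on
    # average, but the exact association is site-specific
    keys = np.arange(n_units) + p["innervation_rank_jitter"] * n_units \
        * rng.standard_normal(n_units)
    rank = np.empty(n_units, dtype=int)
    rank[np.argsort(keys)] = np.arange(n_units)
    innerv = innerv[rank]

    v = p["conduction_velocity_m_s"]            # mm/ms
    half_fiber = geom.fiber_length / 2.0
    z_mid = half_fiber / 2.0                    # electrode pair centre
    ied = geom.inter_electrode_distance
    z_e = (z_mid - ied / 2.0, z_mid + ied / 2.0)
    w0, wk = p["sfap_width_ms"]
    lam = p["depth_lambda_mm"]
    r_u = p["unit_territory_radius_mm"]
    # support window sized so the broadest (deepest) fibre potential of
    # this library fits with its tails; keeps templates zero-mean
    w_max = (w0 + wk * (terr_d + terr_r + r_u)) * width_factor
    lead_ms = 2.0 + 3.5 * w_max
    span_ms = (z_e[1] + geom.iz_scatter / 2.0) / v + lead_ms + 3.5 * w_max
    n_t = int(round(max(span_ms, p["template_ms"]) * 1e-3 * fs))
    t_ms = np.arange(n_t) / fs * 1e3

    templates, depths = [], np.zeros(n_units)
    for i in range(n_units):
        # unit centre: uniform in the selection disc, restricted to muscle
        while True:
            r = terr_r * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            depth_c = terr_d + r * np.sin(ang)
            lateral_c = r * np.cos(ang)
            if geom.muscle_top < depth_c < geom.muscle_bottom:
                break
        depths[i] = np.hypot(depth_c, lateral_c)
        # fibres scattered in the unit territory
        nf = innerv[i]
        rr = r_u * np.sqrt(rng.uniform(size=nf))
        aa = rng.uniform(0, 2 * np.pi, size=nf)
        d_f = np.hypot(depth_c + rr * np.sin(aa), lateral_c + rr * np.cos(aa))
        z0 = rng.uniform(-geom.iz_scatter / 2.0, geom.iz_scatter / 2.0, size=nf)
        amp = np.exp(-d_f / lam)
        w = (w0 + wk * d_f) * width_factor
        t1 = (z_e[0] - z0) / v + lead_ms
        t2 = (z_e[1] - z0) / v + lead_ms
        wave = (amp[:, None] * (_fiber_wave((t_ms[None, :] - t1[:, None]) / w[:, None])
                                - _fiber_wave((t_ms[None, :] - t2[:, None]) / w[:, None])))
        templates.append(wave.sum(axis=0))
    return MUAPLibrary(templates=templates, fs=fs, innervation=innerv,
                       depths=depths, library_id=library_id)


def _unit_trains(spikes: SpikeTrainSet, fs: float, n: int) -> np.ndarray:
    trains = np.zeros((spikes.n_units, n))
    for i, st in enumerate(spikes.trains):
        if st.size:
            b = np.minimum((st * fs).astype(int), n - 1)
            np.add.at(trains[i], b, 1.0)
    return trains


def synthesize_emg(spikes: SpikeTrainSet, lib: MUAPLibrary,
                   fs: float | None = None) -> EMGPair:
    """Convolve spike trains with the templates (and their rectifications).

    ``emg = sum_i delta_i * p_i`` and ``emg_nc = sum_i delta_i * |p_i|``;
    both are linear in the spike trains.
    """
    fs = lib.fs if fs is None else fs
    if fs != lib.fs:
        raise ValueError("requested fs does not match the MUAP library fs")
    if lib.n_units != spikes.n_units:
        raise ValueError("library and spike train set disagree on n_units")
    n = int(round(spikes.duration * fs))
    trains = _unit_trains(spikes, fs, n)
    emg = np.zeros(n)
    emg_nc = np.zeros(n)
    for i in range(lib.n_units):
        if trains[i].any():
            emg += sps.fftconvolve(trains[i], lib.templates[i])[:n]
            emg_nc += sps.fftconvolve(trains[i], lib.rect_templates[i])[:n]
    return EMGPair(emg=SignalTrace(emg, fs, units="mV"),
                   emg_nc=SignalTrace(emg_nc, fs, units="mV"))


def cancellation_signal(pair: EMGPair) -> SignalTrace:
    """The cancellation term ``c(t) = EMG_nc(t) - |EMG(t)|`` (>= 0)."""
    c = pair.emg_nc.samples - np.abs(pair.emg.samples)
    # exact non-negativity up to FFT round-off
    return SignalTrace(np.maximum(c, 0.0), pair.fs, units="mV")


def cancellation_index(pair: EMGPair) -> float:
    """Mean cancellation relative to the no-cancellation amplitude, in [0, 1).

    Ratio of the averages of ``c(t)`` and ``EMG_nc(t)``; multiplied by
    100 it is the percent amplitude cancellation of a record.
    """
    denom = pair.emg_nc.samples.mean()
    if denom <= 0:
        raise SilentRecordError("cancellation index undefined: no activity")
    return float(cancellation_signal(pair).samples.mean() / denom)
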