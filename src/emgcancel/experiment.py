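"""Orchestration of the simulation grid.

A *condition* is a (pool size, common-input gain G2, offset) triple; the
full study grid crosses pool sizes {100, 400} with three G2 levels and
four offsets, excluding the one combination (highest G2, highest
offset) whose contraction level exceeds 20 %MVC — 22 conditions, each
repeated with fresh sine gains/phases, noise and action-potential
library per repetition.  A reduced desk-scale profile (100-unit pool,
fewer/shorter repetitions, 11 conditions) exercises the identical
pipeline at a fraction of the cost.

Seeding is hierarchical: a master seed spawns one stream per condition
and per repetition for each stochastic ingredient, so any repetition is
replayable in isolation from the manifest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .common_input import (CommonInputSpec, calibrate_noise_gain,
                           generate_common_input, generate_noise_bank)
from .emg import (VolumeGeometry, build_muap_library, cancellation_index,
                  synthesize_emg)
from .force import build_twitch_bank, estimate_mvc, simulate_force
from .motoneuron import (build_pool, cumulative_spike_train,
                         recruitment_summary, simulate_pool)
from .params import load_parameters
from .spectral import (band_summary, cancellation_r2_relation, line_power,
                       median_frequency, per_frequency_r2)
from .common_input import SignalTrace

__all__ = [
    "G2_LEVELS",
    "OFFSETS",
    "ConditionSpec",
    "build_grid",
    "run_condition",
    "run_grid",
    "summarize",
    "GridResult",
    "ExcludedConditionError",
]

G2_LEVELS = {"low": 5.7e-5, "medium": 1.5e-4, "high": 2.4e-4}
OFFSETS = (3.5e-3, 3.8e-3, 4.0e-3, 4.3e-3)


class ExcludedConditionError(ValueError):
    """The (highest G2, highest offset) combination is not simulated.

    It evokes contraction levels above 20 %MVC where the pool's
    discharge patterns are no longer realistic.
    """


@dataclass(frozen=True)
class ConditionSpec:
    n_units: int
    g2_level: str
    offset: float

    def __post_init__(self):
        if self.g2_level not in G2_LEVELS:
            raise ValueError(f"unknown G2 level {self.g2_level!r}")
        if self.offset not in OFFSETS:
            raise ValueError(f"offset {self.offset} not on the study grid")
        if self.g2_level == "high" and self.offset == max(OFFSETS):
            raise ExcludedConditionError(
                "highest G2 with highest offset is excluded from the grid "
                "(contraction level >20% MVC)")

    @property
    def g2(self) -> float:
        return G2_LEVELS[self.g2_level]

    @property
    def label(self) -> str:
        return f"n{self.n_units}-{self.g2_level}-off{self.offset:g}"


def build_grid(pool_sizes=(100, 400)) -> list:
    """All valid conditions: (3 G2 x 4 offsets - 1) per pool size."""
    grid = []
    for n in pool_sizes:
        for lvl in G2_LEVELS:
            for off in OFFSETS:
                try:
                    grid.append(ConditionSpec(n, lvl, off))
                except ExcludedConditionError:
                    continue
    return grid


@dataclass
class RepetitionResult:
    power_cst: np.ndarray
    power_emg: np.ndarray       # rectified interference EMG
    power_nc: np.ndarray
    cancellation: float
    median_freq_hz: float
    force_mean_pct: float
    force_sd_pct: float
    fraction_recruited: float
    mean_rate_pps: float
    library_id: int
    seed_entropy: tuple


@dataclass
class ConditionResult:
    spec: ConditionSpec
    reps: list

    def _stack(self, attr):
        return np.stack([getattr(r, attr) for r in self.reps])

    def r2_tables(self):
        """Per-frequency r^2 of CST power vs each EMG power across reps."""
        p_cst = self._stack("power_cst")
        return (per_frequency_r2(p_cst, self._stack("power_emg")),
                per_frequency_r2(p_cst, self._stack("power_nc")))

    def summary_row(self) -> dict:
        r2_emg, r2_nc = self.r2_tables()
        bands_emg = band_summary(r2_emg)
        bands_nc = band_summary(r2_nc)
        row = {
            "condition": self.spec.label,
            "n_units": self.spec.n_units,
            "g2_level": self.spec.g2_level,
            "g2": self.spec.g2,
            "offset": self.spec.offset,
            "n_reps": len(self.reps),
            "mvc_pct": np.mean([r.force_mean_pct for r in self.reps]),
            "force_sd_pct": np.mean([r.force_sd_pct for r in self.reps]),
            "cancellation": np.mean([r.cancellation for r in self.reps]),
            "median_freq_hz": np.mean([r.median_freq_hz for r in self.reps]),
            "fraction_recruited": np.mean([r.fraction_recruited
                                           for r in self.reps]),
            "mean_rate_pps": np.mean([r.mean_rate_pps for r in self.reps]),
            "r2_emg_mean": float(np.nanmean(r2_emg)),
            "r2_nc_mean": float(np.nanmean(r2_nc)),
        }
        for b in ("delta", "alpha", "beta"):
            row[f"r2_emg_{b}"] = bands_emg[b]
            row[f"r2_nc_{b}"] = bands_nc[b]
        return row


@dataclass
class GridResult:
    conditions: list                 # ConditionResult
    table: pd.DataFrame              # one summary row per condition
    manifest: dict


def _int_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_condition(spec: ConditionSpec, n_reps: int, duration: float,
                  master_seed: int, cond_index: int, noise_gain: float,
                  pool=None, bank=None, mvc=None,
                  geom: VolumeGeometry | None = None) -> ConditionResult:
    """Simulate one condition: ``n_reps`` independent repetitions.

    Every repetition redraws the sine gains G1 and phases, the noise and
    the action-potential library (electrode pair ``rep % 15 + 1``).
    """
    prm = load_parameters()
    fs = prm["input"]["fs_hz"]
    geom = geom or VolumeGeometry()
    pool = pool if pool is not None else build_pool(spec.n_units)
    bank = bank if bank is not None else build_twitch_bank(spec.n_units)
    mvc = mvc if mvc is not None else estimate_mvc(bank, fs=fs)

    reps = []
    for rep in range(n_reps):
        ent = (master_seed, cond_index, rep)
        cspec = CommonInputSpec(g2=spec.g2, offset=spec.offset,
                                duration=duration, fs=fs)
        common = generate_common_input(cspec, seed=list(ent) + [0])
        noise = generate_noise_bank(spec.n_units, duration, fs, noise_gain,
                                    seed=list(ent) + [1])
        spikes = simulate_pool(pool, common, noise)
        cst = cumulative_spike_train(spikes, fs)
        lib_id = rep % prm["emg"]["n_electrode_pairs"] + 1
        lib = build_muap_library(geom, spec.n_units, lib_id,
                                 seed=_int_seed(*ent, 2))
        pair = synthesize_emg(spikes, lib)
        force = simulate_force(spikes, bank, fs, mvc=mvc)
        # force statistics on the steady part only (contraction onset and
        # twitch-kernel warm-up excluded)
        settle = min(2.0, 0.25 * duration)
        f_steady = force.samples[int(settle * fs):]
        rect = SignalTrace(np.abs(pair.emg.samples), fs, units="mV")
        frac, rate = recruitment_summary(spikes)
        reps.append(RepetitionResult(
            power_cst=line_power(cst.as_trace()),
            power_emg=line_power(rect),
            power_nc=line_power(pair.emg_nc),
            cancellation=cancellation_index(pair),
            median_freq_hz=median_frequency(pair.emg),
            force_mean_pct=float(f_steady.mean()),
            force_sd_pct=float(f_steady.std()),
            fraction_recruited=frac,
            mean_rate_pps=rate,
            library_id=lib_id,
            seed_entropy=ent,
        ))
    return ConditionResult(spec=spec, reps=reps)


def run_grid(conditions=None, n_reps: int = 5, duration: float = 20.0,
             master_seed: int = 0, noise_gains: dict | None = None,
             calibration_seed: int | None = None,
             progress: bool = False) -> GridResult:
    """Run a set of conditions with hierarchical seeding.

    ``conditions`` defaults to the desk-scale profile: the 11-condition
    100-unit half of the study grid.  ``noise_gains`` maps pool size to
    a pre-calibrated noise gain; missing pool sizes are calibrated here
    (pilot simulations at the middle of the offset range, G2 = 0).
    """
    if conditions is None:
        conditions = build_grid(pool_sizes=(100,))
    if n_reps == 0:
        warnings.warn("n_reps=0: returning an empty result")
        return GridResult([], pd.DataFrame(), {"master_seed": master_seed,
                                               "conditions": []})
    prm = load_parameters()
    fs = prm["input"]["fs_hz"]
    noise_gains = dict(noise_gains or {})
    pools, banks, mvcs = {}, {}, {}
    calibration_log = {}
    for n in sorted({c.n_units for c in conditions}):
        pools[n] = build_pool(n)
        banks[n] = build_twitch_bank(n)
        mvcs[n] = estimate_mvc(banks[n], fs=fs)
        if n not in noise_gains:
            log = []
            noise_gains[n] = calibrate_noise_gain(
                pools[n], offset=float(np.mean(OFFSETS)),
                seed=(master_seed if calibration_seed is None
                      else calibration_seed), log=log)
            calibration_log[n] = log

    results = []
    for ci, spec in enumerate(conditions):
        if progress:
            print(f"[{ci + 1}/{len(conditions)}] {spec.label}")
        results.append(run_condition(
            spec, n_reps, duration, master_seed, ci,
            noise_gains[spec.n_units], pool=pools[spec.n_units],
            bank=banks[spec.n_units], mvc=mvcs[spec.n_units]))
    table = pd.DataFrame([c.summary_row() for c in results])
    manifest = {
        "master_seed": master_seed,
        "n_reps": n_reps,
        "duration_s": duration,
        "fs_hz": fs,
        "noise_gains": noise_gains,
        "calibration_log": calibration_log,
        "conditions": [{"index": i, "label": c.label,
                        "n_units": c.n_units, "g2": c.g2,
                        "offset": c.offset,
                        "rep_entropy": [[master_seed, i, r]
                                        for r in range(n_reps)]}
                       for i, c in enumerate(conditions)],
    }
    return GridResult(conditions=results, table=table, manifest=manifest)


def summarize(grid: GridResult) -> dict:
    """Headline statistics of a grid run.

    Percentages are on the 0-100 scale; rates in pulses per second.
    """
    t = grid.table
    if t.empty:
        raise ValueError("cannot summarize an empty grid result")
    low_g2 = t[t.g2_level == "low"]
    lowest = low_g2[low_g2.offset == min(OFFSETS)]
    highest = t[t.offset == max(OFFSETS)]
    matched = [o for o in OFFSETS
               if {"low", "high"} <= set(t[t.offset == o].g2_level)]
    gain_pts = np.mean(
        [t[(t.offset == o) & (t.g2_level == "high")].fraction_recruited.mean()
         - t[(t.offset == o) & (t.g2_level == "low")].fraction_recruited.mean()
         for o in matched]) * 100 if matched else np.nan
    r, scatter = cancellation_r2_relation(t.cancellation.to_numpy(),
                                          t.r2_emg_mean.to_numpy())
    return {
        "recruited_lowest_offset_low_g2_pct": lowest.fraction_recruited.mean() * 100,
        "rate_lowest_offset_low_g2_pps": lowest.mean_rate_pps.mean(),
        "recruited_highest_offset_pct": highest.fraction_recruited.mean() * 100,
        "rate_highest_offset_pps": highest.mean_rate_pps.mean(),
        "recruitment_gain_g2_pts": gain_pts,
        "median_freq_low_g2_hz": low_g2.median_freq_hz.mean(),
        "force_sd_low_g2_max_pct": low_g2.force_sd_pct.max(),
        "cancellation_min_pct": t.cancellation.min() * 100,
        "cancellation_max_pct": t.cancellation.max() * 100,
        "r2_nc_grand_mean": t.r2_nc_mean.mean(),
        "cancellation_r2_pearson_r": r,
        "cancellation_r2_scatter": scatter,
    }
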