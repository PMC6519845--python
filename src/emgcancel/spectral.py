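"""Spectral analysis of the neural drive, EMG signals and force.

The common input imposes sinusoids at the 30 integer frequencies
1..30 Hz, so the power of each component is read from the periodogram
bin at that exact frequency (records must span an integer number of
seconds so integer frequencies fall on bins).  Associations between the
drive (cumulative spike train) and the EMG signals are quantified per
frequency as the squared Pearson correlation of line powers across the
repetitions of a condition, then averaged over the delta (1-5 Hz),
alpha (6-15 Hz) and beta (16-30 Hz) bands.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats

from .common_input import SignalTrace

__all__ = [
    "line_power",
    "per_frequency_r2",
    "band_summary",
    "median_frequency",
    "cancellation_r2_relation",
    "BANDS",
]

BANDS = {"delta": (1, 5), "alpha": (6, 15), "beta": (16, 30)}


def line_power(x: SignalTrace, freqs=None) -> np.ndarray:
    """Periodogram line power at the requested integer frequencies.

    The mean is removed first; the value returned for a pure sinusoid of
    amplitude A at an on-bin frequency is A^2/2 (one-sided 'spectrum'
    scaling of a boxcar periodogram).
    """
    freqs = np.arange(1, 31) if freqs is None else np.asarray(freqs)
    n = x.samples.size
    dur = n / x.fs
    if abs(dur - round(dur)) > 1e-9:
        raise ValueError("record must span an integer number of seconds "
                         "so integer frequencies fall on periodogram bins")
    f, p = sps.periodogram(x.samples - x.samples.mean(), fs=x.fs,
                           window="boxcar", scaling="spectrum")
    df = f[1] - f[0]
    idx = np.round(freqs / df).astype(int)
    if np.any(idx >= f.size):
        raise ValueError("requested frequency above Nyquist")
    return p[idx]


def per_frequency_r2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation across repetitions, per frequency.

    ``a`` and ``b`` are (n_reps, n_freqs) line-power matrices.  A
    frequency with zero variance in either signal is returned as NaN
    (undefined) and is excluded from band means downstream.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("power matrices must have the same shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 repetitions")
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        if a[:, j].std() == 0 or b[:, j].std() == 0:
            continue
        r = stats.pearsonr(a[:, j], b[:, j]).statistic
        out[j] = r * r
    return out


def band_summary(r2: np.ndarray, freqs=None) -> dict:
    """Mean r^2 in the delta, alpha and beta bands (NaNs excluded)."""
    freqs = np.arange(1, 31) if freqs is None else np.asarray(freqs)
    r2 = np.asarray(r2, float)
    out = {}
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs <= hi)
        vals = r2[sel]
        out[name] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
    return out


def median_frequency(raw_emg: SignalTrace, nperseg_s: float = 1.0) -> float:
    """Frequency splitting the Welch power of the raw EMG in half.

    Welch spectrum with 1 s segments and 50 % overlap, 0 to Nyquist.
    """
    nper = int(round(nperseg_s * raw_emg.fs))
    f, pxx = sps.welch(raw_emg.samples - raw_emg.samples.mean(),
                       fs=raw_emg.fs, nperseg=min(nper, raw_emg.samples.size))
    c = np.cumsum(pxx)
    if c[-1] <= 0:
        return 0.0
    return float(np.interp(0.5 * c[-1], c, f))


def cancellation_r2_relation(cancellation: np.ndarray, mean_r2: np.ndarray):
    """Pearson r between condition-mean cancellation and mean CST-EMG r^2.

    Returns ``(r, table)`` where the table pairs the inputs row-wise.
    """
    cancellation = np.asarray(cancellation, float)
    mean_r2 = np.asarray(mean_r2, float)
    if cancellation.size != mean_r2.size or cancellation.size < 5:
        raise ValueError("need >= 5 paired condition values")
    r = stats.pearsonr(cancellation, mean_r2).statistic
    return float(r), np.column_stack([cancellation, mean_r2])
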