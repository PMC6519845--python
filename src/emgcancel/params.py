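"""Access to the frozen model parameter file.

All numerical constants of the model (printed values of the published
model plus the values fixed by the pilot tuning scripts) live in
``parameters.yaml`` inside the package.  Code reads them through
:func:`load_parameters` so a single versioned file defines a run.
"""
from __future__ import annotations

import copy
import functools
from importlib import resources

import yaml


@functools.lru_cache(maxsize=1)
def _raw() -> dict:
    text = resources.files("emgcancel").joinpath("parameters.yaml").read_text()
    return yaml.safe_load(text)


def load_parameters() -> dict:
    """Return a deep copy of the frozen parameter dictionary."""
    return copy.deepcopy(_raw())


def interp_exp(lo: float, hi: float, x):
    """Exponential interpolation between ``lo`` (x=0) and ``hi`` (x=1).

    Used for every across-pool parameter profile: equal steps in x give
    equal ratios, i.e. many units near the low-threshold end of the range.
    """
    import numpy as np

    x = np.asarray(x, dtype=float)
    return lo * (hi / lo) ** x
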