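"""Experimental-design arithmetic of the emulated paradigm.

Small closed-form helpers for the bookkeeping quantities of the study
design: supertrial counts, epoch sample counts after downsampling,
presentations per image across runs, and mean trial durations from
stimulus/ISI timings.
"""
from __future__ import annotations

import math

import numpy as np

from .containers import ParameterError


def supertrials_per_category(n_trials: int, group_size: int = 2) -> int:
    """Number of supertrials obtained by averaging groups of trials.

    24 trials grouped in pairs give 12 supertrials per category.
    """
    if n_trials % group_size != 0:
        raise ParameterError(
            f"{n_trials} trials not divisible by group size {group_size}")
    return n_trials // group_size


def epoch_sample_count(tmin_ms: float = -100.0, tmax_ms: float = 1001.0,
                       acq_srate: float = 1000.0,
                       target_srate: float = 100.0) -> int:
    """Samples per epoch after segmenting at the acquisition rate and decimating.

    An epoch from -100 to 1001 ms at 1000 Hz holds 1102 samples; keeping
    every 10th sample (100 Hz) leaves 111.
    """
    if acq_srate <= 0 or target_srate <= 0:
        raise ParameterError("sampling rates must be positive")
    n_acq = int(math.floor((tmax_ms - tmin_ms) * acq_srate / 1000.0)) + 1
    factor = int(round(acq_srate / target_srate))
    return int(math.ceil(n_acq / factor))


def presentations_per_image(n_runs: int, presentations_per_run: int) -> int:
    """Total stimulus presentations per image across runs (runs x per-run)."""
    return n_runs * presentations_per_run


def mean_trial_duration_ms(stim_ms: float, isi_ms) -> float:
    """Mean trial duration = stimulus duration + mean inter-stimulus interval.

    ``isi_ms`` may be a scalar or an iterable of equiprobable ISI values
    (jittered designs draw the ISI uniformly from a discrete set).
    """
    isi = np.atleast_1d(np.asarray(isi_ms, dtype=float))
    return float(stim_ms + isi.mean())
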