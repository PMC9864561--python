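"""RSA-based MEG-fMRI fusion.

A time-resolved series of MEG RDMs (one per time point, from trial-averaged
channel patterns) is correlated with a region's fMRI RDM, yielding a fusion
time course that localizes when the region's representational geometry is
expressed in the MEG signal. Computed per subject; group averaging and
inference live in :mod:`stmvpa.stats`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet, ParameterError, ValidationError
from .rdm import RDM, compute_rdm, correlate_rdms


@dataclass
class FusionTimeCourse:
    """Pearson correlation between MEG and fMRI RDMs per time point."""

    values: np.ndarray
    times: np.ndarray
    roi_label: str = ""


def meg_rdm_series(epochs: EpochSet) -> list:
    """One RDM per time point from trial-averaged channel patterns.

    Per time point, the condition pattern is the mean over trials of the
    channel vector for that category; dissimilarity is 1 - Pearson r.
    Expects a single depiction (subset with ``epochs.select`` first).
    """
    if len(np.unique(epochs.depiction)) > 1:
        raise ValidationError("meg_rdm_series expects a single depiction")
    cats, means = epochs.category_means()     # (n_cat, n_channels, n_times)
    return [compute_rdm(means[:, :, t], cats) for t in range(epochs.n_times)]


def fusion_timecourse(meg_rdms, fmri_rdm: RDM, times,
                      roi_label: str = "") -> FusionTimeCourse:
    """Correlate each time point's MEG RDM with a region's fMRI RDM."""
    times = np.asarray(times, dtype=float)
    if len(meg_rdms) != times.size:
        raise ParameterError("need one MEG RDM per time point")
    vals = np.array([correlate_rdms(m, fmri_rdm) for m in meg_rdms])
    return FusionTimeCourse(vals, times, roi_label)
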