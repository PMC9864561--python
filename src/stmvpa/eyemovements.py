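"""Gaze-based trial quality control.

Velocity-threshold microsaccade detection (median-based elliptic criterion
with a 5-sample moving-window differentiator), amplitude-based epoch
dropping and on-stimulus flagging, and the per-subject contamination /
exclusion rule. Monocular traces (one x/y pair) are assumed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig

from .containers import GazeEpoch, ParameterError, ValidationError

#: epochs containing any movement larger than this cannot be on-stimulus
DROP_AMPLITUDE_DEG = 3.0
#: saccades larger than this count as eye movements on the stimulus
ON_STIMULUS_AMPLITUDE_DEG = 1.5
#: subjects with more than this fraction of contaminated trials are excluded
EXCLUSION_RATIO = 0.05


@dataclass
class Saccade:
    onset_sample: int
    offset_sample: int
    amplitude: float        # degrees of visual angle
    peak_velocity: float    # degrees / s

    def __post_init__(self):
        if self.onset_sample >= self.offset_sample:
            raise ValidationError("saccade onset must precede offset")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")


def detrend_gaze(epoch: GazeEpoch, highpass_hz: float = 0.1) -> GazeEpoch:
    """Remove slow drifts with a first-order high-pass (zero-phase)."""
    b, a = spsig.butter(1, highpass_hz / (epoch.srate / 2.0), "highpass")
    return GazeEpoch(spsig.filtfilt(b, a, epoch.x),
                     spsig.filtfilt(b, a, epoch.y),
                     epoch.srate, epoch.planted_saccades)


def _velocity(pos: np.ndarray, srate: float) -> np.ndarray:
    """5-sample moving-window differentiator; edge velocities set to zero."""
    v = np.zeros_like(pos)
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) * srate / 6.0
    return v


def detect_microsaccades(gaze: GazeEpoch, lambda_threshold: float = 6.0,
                         min_duration_samples: int = 3) -> list:
    """Velocity-threshold (micro)saccade detection.

    Velocities from the 5-sample differentiator are compared against an
    elliptic threshold of ``lambda_threshold`` times a median-based
    velocity SD per axis; runs of suprathreshold samples lasting at least
    ``min_duration_samples`` become saccades. The amplitude is the
    positional displacement between onset and offset (so detections are
    invariant to constant position offsets).
    """
    if gaze.n_samples < min_duration_samples + 4:
        raise ValidationError("epoch too short for saccade detection")
    vx = _velocity(gaze.x, gaze.srate)
    vy = _velocity(gaze.y, gaze.srate)
    sx = np.sqrt(np.median(vx ** 2) - np.median(vx) ** 2)
    sy = np.sqrt(np.median(vy ** 2) - np.median(vy) ** 2)
    sx = max(sx, 1e-12)
    sy = max(sy, 1e-12)
    crit = (vx / (lambda_threshold * sx)) ** 2 \
        + (vy / (lambda_threshold * sy)) ** 2 > 1.0
    saccades = []
    i = 0
    n = crit.size
    while i < n:
        if crit[i]:
            j = i
            while j + 1 < n and crit[j + 1]:
                j += 1
            if j - i + 1 >= min_duration_samples:
                amp = float(np.hypot(gaze.x[j] - gaze.x[i],
                                     gaze.y[j] - gaze.y[i]))
                pv = float(np.max(np.hypot(vx[i:j + 1], vy[i:j + 1])))
                saccades.append(Saccade(i, j, amp, pv))
            i = j + 1
        else:
            i += 1
    return saccades


@dataclass
class TrialQC:
    """Per-trial gaze QC outcome."""

    dropped: np.ndarray        # epoch contained a movement > 3 degrees
    on_stimulus: np.ndarray    # retained epoch with a saccade > 1.5 degrees
    saccades: list             # detector output per epoch


def filter_and_label(epochs, lambda_threshold: float = 6.0,
                     min_duration_samples: int = 3,
                     drop_amplitude_deg: float = DROP_AMPLITUDE_DEG,
                     flag_amplitude_deg: float = ON_STIMULUS_AMPLITUDE_DEG) -> TrialQC:
    """Apply the amplitude rules to a list of gaze epochs.

    Epochs containing any detected movement larger than 3 degrees are
    dropped from consideration (such movements cannot have landed on the
    stimulus); remaining epochs are flagged on-stimulus when any saccade
    exceeds 1.5 degrees.
    """
    n = len(epochs)
    dropped = np.zeros(n, dtype=bool)
    flagged = np.zeros(n, dtype=bool)
    all_sacc = []
    for i, ep in enumerate(epochs):
        sacc = detect_microsaccades(ep, lambda_threshold, min_duration_samples)
        all_sacc.append(sacc)
        amps = np.array([s.amplitude for s in sacc]) if sacc else np.zeros(0)
        if np.any(amps > drop_amplitude_deg):
            dropped[i] = True
        elif np.any(amps > flag_amplitude_deg):
            flagged[i] = True
    return TrialQC(dropped, flagged, all_sacc)


def contamination_ratio(on_stimulus_flags, n_experimental_trials: int,
                        exclusion_ratio: float = EXCLUSION_RATIO):
    """Fraction of experimental trials contaminated by on-stimulus movements.

    Returns (ratio, excluded); the subject is excluded when strictly more
    than ``exclusion_ratio`` (default 5%) of the experimental (non-catch)
    trials are contaminated.
    """
    if n_experimental_trials <= 0:
        raise ParameterError("n_experimental_trials must be positive")
    ratio = float(np.sum(on_stimulus_flags)) / n_experimental_trials
    return ratio, ratio > exclusion_ratio
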