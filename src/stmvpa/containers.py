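"""Core data containers shared across the pipeline.

Conventions enforced package-wide: time is in milliseconds relative to
stimulus onset, decoding accuracies are in percent, voxel grid coordinates
are 0-based integers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The three depiction types of the emulated study design.
DEPICTIONS = ("photo", "drawing", "sketch")


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class ValidationError(ValueError):
    """Input data violate a structural contract."""


def default_times(tmin_ms: float = -100.0, tmax_ms: float = 1000.0,
                  srate: float = 100.0) -> np.ndarray:
    """Uniform epoch time grid in ms (default: 111 samples, -100..1000 ms)."""
    step = 1000.0 / srate
    n = int(round((tmax_ms - tmin_ms) / step)) + 1
    return tmin_ms + step * np.arange(n)


@dataclass
class GroundTruth:
    """Known per-depiction category patterns used to generate all synthetic data.

    Each depiction's pattern matrix is a weighted sum of a component shared
    across depictions and a depiction-specific component,

        P_d = sqrt(s) * C + sqrt(1 - s) * S_d,

    with ``s = shared_fraction`` so that the expected correlation between
    corresponding category patterns of two depictions equals ``s``.
    """

    patterns: dict  # depiction -> (n_categories, n_features) array
    shared_fraction: float
    noise_sd: float
    seed: int
    peak_ms: float = 100.0

    def __post_init__(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ParameterError(
                f"shared_fraction must be in [0, 1], got {self.shared_fraction}")
        for dep, mat in self.patterns.items():
            if not np.all(np.isfinite(mat)):
                raise ValidationError(f"non-finite pattern for depiction {dep!r}")

    @property
    def n_categories(self) -> int:
        return next(iter(self.patterns.values())).shape[0]

    @property
    def n_features(self) -> int:
        return next(iter(self.patterns.values())).shape[1]

    def response_profile(self, times_ms: np.ndarray) -> np.ndarray:
        """Transient evoked amplitude profile: an alpha function.

        Zero before stimulus onset, rises to 1 at ``peak_ms`` and decays
        exponentially afterwards — a stylized evoked response.
        """
        t = np.asarray(times_ms, dtype=float)
        prof = np.zeros_like(t)
        pos = t > 0
        x = t[pos] / self.peak_ms
        prof[pos] = x * np.exp(1.0 - x)
        return prof


@dataclass
class EpochSet:
    """Trials x channels x time array with category and depiction labels."""

    data: np.ndarray          # (n_trials, n_channels, n_times)
    category: np.ndarray      # (n_trials,) integer labels
    depiction: np.ndarray     # (n_trials,) strings
    times: np.ndarray         # ms relative to stimulus onset
    srate: float              # Hz

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.category = np.asarray(self.category)
        self.depiction = np.asarray(self.depiction)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("data must be trials x channels x time")
        if self.data.shape[0] != self.category.shape[0] or \
                self.data.shape[0] != self.depiction.shape[0]:
            raise ValidationError("label length does not match number of trials")
        if self.data.shape[2] != self.times.shape[0]:
            raise ValidationError("times length does not match data")
        if np.isnan(self.data).any():
            raise ValidationError("epoch data contain NaNs")
        step = 1000.0 / self.srate
        diffs = np.diff(self.times)
        if self.times.size > 1 and (
                np.any(diffs <= 0) or not np.allclose(diffs, step, rtol=1e-6)):
            raise ValidationError(
                f"times must increase uniformly at {step:g} ms (srate {self.srate} Hz)")
        for cat in np.unique(self.category):
            for dep in np.unique(self.depiction):
                n = np.sum((self.category == cat) & (self.depiction == dep))
                if 0 < n < 2:
                    raise ValidationError(
                        f"cell (category={cat}, depiction={dep}) has {n} trial; "
                        "need >= 2")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, depiction: str) -> "EpochSet":
        """Subset of trials belonging to one depiction type."""
        m = self.depiction == depiction
        if not m.any():
            raise ValidationError(f"no trials with depiction {depiction!r}")
        return EpochSet(self.data[m], self.category[m], self.depiction[m],
                        self.times, self.srate)

    def category_means(self) -> tuple:
        """(sorted category ids, (n_categories, n_channels, n_times) means)."""
        cats = np.unique(self.category)
        means = np.stack([self.data[self.category == c].mean(axis=0)
                          for c in cats])
        return cats, means


@dataclass
class BetaSet:
    """Run-wise GLM beta patterns: runs x conditions x voxels.

    Condition ordering is identical across runs. ``voxel_coords`` are
    0-based integer grid coordinates (rows unique); ROI-style sets without a
    spatial grid use a synthetic 1-D coordinate column.
    """

    betas: np.ndarray            # (n_runs, n_conditions, n_voxels)
    voxel_coords: np.ndarray     # (n_voxels, 3) int
    roi_label: str = ""
    condition_ids: np.ndarray | None = None
    signal_mask: np.ndarray | None = None  # set by grid-mode simulators

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValidationError("betas must be runs x conditions x voxels")
        if self.betas.shape[0] < 2:
            raise ParameterError("need at least 2 runs")
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.voxel_coords.shape != (self.betas.shape[2], 3):
            raise ValidationError("voxel_coords must be (n_voxels, 3)")
        if len(np.unique(self.voxel_coords, axis=0)) != self.voxel_coords.shape[0]:
            raise ValidationError("voxel_coords must be unique")
        if self.condition_ids is None:
            self.condition_ids = np.arange(self.betas.shape[1])
        else:
            self.condition_ids = np.asarray(self.condition_ids)

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]


@dataclass
class GazeEpoch:
    """Horizontal/vertical gaze position (degrees of visual angle) per sample."""

    x: np.ndarray
    y: np.ndarray
    srate: float
    planted_saccades: list = field(default_factory=list)  # (onset_sample, amplitude_deg)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("gaze traces must be finite")
        if self.srate <= 0:
            raise ParameterError("srate must be positive")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]
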