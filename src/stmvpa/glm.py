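"""First-level fMRI modeling with per-voxel HRF selection.

The design convolves condition boxcars with each kernel of a 20-member HRF
library (a parameterized double-gamma family spanning peak times of roughly
4-8 s with two undershoot depths; a loader hook accepts an externally
supplied kernel array instead). The GLM is fit once per kernel by ordinary
least squares, and each voxel's betas are taken from the kernel with the
minimum mean residual for that voxel. Also provides outlier-volume
screening/interpolation and aCompCor-style nuisance-component extraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ParameterError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HRF library

@dataclass
class HRFLibrary:
    """Candidate hemodynamic response kernels, peak-normalized to 1.

    ``kernels`` is (n_kernels, n_samples) sampled every ``dt_s`` seconds;
    indices are 1-based to match the convention of numbered HRF libraries.
    """

    kernels: np.ndarray
    dt_s: float
    peak_times_s: np.ndarray | None = None

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=float)
        peaks = self.kernels.max(axis=1)
        if np.any(peaks <= 0) or not np.allclose(peaks, 1.0):
            raise ValidationError("each kernel must be peak-normalized to 1")

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    def kernel(self, index: int) -> np.ndarray:
        """Kernel by 1-based index."""
        if not 1 <= index <= self.n_kernels:
            raise ParameterError(
                f"hrf index {index} outside 1..{self.n_kernels}")
        return self.kernels[index - 1]

    @classmethod
    def from_array(cls, kernels: np.ndarray, dt_s: float) -> "HRFLibrary":
        """Loader hook for an externally supplied kernel matrix."""
        k = np.asarray(kernels, dtype=float)
        return cls(k / k.max(axis=1, keepdims=True), dt_s)


def _double_gamma(t: np.ndarray, peak_s: float, undershoot_ratio: float,
                  undershoot_delay_s: float = 10.0) -> np.ndarray:
    pos = sps.gamma.pdf(t, a=peak_s + 1.0, scale=1.0)
    neg = sps.gamma.pdf(t, a=peak_s + undershoot_delay_s + 1.0, scale=1.0)
    h = pos / pos.max() - undershoot_ratio * neg / neg.max()
    return h / h.max()


def default_hrf_library(tr_s: float = 1.5, duration_s: float = 30.0,
                        n_peaks: int = 10,
                        undershoot_ratios=(0.1, 0.35)) -> HRFLibrary:
    """20 double-gamma variants: 10 peak times (4-8 s) x 2 undershoot depths."""
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    peaks = np.linspace(4.0, 8.0, n_peaks)
    kernels = [_double_gamma(t, p, r) for r in undershoot_ratios for p in peaks]
    return HRFLibrary(np.asarray(kernels), tr_s,
                      np.tile(peaks, len(undershoot_ratios)))


# ---------------------------------------------------------------------------
# design matrix

def build_design(events: pd.DataFrame, hrf: np.ndarray, n_scans: int,
                 tr_s: float, dt_s: float | None = None) -> np.ndarray:
    """One column per condition: boxcar(onset, duration) convolved with hrf.

    ``events`` needs columns onset, duration (seconds) and condition;
    columns are ordered by sorted unique condition label. The boxcar is
    built on the HRF's time step (default: the TR) and sampled at scan
    times. Construction is linear in events: two events of one condition
    yield the sum of the shifted responses.
    """
    if dt_s is None:
        dt_s = tr_s
    required = {"onset", "duration", "condition"}
    if not required.issubset(events.columns):
        raise ValidationError(f"events must have columns {sorted(required)}")
    total_s = n_scans * tr_s
    onset = events["onset"].to_numpy(dtype=float)
    dur = events["duration"].to_numpy(dtype=float)
    if np.any(onset < 0) or np.any(onset + dur > total_s + 1e-9):
        raise ValidationError("events fall outside the scan duration")
    hrf = np.asarray(hrf, dtype=float)
    n_fine = int(np.ceil(total_s / dt_s)) + 1
    conds = np.unique(events["condition"].to_numpy())
    osf = tr_s / dt_s
    scan_idx = np.round(np.arange(n_scans) * osf).astype(int)
    x = np.zeros((n_scans, conds.size))
    for j, c in enumerate(conds):
        box = np.zeros(n_fine)
        sel = events["condition"].to_numpy() == c
        for o, d in zip(onset[sel], dur[sel]):
            i0 = int(np.round(o / dt_s))
            i1 = max(i0 + 1, int(np.round((o + d) / dt_s)))
            box[i0:i1] += 1.0
        x[:, j] = np.convolve(box, hrf)[scan_idx]
    return x


# ---------------------------------------------------------------------------
# HRF-selected GLM

@dataclass
class GLMFit:
    """Per-run GLM result with the per-voxel winning HRF.

    ``chosen_hrf_index`` (1-based) minimizes the mean squared residual for
    each voxel; ``betas`` holds the condition betas from that kernel's fit.
    """

    betas: np.ndarray             # (n_conditions, n_voxels)
    chosen_hrf_index: np.ndarray  # (n_voxels,)
    mean_residual: np.ndarray     # (n_hrfs, n_voxels)
    condition_ids: np.ndarray


def _check_rank(x: np.ndarray):
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify near-collinear columns via the QR diagonal
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-8 * diag.max()).tolist()
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear column indices: {bad}")


def fit_hrf_selected_glm(bold: np.ndarray, events: pd.DataFrame,
                         hrf_library: HRFLibrary,
                         nuisance: np.ndarray | None = None,
                         tr_s: float = 1.5) -> GLMFit:
    """OLS per HRF kernel; betas taken from each voxel's best kernel.

    ``bold`` is (n_scans, n_voxels). The design holds one regressor per
    condition plus optional nuisance columns and an intercept. The winning
    kernel per voxel minimizes the mean squared residual.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    if not np.all(np.isfinite(bold)):
        raise ValidationError("bold contains non-finite values")
    n_scans, n_vox = bold.shape
    conds = np.unique(events["condition"].to_numpy())
    n_cond = conds.size
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValidationError("nuisance rows must match n_scans")
        if nuisance.shape[1] >= n_scans - n_cond:
            raise ParameterError("too many nuisance columns for n_scans")
    all_betas = np.empty((hrf_library.n_kernels, n_cond, n_vox))
    resid = np.empty((hrf_library.n_kernels, n_vox))
    for k in range(hrf_library.n_kernels):
        task = build_design(events, hrf_library.kernels[k], n_scans, tr_s,
                            dt_s=hrf_library.dt_s)
        parts = [task]
        if nuisance is not None:
            parts.append(nuisance)
        parts.append(np.ones((n_scans, 1)))
        x = np.column_stack(parts)
        _check_rank(x)
        coef, *_ = np.linalg.lstsq(x, bold, rcond=None)
        res = bold - x @ coef
        all_betas[k] = coef[:n_cond]
        resid[k] = np.mean(res ** 2, axis=0)
    chosen = np.argmin(resid, axis=0)
    betas = all_betas[chosen, :, np.arange(n_vox)].T
    return GLMFit(betas, chosen + 1, resid, conds)


# ---------------------------------------------------------------------------
# outlier volumes

def detect_outlier_volumes(bold: np.ndarray,
                           motion_params: np.ndarray | None = None,
                           intensity_factor: float = 30.0,
                           displacement_mm: float = 0.5):
    """Flag and interpolate artifact volumes.

    A volume is an outlier when its framewise mean absolute intensity
    difference exceeds ``intensity_factor`` times the overall mean of the
    differences, or when the frame-to-frame displacement exceeds
    ``displacement_mm`` on any motion axis. Flagged volumes are replaced by
    linear interpolation between the nearest clean neighbors (edge
    outliers take the nearest clean volume). ``bold`` has time first:
    (n_volumes, ...); returns (outlier indices, cleaned series).
    """
    bold = np.asarray(bold, dtype=float)
    n_vol = bold.shape[0]
    if n_vol < 3:
        raise ParameterError("need at least 3 volumes")
    flat = bold.reshape(n_vol, -1)
    d = np.mean(np.abs(np.diff(flat, axis=0)), axis=1)   # diff t -> vol t+1
    scaled = d / d.mean() if d.mean() > 0 else d
    out = np.zeros(n_vol, dtype=bool)
    out[1:] |= scaled > intensity_factor
    if motion_params is not None:
        mp = np.atleast_2d(np.asarray(motion_params, dtype=float))
        disp = np.abs(np.diff(mp, axis=0))
        out[1:] |= np.any(disp > displacement_mm, axis=1)
    idx = np.flatnonzero(out)
    clean = flat.copy()
    good = np.flatnonzero(~out)
    if idx.size and good.size:
        for v in idx:
            left = good[good < v]
            right = good[good > v]
            if left.size and right.size:
                l, r = left[-1], right[0]
                w = (v - l) / (r - l)
                clean[v] = (1 - w) * flat[l] + w * flat[r]
            else:
                nearest = left[-1] if left.size else right[0]
                logger.warning("edge outlier volume %d replaced by nearest "
                               "clean volume %d", v, nearest)
                clean[v] = flat[nearest]
    return idx, clean.reshape(bold.shape)


# ---------------------------------------------------------------------------
# nuisance components

def extract_noise_components(noise_timeseries: np.ndarray,
                             n_components: int) -> np.ndarray:
    """Top principal components of standardized noise-voxel series.

    ``noise_timeseries`` is (n_scans, n_noise_voxels), e.g. white-matter
    and CSF voxels; returns an orthonormal (n_scans, n_components) matrix
    of nuisance regressors (aCompCor style).
    """
    ts = np.atleast_2d(np.asarray(noise_timeseries, dtype=float))
    if ts.shape[1] < n_components:
        raise ParameterError("fewer noise voxels than requested components")
    z = ts - ts.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    z = z / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_components > rank:
        raise ParameterError(
            f"requested {n_components} components but rank is {rank}")
    return u[:, :n_components]
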