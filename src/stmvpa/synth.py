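"""Synthetic-data generators with known ground truth.

Every pipeline stage (decoding, fusion, GLM, eye-movement QC) is exercised
against data produced here, so each generator records the parameters needed
for parameter-recovery tests. The emulated design: 48 object categories in
three depiction types (photo, drawing, sketch), MEG-like epochs of
306 channels x 111 time points at 100 Hz (-100..1000 ms), run-wise fMRI
beta patterns, BOLD series driven by a known HRF, and gaze traces with
planted saccades.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (DEPICTIONS, BetaSet, EpochSet, GazeEpoch,
                         GroundTruth, ParameterError, ValidationError,
                         default_times)


def _orthonormal_mixing(rng: np.random.Generator, n_out: int,
                        n_in: int) -> np.ndarray:
    """Random mixing map with orthonormal columns (or rows if n_out < n_in).

    Orthonormality keeps injected signal energy comparable across seeds.
    """
    a = rng.standard_normal((max(n_out, n_in), min(n_out, n_in)))
    q, _ = np.linalg.qr(a)
    return q if n_out >= n_in else q.T


def make_ground_truth(n_categories: int, n_features: int,
                      shared_fraction: float, seed: int,
                      noise_sd: float = 1.0,
                      peak_ms: float = 100.0) -> GroundTruth:
    """Draw per-depiction category patterns with controlled overlap.

    ``P_d = sqrt(s) * common + sqrt(1 - s) * specific_d`` with all components
    iid standard normal, so corresponding patterns of two depictions have
    expected correlation ``s = shared_fraction``.
    """
    if n_categories < 3:
        raise ParameterError("need at least 3 categories")
    if n_features < 2:
        raise ParameterError("need at least 2 features")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ParameterError(
            f"shared_fraction must be in [0, 1], got {shared_fraction}")
    rng = np.random.default_rng(seed)
    common = rng.standard_normal((n_categories, n_features))
    patterns = {}
    for dep in DEPICTIONS:
        specific = rng.standard_normal((n_categories, n_features))
        patterns[dep] = (np.sqrt(shared_fraction) * common
                         + np.sqrt(1.0 - shared_fraction) * specific)
    return GroundTruth(patterns=patterns, shared_fraction=shared_fraction,
                       noise_sd=noise_sd, seed=seed, peak_ms=peak_ms)


def _random_spd(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random SPD channel covariance with unit mean diagonal."""
    a = rng.standard_normal((n, 2 * n))
    c = a @ a.T / (2 * n)
    return c / np.mean(np.diag(c))


def simulate_epochs(gt: GroundTruth, n_trials_per_cell: int,
                    n_channels: int = 306, times: np.ndarray | None = None,
                    seed: int = 0, depictions=DEPICTIONS,
                    noise_sd: float | None = None,
                    channel_cov: str | np.ndarray | None = None) -> EpochSet:
    """Simulate evoked epochs: profile(t) * (mixing @ pattern) + noise.

    The channels x features mixing map is a fixed random orthonormal matrix
    per seed; noise is iid Gaussian per trial/channel/time unless a channel
    covariance is requested (``channel_cov="random"`` or an SPD matrix), in
    which case spatially correlated noise exercises noise normalization.
    """
    if n_trials_per_cell % 2 != 0:
        raise ParameterError(
            f"n_trials_per_cell must be even, got {n_trials_per_cell}")
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    srate = 1000.0 / (times[1] - times[0])
    rng = np.random.default_rng(seed)
    mixing = _orthonormal_mixing(rng, n_channels, gt.n_features)
    profile = gt.response_profile(times)
    sd = gt.noise_sd if noise_sd is None else noise_sd

    chol = None
    if channel_cov is not None:
        cov = _random_spd(rng, n_channels) if isinstance(channel_cov, str) \
            else np.asarray(channel_cov, dtype=float)
        chol = np.linalg.cholesky(cov)

    data, cats, deps = [], [], []
    for dep in depictions:
        proj = gt.patterns[dep] @ mixing.T          # (n_cat, n_channels)
        for c in range(gt.n_categories):
            signal = proj[c][:, None] * profile[None, :]
            noise = rng.standard_normal(
                (n_trials_per_cell, n_channels, times.size)) * sd
            if chol is not None:
                noise = np.einsum("ij,tjk->tik", chol, noise)
            data.append(signal[None] + noise)
            cats.extend([c] * n_trials_per_cell)
            deps.extend([dep] * n_trials_per_cell)
    return EpochSet(np.concatenate(data), np.array(cats), np.array(deps),
                    times, srate)


def simulate_staged_epochs(pattern_stages, profiles, n_trials_per_category: int,
                           n_channels: int, times: np.ndarray,
                           noise_sd: float, seed: int,
                           depiction: str = "photo") -> EpochSet:
    """Epochs whose representational geometry changes over time.

    ``pattern_stages`` is a list of (n_categories x n_features) matrices and
    ``profiles`` the matching list of temporal amplitude profiles (one value
    per time point); the signal is the profile-weighted sum of the mixed
    stage patterns. Used to plant distinct geometries at distinct latencies
    (e.g., an early and a late processing stage).
    """
    if len(pattern_stages) != len(profiles):
        raise ParameterError("one profile per pattern stage required")
    times = np.asarray(times, dtype=float)
    srate = 1000.0 / (times[1] - times[0])
    rng = np.random.default_rng(seed)
    n_cat = pattern_stages[0].shape[0]
    if len({p.shape[1] for p in pattern_stages}) != 1:
        raise ParameterError("all stages must share the feature dimension")
    # one sensor array: a single mixing map shared by all stages
    mixing = _orthonormal_mixing(rng, n_channels, pattern_stages[0].shape[1])
    signal = np.zeros((n_cat, n_channels, times.size))
    for patterns, profile in zip(pattern_stages, profiles):
        proj = patterns @ mixing.T
        signal += proj[:, :, None] * np.asarray(profile)[None, None, :]
    data, cats = [], []
    for c in range(n_cat):
        noise = rng.standard_normal(
            (n_trials_per_category, n_channels, times.size)) * noise_sd
        data.append(signal[c][None] + noise)
        cats.extend([c] * n_trials_per_category)
    deps = np.array([depiction] * len(cats))
    return EpochSet(np.concatenate(data), np.array(cats), deps, times, srate)


def simulate_betas(gt: GroundTruth, n_runs: int, n_voxels: int | None = None,
                   noise_sd: float = 1.0, seed: int = 0,
                   depiction: str = "photo", roi_label: str = "sim",
                   grid_shape: tuple | None = None,
                   blob_center: tuple | None = None,
                   blob_radius: float = 2.0) -> BetaSet:
    """Run-wise beta patterns: voxel mixing of category patterns + run noise.

    ROI mode (``n_voxels``): every voxel carries signal. Grid mode
    (``grid_shape``): signal voxels form a compact spherical blob of radius
    ``blob_radius`` around ``blob_center`` inside a larger null grid, for
    searchlight recovery tests; the blob membership is recorded in
    ``signal_mask``.
    """
    if n_runs < 2:
        raise ParameterError("need at least 2 runs")
    # the voxel mixing depends on the seed only (one brain across depictions);
    # run noise additionally depends on the depiction, so cross-decoding
    # between depictions simulated with the same seed is meaningful
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng([seed, DEPICTIONS.index(depiction)])
    patterns = gt.patterns[depiction]
    n_cat = patterns.shape[0]

    if grid_shape is not None:
        grid_shape = tuple(int(s) for s in grid_shape)
        if blob_center is None:
            blob_center = tuple(s // 2 for s in grid_shape)
        coords = np.indices(grid_shape).reshape(3, -1).T
        d2 = np.sum((coords - np.asarray(blob_center)) ** 2, axis=1)
        blob = d2 <= blob_radius ** 2
        lo = np.asarray(blob_center) - blob_radius
        hi = np.asarray(blob_center) + blob_radius
        if np.any(lo < 0) or np.any(hi > np.asarray(grid_shape) - 1):
            raise ParameterError("grid smaller than blob: enlarge grid_shape "
                                 "or shrink blob_radius")
        n_vox = coords.shape[0]
        signal = np.zeros((n_cat, n_vox))
        mixing = _orthonormal_mixing(rng, int(blob.sum()), gt.n_features)
        signal[:, blob] = patterns @ mixing.T
        betas = signal[None] + noise_rng.standard_normal(
            (n_runs, n_cat, n_vox)) * noise_sd
        return BetaSet(betas, coords, roi_label=roi_label,
                       signal_mask=blob)

    if n_voxels is None:
        raise ParameterError("give either n_voxels or grid_shape")
    mixing = _orthonormal_mixing(rng, n_voxels, gt.n_features)
    signal = patterns @ mixing.T
    betas = signal[None] + noise_rng.standard_normal(
        (n_runs, n_cat, n_voxels)) * noise_sd
    coords = np.column_stack([np.arange(n_voxels),
                              np.zeros(n_voxels, int),
                              np.zeros(n_voxels, int)])
    return BetaSet(betas, coords, roi_label=roi_label)


def simulate_bold(events: pd.DataFrame, hrf_index, true_betas: np.ndarray,
                  noise_sd: float, seed: int = 0, hrf_library=None,
                  tr_s: float = 1.5, n_scans: int | None = None) -> np.ndarray:
    """BOLD series per voxel: design(hrf_index) @ true_betas + noise.

    ``hrf_index`` is a 1-based index into the HRF library, scalar or one per
    voxel (enabling per-voxel HRF-selection recovery tests). Returns an
    (n_scans, n_voxels) array.
    """
    from .glm import build_design, default_hrf_library

    if hrf_library is None:
        hrf_library = default_hrf_library(tr_s=tr_s)
    true_betas = np.atleast_2d(np.asarray(true_betas, dtype=float))
    n_vox = true_betas.shape[1]
    ev = events.sort_values("onset").reset_index(drop=True)
    ends = (ev["onset"] + ev["duration"]).to_numpy()
    if np.any(ev["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
        raise ValidationError("events overlap in time")
    if n_scans is None:
        n_scans = int(np.ceil(ends.max() / tr_s)) + hrf_library.kernels.shape[1]
    idx = np.broadcast_to(np.asarray(hrf_index, dtype=int), (n_vox,))
    rng = np.random.default_rng(seed)
    bold = np.empty((n_scans, n_vox))
    for h in np.unique(idx):
        x = build_design(events, hrf_library.kernel(int(h)), n_scans, tr_s,
                         dt_s=hrf_library.dt_s)
        cols = idx == h
        bold[:, cols] = x @ true_betas[:, cols]
    bold += rng.standard_normal(bold.shape) * noise_sd
    return bold


def _minimum_jerk(n: int) -> np.ndarray:
    """Smooth 0->1 displacement profile (minimum-jerk polynomial)."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def simulate_gaze(n_trials: int, srate: float = 500.0,
                  fixation_noise_sd: float = 0.02,
                  saccade_specs: dict | None = None,
                  epoch_duration_ms: float = 600.0,
                  seed: int = 0) -> list:
    """Gaze epochs with optional planted saccades.

    ``saccade_specs`` maps trial index -> list of (onset_sample,
    amplitude_deg). Planted saccades follow a minimum-jerk displacement
    profile (duration scaling with amplitude, a stylized main sequence)
    whose peak velocity far exceeds velocity-threshold detection criteria
    at realistic fixation noise.
    """
    if saccade_specs is None:
        saccade_specs = {}
    for specs in saccade_specs.values():
        for _, amp in specs:
            if amp < 0:
                raise ParameterError("saccade amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(epoch_duration_ms * srate / 1000.0))
    epochs = []
    for t in range(n_trials):
        x = rng.standard_normal(n_samples) * fixation_noise_sd
        y = rng.standard_normal(n_samples) * fixation_noise_sd
        planted = []
        for onset, amp in saccade_specs.get(t, []):
            dur_ms = 20.0 + 8.0 * amp
            n_sac = max(4, int(round(dur_ms * srate / 1000.0)))
            if onset + n_sac > n_samples:
                raise ParameterError("planted saccade exceeds epoch length")
            theta = rng.uniform(0, 2 * np.pi)
            disp = amp * _minimum_jerk(n_sac)
            x[onset:onset + n_sac] += np.cos(theta) * disp
            x[onset + n_sac:] += np.cos(theta) * amp
            y[onset:onset + n_sac] += np.sin(theta) * disp
            y[onset + n_sac:] += np.sin(theta) * amp
            planted.append((onset, amp))
        epochs.append(GazeEpoch(x, y, srate, planted))
    return epochs


def make_trial_sequence(n_stimuli: int, catch_spacing: tuple = (4, 6),
                        catch_proportion: float | None = None,
                        seed: int = 0) -> list:
    """Stimulus/catch trial sequence.

    Either inserts a catch trial after every ``catch_spacing`` = (lo, hi)
    stimulus presentations (spacing drawn uniformly), or — if
    ``catch_proportion`` is given — spaces catch trials to hit that overall
    proportion. Both parameterizations are exposed; they are not forced to
    agree.
    """
    rng = np.random.default_rng(seed)
    seq = []
    if catch_proportion is not None:
        if not 0.0 < catch_proportion < 1.0:
            raise ParameterError("catch_proportion must be in (0, 1)")
        spacing = max(1, int(round((1.0 - catch_proportion) / catch_proportion)))
        lo = hi = spacing
    else:
        lo, hi = catch_spacing
    remaining = n_stimuli
    while remaining > 0:
        k = min(int(rng.integers(lo, hi + 1)), remaining)
        seq.extend(["stim"] * k)
        remaining -= k
        if remaining > 0 or catch_proportion is not None:
            seq.append("catch")
    return seq
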