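"""Pairwise linear decoding of object category from activity patterns.

Covers the time-resolved (MEG-style) scheme — supertrial averaging,
leave-one-supertrial-out cross-validation with linear SVMs, averaging over
all category pairs and assignment repetitions — the run-wise (fMRI-style)
leave-one-run-out scheme for ROIs and searchlights, cross-decoding between
depiction types (both train/test directions averaged), and temporal
generalization. Chance level of the pairwise scheme is 50%.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.covariance import LedoitWolf
from sklearn.svm import SVC

from .containers import EpochSet, BetaSet, ParameterError, ValidationError

logger = logging.getLogger(__name__)

CHANCE_PERCENT = 50.0


# ---------------------------------------------------------------------------
# containers

@dataclass
class SupertrialSet:
    """Supertrials (averages of ``group_size`` same-category trials).

    One set per assignment repetition; within a repetition every trial is
    used in exactly one supertrial.
    """

    data: np.ndarray        # (n_supertrials, n_channels, n_times)
    category: np.ndarray
    times: np.ndarray
    srate: float
    assignment_repetition: int = 0

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def by_category(self) -> dict:
        return {c: self.data[self.category == c]
                for c in np.unique(self.category)}


@dataclass
class TimeCourse:
    """One accuracy (%) or correlation value per time point."""

    values: np.ndarray
    times: np.ndarray
    chance: float | None = CHANCE_PERCENT
    n_decisions: int = 0


@dataclass
class TGMatrix:
    """Train-time x test-time decoding accuracies (%)."""

    values: np.ndarray
    times: np.ndarray


@dataclass
class AccuracyMap:
    """Per-voxel accuracies (%) on an integer grid; NaN where not computed."""

    values: np.ndarray        # (n_voxels,)
    voxel_coords: np.ndarray  # (n_voxels, 3)
    grid_shape: tuple
    mask: np.ndarray          # bool, True where an accuracy was computed

    def to_volume(self) -> np.ndarray:
        vol = np.full(self.grid_shape, np.nan)
        vol[tuple(self.voxel_coords.T)] = self.values
        return vol


# ---------------------------------------------------------------------------
# noise normalization

def noise_normalize(epochs: EpochSet, shrinkage="ledoit") -> EpochSet:
    """Whiten channels by the inverse square root of the residual covariance.

    Residuals are epochs minus their (category, depiction) cell mean, pooled
    over trials and time points. The covariance is shrinkage-regularized
    (Ledoit-Wolf by default, or a fixed shrinkage weight toward the scaled
    identity); whitening is applied to every trial and time point, leaving
    the shape unchanged.
    """
    resid = epochs.data.copy()
    for cat in np.unique(epochs.category):
        for dep in np.unique(epochs.depiction):
            m = (epochs.category == cat) & (epochs.depiction == dep)
            if m.any():
                resid[m] -= resid[m].mean(axis=0)
    samples = resid.transpose(0, 2, 1).reshape(-1, epochs.n_channels)
    if shrinkage == "ledoit":
        cov = LedoitWolf(assume_centered=True).fit(samples).covariance_
    else:
        emp = samples.T @ samples / samples.shape[0]
        gamma = float(shrinkage)
        cov = (1 - gamma) * emp + gamma * np.trace(emp) / emp.shape[0] * \
            np.eye(emp.shape[0])
    w, v = np.linalg.eigh(cov)
    if w.min() <= 1e-12 * w.max():
        raise np.linalg.LinAlgError(
            "residual channel covariance is singular; increase the shrinkage "
            "weight (e.g. shrinkage=0.05) or provide more trials")
    whitener = (v / np.sqrt(w)) @ v.T
    data = np.einsum("ij,tjs->tis", whitener, epochs.data)
    return EpochSet(data, epochs.category, epochs.depiction, epochs.times,
                    epochs.srate)


# ---------------------------------------------------------------------------
# supertrials

def make_supertrials(epochs: EpochSet, group_size: int = 2,
                     n_repetitions: int = 5, seed: int = 0) -> list:
    """Average disjoint groups of same-category trials into supertrials.

    Returns one :class:`SupertrialSet` per assignment repetition; trial
    group assignment is random, uses every trial exactly once within a
    repetition, and differs across repetitions. 24 trials with pairs give
    12 supertrials per category.
    """
    if len(np.unique(epochs.depiction)) > 1:
        raise ValidationError("make_supertrials expects a single depiction; "
                              "use epochs.select(...) first")
    cats = np.unique(epochs.category)
    for c in cats:
        n = int(np.sum(epochs.category == c))
        if n % group_size != 0:
            raise ParameterError(
                f"category {c}: {n} trials not divisible by group_size "
                f"{group_size}")
    rng = np.random.default_rng(seed)
    sets = []
    for rep in range(n_repetitions):
        data, labels = [], []
        for c in cats:
            idx = np.flatnonzero(epochs.category == c)
            idx = rng.permutation(idx)
            groups = idx.reshape(-1, group_size)
            data.append(epochs.data[groups].mean(axis=1))
            labels.extend([c] * groups.shape[0])
        sets.append(SupertrialSet(np.concatenate(data), np.array(labels),
                                  epochs.times, epochs.srate, rep))
    return sets


# ---------------------------------------------------------------------------
# decoding engines

def _fit_svm(x, y, C):
    clf = SVC(kernel="linear", C=C)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            clf.fit(x, y)
    except Exception as exc:  # non-convergence or degenerate fold
        warnings.warn(f"classifier failed on a fold ({exc}); fold skipped")
        logger.warning("skipped fold: %s", exc)
        return None
    return clf


def _timecourse_engine(train_sets, test_sets, C, full_matrix):
    """Shared engine for within/cross time-resolved decoding and TGMs.

    ``train_sets`` and ``test_sets`` are parallel lists of SupertrialSets
    (identical objects for within-decoding). Fold f leaves out supertrial f
    of each class; training patterns come from ``train_sets`` and test
    patterns from ``test_sets``.
    """
    n_times = train_sets[0].n_times
    shape = (n_times, n_times) if full_matrix else (n_times,)
    correct = np.zeros(shape)
    total = np.zeros(shape)
    for st_train, st_test in zip(train_sets, test_sets):
        if not np.array_equal(np.unique(st_train.category),
                              np.unique(st_test.category)):
            raise ValidationError("train/test category sets differ")
        by_tr = st_train.by_category()
        by_te = st_test.by_category()
        cats = sorted(by_tr)
        n_super = min(len(by_tr[c]) for c in cats)
        if n_super < 3:
            raise ParameterError("need >= 3 supertrials per category")
        for a in range(len(cats)):
            for b in range(a + 1, len(cats)):
                xa, xb = by_tr[cats[a]], by_tr[cats[b]]
                ta, tb = by_te[cats[a]], by_te[cats[b]]
                for f in range(n_super):
                    train = np.concatenate([np.delete(xa, f, axis=0),
                                            np.delete(xb, f, axis=0)])
                    y = np.array([0] * (len(xa) - 1) + [1] * (len(xb) - 1))
                    test = np.stack([ta[f], tb[f]])        # (2, ch, T)
                    for t in range(n_times):
                        clf = _fit_svm(train[:, :, t], y, C)
                        if clf is None:
                            continue
                        if full_matrix:
                            flat = test.transpose(0, 2, 1).reshape(-1,
                                                                   test.shape[1])
                            pred = clf.predict(flat).reshape(2, n_times)
                            correct[t] += (pred == np.array([[0], [1]])).sum(0)
                            total[t] += 2
                        else:
                            pred = clf.predict(test[:, :, t])
                            correct[t] += int(pred[0] == 0) + int(pred[1] == 1)
                            total[t] += 2
    with np.errstate(invalid="ignore"):
        acc = 100.0 * correct / total
    return acc, int(total.flat[0])


def pairwise_decode_timecourse(supertrial_sets, C: float = 1.0) -> TimeCourse:
    """Time-resolved pairwise decoding accuracy.

    Per time point and unordered category pair, a linear SVM is evaluated
    leave-one-supertrial-out (one supertrial per class left out per fold);
    accuracies are averaged over pairs, folds and assignment repetitions.
    Chance is 50%.
    """
    if len(supertrial_sets) == 0:
        raise ParameterError("no supertrial sets given")
    acc, n_dec = _timecourse_engine(supertrial_sets, supertrial_sets, C,
                                    full_matrix=False)
    return TimeCourse(acc, supertrial_sets[0].times, CHANCE_PERCENT, n_dec)


def temporal_generalization(supertrial_sets, C: float = 1.0) -> TGMatrix:
    """Train at each time point, test at all time points.

    The diagonal reproduces :func:`pairwise_decode_timecourse` exactly when
    computed from the same supertrial sets (identical folds and fits).
    """
    acc, _ = _timecourse_engine(supertrial_sets, supertrial_sets, C,
                                full_matrix=True)
    return TGMatrix(acc, supertrial_sets[0].times)


def cross_decode_timecourse(sets_a, sets_b, C: float = 1.0) -> TimeCourse:
    """Time-resolved cross-decoding between two depiction types.

    Folds mirror the within-type scheme; accuracies for the two train/test
    directions (A->B and B->A) are averaged, so the result is symmetric in
    its arguments by construction.
    """
    acc_ab, n1 = _timecourse_engine(sets_a, sets_b, C, full_matrix=False)
    acc_ba, n2 = _timecourse_engine(sets_b, sets_a, C, full_matrix=False)
    return TimeCourse((acc_ab + acc_ba) / 2.0, sets_a[0].times,
                      CHANCE_PERCENT, n1 + n2)


def _loro_accuracy(train_betas, test_betas, C):
    """Leave-one-run-out pairwise accuracy; train/test may differ (cross)."""
    n_runs, n_cond = train_betas.shape[:2]
    correct = total = 0
    for a in range(n_cond):
        for b in range(a + 1, n_cond):
            for r in range(n_runs):
                tr = [d for rr in range(n_runs) if rr != r
                      for d in (train_betas[rr, a], train_betas[rr, b])]
                y = np.tile([0, 1], n_runs - 1)
                clf = _fit_svm(np.asarray(tr), y, C)
                if clf is None:
                    continue
                pred = clf.predict(np.stack([test_betas[r, a],
                                             test_betas[r, b]]))
                correct += int(pred[0] == 0) + int(pred[1] == 1)
                total += 2
    return 100.0 * correct / total if total else np.nan


def pairwise_decode_roi(betas: BetaSet, C: float = 1.0) -> float:
    """Leave-one-run-out pairwise SVM accuracy (%) for one ROI.

    Training uses the pattern vectors of all runs but one, testing the held
    out run; accuracies are averaged over condition pairs and folds.
    """
    if betas.n_runs < 2:
        raise ParameterError("need at least 2 runs")
    return _loro_accuracy(betas.betas, betas.betas, C)


def cross_decode_roi(a: BetaSet, b: BetaSet, C: float = 1.0) -> float:
    """ROI cross-decoding between depictions, both directions averaged."""
    if a.betas.shape != b.betas.shape or \
            not np.array_equal(a.condition_ids, b.condition_ids):
        raise ValidationError("BetaSets must share runs, conditions and grid")
    return (_loro_accuracy(a.betas, b.betas, C)
            + _loro_accuracy(b.betas, a.betas, C)) / 2.0


# ---------------------------------------------------------------------------
# searchlight

def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets with Euclidean norm <= radius (center included).

    At radius 4 the sphere holds 257 voxels.
    """
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    r = int(np.floor(radius))
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1].reshape(3, -1).T
    return g[np.sum(g ** 2, axis=1) <= radius ** 2]


def _searchlight_engine(a: BetaSet, b: BetaSet | None, radius_voxels, C):
    offsets = sphere_offsets(radius_voxels)
    coords = a.voxel_coords
    index = {tuple(c): i for i, c in enumerate(coords)}
    values = np.full(coords.shape[0], np.nan)
    for ci, center in enumerate(coords):
        neigh = [index[t] for t in map(tuple, center + offsets) if t in index]
        if len(neigh) < 2:
            logger.warning("searchlight at %s has <2 voxels; skipped",
                           tuple(center))
            continue
        sub_a = a.betas[:, :, neigh]
        if b is None:
            values[ci] = _loro_accuracy(sub_a, sub_a, C)
        else:
            sub_b = b.betas[:, :, neigh]
            values[ci] = (_loro_accuracy(sub_a, sub_b, C)
                          + _loro_accuracy(sub_b, sub_a, C)) / 2.0
    return values


def _smooth_map(values, coords, grid_shape, fwhm_mm, voxel_size_mm):
    """Mask-aware Gaussian smoothing of an accuracy map."""
    sigma = fwhm_mm / voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vol = np.zeros(grid_shape)
    msk = np.zeros(grid_shape)
    good = np.isfinite(values)
    vol[tuple(coords[good].T)] = values[good]
    msk[tuple(coords[good].T)] = 1.0
    num = ndimage.gaussian_filter(vol, sigma, truncate=4.0)
    den = ndimage.gaussian_filter(msk, sigma, truncate=4.0)
    with np.errstate(invalid="ignore"):
        sm = num / den
    out = values.copy()
    out[good] = sm[tuple(coords[good].T)]
    return out


def searchlight_decode(betas: BetaSet, radius_voxels: float = 4,
                       smoothing_fwhm_mm: float = 5.0,
                       voxel_size_mm: float = 2.5,
                       C: float = 1.0) -> AccuracyMap:
    """Whole-grid searchlight decoding.

    For every in-mask center, the pattern vector holds the betas of all
    in-mask voxels within ``radius_voxels`` (Euclidean distance in voxel
    units, center included), decoded with the leave-one-run-out pairwise
    scheme. The accuracy map is optionally Gaussian-smoothed afterwards
    (set ``smoothing_fwhm_mm=0`` to skip); kernels are truncated at 4 SD.
    """
    if betas.n_voxels == 0:
        raise ParameterError("empty mask")
    values = _searchlight_engine(betas, None, radius_voxels, C)
    grid_shape = tuple(betas.voxel_coords.max(axis=0) + 1)
    if smoothing_fwhm_mm:
        values = _smooth_map(values, betas.voxel_coords, grid_shape,
                             smoothing_fwhm_mm, voxel_size_mm)
    return AccuracyMap(values, betas.voxel_coords, grid_shape,
                       np.isfinite(values))


def cross_decode_searchlight(a: BetaSet, b: BetaSet, radius_voxels: float = 4,
                             smoothing_fwhm_mm: float = 5.0,
                             voxel_size_mm: float = 2.5,
                             C: float = 1.0) -> AccuracyMap:
    """Searchlight cross-decoding between depictions (directions averaged)."""
    if not np.array_equal(a.voxel_coords, b.voxel_coords):
        raise ValidationError("BetaSets must share the voxel grid")
    values = _searchlight_engine(a, b, radius_voxels, C)
    grid_shape = tuple(a.voxel_coords.max(axis=0) + 1)
    if smoothing_fwhm_mm:
        values = _smooth_map(values, a.voxel_coords, grid_shape,
                             smoothing_fwhm_mm, voxel_size_mm)
    return AccuracyMap(values, a.voxel_coords, grid_shape,
                       np.isfinite(values))


def cross_decode(data_a, data_b, mode: str = "timecourse", **kwargs):
    """Dispatch cross-decoding by mode: timecourse, roi, or searchlight."""
    if mode == "timecourse":
        return cross_decode_timecourse(data_a, data_b, **kwargs)
    if mode == "roi":
        return cross_decode_roi(data_a, data_b, **kwargs)
    if mode == "searchlight":
        return cross_decode_searchlight(data_a, data_b, **kwargs)
    raise ValueError(f"unknown mode {mode!r}")
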