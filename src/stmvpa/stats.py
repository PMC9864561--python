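"""Nonparametric inference for group-level time courses and maps.

Sign-permutation tests (exact enumeration when feasible), Benjamini-
Hochberg FDR, cluster-size permutation correction with optional
cross-test maxima, conjunction maps, bootstrap peak-latency confidence
intervals and differences, and TOST equivalence testing.

Subject-level effects passed to the permutation tests must already be
centered on their null value (accuracy - 50, correlation - 0).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ParameterError, ValidationError


# ---------------------------------------------------------------------------
# sign permutation

@dataclass
class PermTestResult:
    p_values: np.ndarray
    observed: np.ndarray
    n_permutations: int
    tail: str
    exhaustive: bool = False


def _sign_matrix(n_sub: int, n_perm: int, rng: np.random.Generator):
    """Sign-flip matrix with the identity (all +1) as row 0.

    Enumerates all 2**n_sub patterns exactly when n_perm allows it.
    """
    if 2 ** n_sub <= n_perm:
        bits = (np.arange(2 ** n_sub)[:, None] >> np.arange(n_sub)) & 1
        return (1.0 - 2.0 * bits), True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    signs[0] = 1.0
    return signs, False


def sign_permutation_test(subject_effects: np.ndarray, n_perm: int = 10000,
                          tail: str = "one",
                          seed: int | None = None) -> PermTestResult:
    """Group test by randomly flipping the sign of per-subject effects.

    The null distribution is the group mean under sign flips at the
    participant level; the observed (unflipped) pattern is always part of
    the null, so the smallest attainable p is 1/n_permutations. When
    ``n_perm`` covers all 2**n_subjects patterns the enumeration is exact.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    eff = np.asarray(subject_effects, dtype=float)
    if eff.ndim == 1:
        eff = eff[:, None]
    eff = eff.reshape(eff.shape[0], -1)
    n_sub = eff.shape[0]
    if n_sub < 2:
        raise ParameterError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n_sub, n_perm, rng)
    null = signs @ eff / n_sub               # (n_perm_eff, P)
    obs = null[0]
    if tail == "one":
        p = np.mean(null >= obs[None, :], axis=0)
    elif tail == "two":
        p = np.mean(np.abs(null) >= np.abs(obs)[None, :], axis=0)
    else:
        raise ParameterError("tail must be 'one' or 'two'")
    return PermTestResult(p, obs, signs.shape[0], tail, exhaustive)


# ---------------------------------------------------------------------------
# FDR

def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR control; returns the rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    mask, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return mask.reshape(p.shape)


# ---------------------------------------------------------------------------
# cluster permutation

@dataclass
class ClusterResult:
    """Suprathreshold clusters and their permutation p-values.

    ``clusters`` holds flat index arrays into the tested points;
    ``significant`` flags clusters whose size reaches the (1 - alpha)
    tail of the null maximum-cluster-size distribution.
    """

    clusters: list
    cluster_p: np.ndarray
    significant: np.ndarray
    forming_p: float
    alpha: float
    null_max_sizes: np.ndarray
    point_p: np.ndarray = None

    @property
    def significant_mask(self) -> np.ndarray:
        m = np.zeros(self.point_p.shape, dtype=bool)
        for idx, sig in zip(self.clusters, self.significant):
            if sig:
                m.flat[idx] = True
        return m


def _structure(adjacency: str):
    if adjacency == "time":
        return np.ones(3, dtype=bool)
    if adjacency == "tgm":           # 4-connectivity in train x test time
        return ndimage.generate_binary_structure(2, 1)
    if adjacency == "volume":        # 26-connectivity
        return np.ones((3, 3, 3), dtype=bool)
    raise ParameterError("adjacency must be 'time', 'tgm' or 'volume'")


def _clusters_of(mask_flat: np.ndarray, shape, structure):
    lab, n = ndimage.label(mask_flat.reshape(shape), structure=structure)
    lab = lab.ravel()
    return [np.flatnonzero(lab == k + 1) for k in range(n)]


def _point_p_matrix(null: np.ndarray, tail: str) -> np.ndarray:
    """Per-permutation pointwise p-values against the columnwise null."""
    stat = null if tail == "one" else np.abs(null)
    rank = sps.rankdata(stat, axis=0, method="min")
    return (stat.shape[0] - rank + 1) / stat.shape[0]


def cluster_permutation(subject_effects, adjacency: str = "time",
                        shape: tuple | None = None, forming_p: float = 0.001,
                        alpha: float = 0.05, n_perm: int = 1000,
                        cross_test_max: bool = False, tail: str = "one",
                        seed: int | None = None):
    """Cluster-size permutation correction with sign-flip nulls.

    Points whose sign-permutation p falls below ``forming_p`` are clustered
    by adjacency (consecutive time points, 4-connectivity for
    train x test matrices, 26-connectivity for volumes); the null is the
    per-permutation maximum cluster size, and observed clusters are kept
    when their size reaches the alpha tail of that null. With
    ``cross_test_max`` a list of effect arrays (same subjects) is corrected
    jointly: the per-permutation maximum is taken across all tests before
    thresholding, and one :class:`ClusterResult` per test is returned.
    """
    effect_list = list(subject_effects) if cross_test_max else [subject_effects]
    effect_list = [np.atleast_2d(np.asarray(e, dtype=float).reshape(
        np.asarray(e).shape[0], -1)) for e in effect_list]
    n_sub = effect_list[0].shape[0]
    for e in effect_list:
        if e.shape[0] != n_sub:
            raise ValidationError("all tests must share the subject set")
    rng = np.random.default_rng(seed)
    signs, _ = _sign_matrix(n_sub, n_perm, rng)
    structure = _structure(adjacency)

    per_test = []
    for eff in effect_list:
        pshape = shape if shape is not None else (eff.shape[1],)
        if int(np.prod(pshape)) != eff.shape[1]:
            raise ValidationError("shape does not match number of points")
        null = signs @ eff / n_sub
        p_mat = _point_p_matrix(null, tail)
        supra = p_mat < forming_p
        max_sizes = np.zeros(signs.shape[0], dtype=int)
        for i in np.flatnonzero(supra.any(axis=1)):
            cl = _clusters_of(supra[i], pshape, structure)
            if cl:
                max_sizes[i] = max(len(c) for c in cl)
        per_test.append((p_mat, max_sizes, pshape))

    null_max = np.max(np.stack([m for _, m, _ in per_test]), axis=0)

    results = []
    for p_mat, _, pshape in per_test:
        clusters = _clusters_of(p_mat[0] < forming_p, pshape, structure)
        sizes = np.array([len(c) for c in clusters], dtype=int)
        cluster_p = np.array([np.mean(null_max >= s) for s in sizes])
        significant = cluster_p <= alpha if sizes.size else np.zeros(0, bool)
        results.append(ClusterResult(clusters, cluster_p, significant,
                                     forming_p, alpha, null_max,
                                     point_p=p_mat[0].reshape(pshape)))
    return results if cross_test_max else results[0]


def conjunction_mask(masks) -> np.ndarray:
    """Intersection of significance masks (logical AND across tests)."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ParameterError("no masks given")
    for m in masks[1:]:
        if m.shape != masks[0].shape:
            raise ValidationError("masks must share the same grid")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


# ---------------------------------------------------------------------------
# bootstrap peak latencies

@dataclass
class PeakCI:
    peak_latency: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    boot_mean: float = np.nan
    boot_sd: float = np.nan


@dataclass
class PeakDifference:
    difference: float
    ci_low: float
    ci_high: float
    significant: bool
    n_bootstrap: int
    samples: np.ndarray = field(repr=False, default=None)


def _window_indices(times, window):
    times = np.asarray(times, dtype=float)
    if window is None:
        return np.arange(times.size)
    lo, hi = window
    idx = np.flatnonzero((times >= lo) & (times <= hi))
    if idx.size == 0:
        raise ParameterError("window contains no time points")
    return idx


def _peak_latency(curve, times, idx):
    """First maximum inside the window (ties broken toward earlier times)."""
    return float(times[idx[np.argmax(curve[idx])]])


def _boot_latencies(timecourses, times, idx, n_boot, rng):
    n_sub = timecourses.shape[0]
    lats = np.empty(n_boot)
    chunk = max(1, min(n_boot, 20000))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        draw = rng.integers(0, n_sub, size=(stop - start, n_sub))
        means = timecourses[draw].mean(axis=1)          # (chunk, T)
        lats[start:stop] = times[idx[np.argmax(means[:, idx], axis=1)]]
    return lats


def bootstrap_peak(timecourses: np.ndarray, times, n_boot: int = 100000,
                   window: tuple | None = None,
                   seed: int | None = None) -> PeakCI:
    """95% CI of the group peak latency by bootstrapping participants.

    Participant time series are resampled with replacement, averaged, and
    the latency of the maximum of each bootstrap average is recorded; the
    CI is mean +/- 1.96 SD of that latency distribution. Peak detection can
    be restricted to a time ``window`` (ms); ties take the first maximum.
    """
    tc = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if tc.shape[0] < 2:
        raise ParameterError("need at least 2 subjects")
    times = np.asarray(times, dtype=float)
    idx = _window_indices(times, window)
    grand = tc.mean(axis=0)
    if np.ptp(grand[idx]) == 0:
        warnings.warn("flat curve in window: peak latency is tied; "
                      "reporting the first time point")
    peak = _peak_latency(grand, times, idx)
    rng = np.random.default_rng(seed)
    lats = _boot_latencies(tc, times, idx, n_boot, rng)
    m, s = float(lats.mean()), float(lats.std())
    return PeakCI(peak, m - 1.96 * s, m + 1.96 * s, n_boot, m, s)


def bootstrap_peak_difference(tc_a: np.ndarray, tc_b: np.ndarray, times,
                              n_boot: int = 100000,
                              window_a: tuple | None = None,
                              window_b: tuple | None = None,
                              seed: int | None = None) -> PeakDifference:
    """CI of the peak-latency difference between two conditions.

    The same participant resamples are used for both conditions (paired
    bootstrap); per sample the latency difference peak(a) - peak(b) is
    recorded, the CI is mean +/- 1.96 SD, and the difference is significant
    when the CI excludes zero.
    """
    a = np.atleast_2d(np.asarray(tc_a, dtype=float))
    b = np.atleast_2d(np.asarray(tc_b, dtype=float))
    times = np.asarray(times, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("conditions must share subjects and time grid")
    idx_a = _window_indices(times, window_a)
    idx_b = _window_indices(times, window_b)
    rng = np.random.default_rng(seed)
    n_sub, n = a.shape[0], n_boot
    diffs = np.empty(n)
    chunk = max(1, min(n, 20000))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        draw = rng.integers(0, n_sub, size=(stop - start, n_sub))
        ma, mb = a[draw].mean(axis=1), b[draw].mean(axis=1)
        la = times[idx_a[np.argmax(ma[:, idx_a], axis=1)]]
        lb = times[idx_b[np.argmax(mb[:, idx_b], axis=1)]]
        diffs[start:stop] = la - lb
    obs = _peak_latency(a.mean(0), times, idx_a) \
        - _peak_latency(b.mean(0), times, idx_b)
    m, s = float(diffs.mean()), float(diffs.std())
    lo, hi = m - 1.96 * s, m + 1.96 * s
    return PeakDifference(obs, lo, hi, not (lo <= 0.0 <= hi), n_boot, diffs)


# ---------------------------------------------------------------------------
# TOST equivalence

def tost_equivalence(latency_samples_a, latency_samples_b, bounds_ms: float,
                     scale: str = "subject") -> float:
    """Two one-sided tests for equivalence of two latency distributions.

    ``p = max`` of the one-sided tests that the mean difference exceeds
    ``-bounds_ms`` and falls below ``+bounds_ms``. With
    ``scale="subject"`` the paired differences are treated as independent
    observations (t-tests, SE = SD/sqrt(n)); with ``scale="bootstrap"``
    the spread of the difference distribution is itself the standard error
    of the estimate (z-tests). Bounds are mandatory: no default is assumed.
    """
    if bounds_ms is None or bounds_ms <= 0:
        raise ParameterError("bounds_ms must be a positive equivalence bound")
    a = np.asarray(latency_samples_a, dtype=float)
    b = np.asarray(latency_samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("samples must be paired (equal length)")
    d = a - b
    m = d.mean()
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    if sd == 0:
        return 0.0 if -bounds_ms < m < bounds_ms else 1.0
    if scale == "subject":
        p_lower = sps.ttest_1samp(d, -bounds_ms, alternative="greater").pvalue
        p_upper = sps.ttest_1samp(d, bounds_ms, alternative="less").pvalue
    elif scale == "bootstrap":
        se = d.std(ddof=1)
        p_lower = sps.norm.sf((m + bounds_ms) / se)
        p_upper = sps.norm.cdf((m - bounds_ms) / se)
    else:
        raise ParameterError("scale must be 'subject' or 'bootstrap'")
    return float(max(p_lower, p_upper))
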