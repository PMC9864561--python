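"""Representational dissimilarity matrices (1 - Pearson r) and comparisons.

The RDM is the shared currency of representational similarity analysis:
condition patterns are averaged (across trials or runs) upstream, pairwise
dissimilarities are ``1 - Pearson correlation`` (range [0, 2]), and RDMs
are compared by correlating their lower-triangular parts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ValidationError


class DegenerateInputError(ValueError):
    """A pattern or RDM is constant where variance is required."""


@dataclass
class RDM:
    """Symmetric condition x condition dissimilarity matrix, zero diagonal."""

    values: np.ndarray
    condition_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.condition_ids = np.asarray(self.condition_ids)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("RDM must be square")
        if self.condition_ids.shape[0] != v.shape[0]:
            raise ValidationError("condition_ids length mismatch")
        if np.isnan(v).any():
            raise ValidationError("RDM contains NaNs")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValidationError("RDM diagonal must be zero")
        if v.min() < -1e-10 or v.max() > 2.0 + 1e-10:
            raise ValidationError("RDM entries must lie in [0, 2]")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.condition_ids,
                     columns=self.condition_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), np.asarray(df.index))

    @classmethod
    def from_lower_triangle(cls, vec: np.ndarray, condition_ids) -> "RDM":
        """Rebuild the symmetric matrix from a row-major lower-triangle vector."""
        condition_ids = np.asarray(condition_ids)
        n = condition_ids.shape[0]
        vec = np.asarray(vec, dtype=float)
        if vec.shape[0] != n * (n - 1) // 2:
            raise ValidationError("lower-triangle length does not match n")
        m = np.zeros((n, n))
        m[np.tril_indices(n, -1)] = vec
        return cls(m + m.T, condition_ids)


def compute_rdm(patterns: np.ndarray, condition_ids=None) -> RDM:
    """1 - Pearson correlation between condition pattern vectors.

    ``patterns`` is conditions x features; trial-/run-wise averaging per
    condition must happen before calling (the distance is computed on the
    averaged patterns). A zero-variance pattern has no defined correlation
    and raises, naming the offending condition.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValidationError("patterns must be conditions x features (>= 2)")
    if condition_ids is None:
        condition_ids = np.arange(patterns.shape[0])
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(
            f"constant pattern for condition(s) {np.asarray(condition_ids)[bad].tolist()}: "
            "correlation distance undefined")
    values = 1.0 - np.corrcoef(patterns)
    np.fill_diagonal(values, 0.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 2.0)
    return RDM(values, condition_ids)


def lower_triangle(rdm: RDM) -> np.ndarray:
    """Strictly-below-diagonal entries in row-major (i > j) order.

    Length n(n-1)/2; this fixed ordering is what all RDM-to-RDM
    correlations in the package use.
    """
    n = rdm.n_conditions
    return rdm.values[np.tril_indices(n, -1)]


def correlate_rdms(a: RDM, b: RDM, method: str = "pearson") -> float:
    """Correlation of the two RDMs' lower-triangle vectors.

    Pearson by default (Spearman available for robustness checks).
    """
    if a.n_conditions != b.n_conditions or \
            not np.array_equal(a.condition_ids, b.condition_ids):
        raise ValidationError("RDMs must share condition set and ordering")
    va, vb = lower_triangle(a), lower_triangle(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DegenerateInputError("constant lower triangle: correlation undefined")
    if method == "pearson":
        return float(sps.pearsonr(va, vb).statistic)
    if method == "spearman":
        return float(sps.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown method {method!r}")
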