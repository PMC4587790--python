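"""Resting-state ROI connectivity and group comparison.

Per-subject ROI-by-ROI Pearson correlation matrices on high-pass-filtered
series; group significance from a "super-subject" -- each subject's series
z-scored and concatenated, whose pairwise correlation equals the mean of
the per-subject correlations when all subjects contribute equal-length
series; and per-cell two-sample t-tests (on Fisher-z transformed values by
default) between two groups of matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core import BoldRun, Roi, RunSegments
from .preprocess import highpass_fourier

__all__ = [
    "ConnectivityMatrix",
    "RoiConnectivity",
    "roi_correlation_matrix",
    "supersubject_significance",
    "compare_group_matrices",
    "mean_matrix",
]

#: output ROI ordering convention (V1 seed first, then the motion network)
DEFAULT_ROI_ORDER = ["V1_L", "V1_R", "MT_L", "MT_R", "V6_L", "V6_R",
                     "PIVC_L", "PIVC_R", "PCuCu"]


@dataclass
class ConnectivityMatrix:
    """ROI x ROI correlations with optional significance annotations."""

    labels: list[str]
    values: np.ndarray
    p_values: np.ndarray | None = None
    tiers: np.ndarray | None = None      # "p<0.01" / "p<0.05" / "" per cell

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValueError("matrix shape must match the label list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _roi_series(run: BoldRun, rois: list[Roi], segments: RunSegments,
                highpass_cycles: int) -> np.ndarray:
    """(n_retained, n_rois) high-pass-filtered mean series."""
    idx = segments.retained_indices()
    cols = []
    for roi in rois:
        s = run.voxel_series(roi.voxels).mean(axis=1)[idx]
        cols.append(highpass_fourier(s, highpass_cycles))
    return np.column_stack(cols)


class RoiConnectivity(BaseEstimator):
    """Pearson ROI connectivity of a resting run.

    Attributes after fit: ``matrix_`` (:class:`ConnectivityMatrix`),
    ``series_`` (filtered ROI series used).
    """

    def __init__(self, highpass_cycles: int = 2, min_timepoints: int = 10):
        self.highpass_cycles = highpass_cycles
        self.min_timepoints = min_timepoints

    def fit(self, run: BoldRun, rois: list[Roi],
            segments: RunSegments | None = None):
        segments = segments or RunSegments.full(run.n_timepoints)
        if segments.n_retained < self.min_timepoints:
            raise ValueError("fewer than the minimum retained timepoints")
        series = _roi_series(run, rois, segments, self.highpass_cycles)
        if np.any(series.std(axis=0) == 0):
            bad = [rois[i].label for i in np.flatnonzero(series.std(axis=0) == 0)]
            raise ValueError(f"constant ROI series: correlation undefined for {bad}")
        self.series_ = series
        self.matrix_ = ConnectivityMatrix([r.label for r in rois],
                                          np.corrcoef(series.T))
        return self


def roi_correlation_matrix(run: BoldRun, rois: list[Roi],
                           segments: RunSegments | None = None,
                           highpass_cycles: int = 2) -> ConnectivityMatrix:
    """Correlation matrix of high-pass-filtered ROI means over retained points."""
    return RoiConnectivity(highpass_cycles=highpass_cycles).fit(
        run, rois, segments).matrix_


def supersubject_significance(subject_series: list[np.ndarray],
                              labels: list[str]) -> ConnectivityMatrix:
    """Concatenated z-scored "super-subject" correlations with p-values.

    Each subject's (n_timepoints, n_rois) series is z-scored per ROI and
    concatenated; Pearson r per ROI pair is computed on the concatenation
    with p from the t distribution at df = total length - 2.  For
    equal-length subjects this r equals the mean of the per-subject r.
    """
    if len(subject_series) < 2:
        raise ValueError("need at least two subjects")
    zs = []
    for s in subject_series:
        s = np.asarray(s, dtype=float)
        sd = s.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("a subject has a constant ROI series")
        zs.append((s - s.mean(axis=0)) / sd)
    concat = np.vstack(zs)
    n = concat.shape[0]
    r = np.corrcoef(concat.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    return ConnectivityMatrix(list(labels), r, p_values=p)


def mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise group-mean correlation matrix."""
    labels = matrices[0].labels
    if any(m.labels != labels for m in matrices):
        raise ValueError("matrices must share the same ROI set and order")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(labels, mean)


def compare_group_matrices(group_a: list[ConnectivityMatrix],
                           group_b: list[ConnectivityMatrix],
                           fisher: bool = True) -> pd.DataFrame:
    """Per-cell two-tailed two-sample t-test between two groups of matrices.

    Correlations are Fisher-z transformed by default (raw-r mode available
    for fidelity runs).  Returns a tidy frame with one row per unordered
    ROI pair: t, df, p and the significance tier at the printed p < 0.01 /
    p < 0.05 levels.
    """
    for g in (group_a, group_b):
        if len(g) < 2:
            raise ValueError("need at least two matrices per group")
    labels = group_a[0].labels
    if any(m.labels != labels for m in group_a + group_b):
        raise ValueError("all matrices must share the same ROI set and order")
    A = np.stack([m.values for m in group_a])
    B = np.stack([m.values for m in group_b])
    if fisher:
        A, B = np.arctanh(np.clip(A, -1 + 1e-12, 1 - 1e-12)), \
               np.arctanh(np.clip(B, -1 + 1e-12, 1 - 1e-12))
    rows = []
    k = len(labels)
    for i in range(k):
        for j in range(i + 1, k):
            t, p = stats.ttest_ind(A[:, i, j], B[:, i, j])
            tier = "p<0.01" if p < 0.01 else ("p<0.05" if p < 0.05 else "")
            rows.append({"roi_a": labels[i], "roi_b": labels[j],
                         "t": float(t), "df": len(A) + len(B) - 2,
                         "p": float(p), "tier": tier})
    return pd.DataFrame(rows)
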