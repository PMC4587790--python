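"""Run conditioning: motion scrubbing, mean-intensity adjustment, high-pass.

Scrubbing removes whole half-period intervals of task runs (single
timepoints of rest runs) whenever any rigid-body parameter exceeds the
4 mm / 5 deg thresholds, and flags runs that keep less than half their
duration.  The high-pass filter is the GLM-Fourier projection: constant plus
sine/cosine pairs up to two cycles per run are regressed out.
"""

from __future__ import annotations

import numpy as np

from .core import AcquisitionSpec, BoldRun, MotionTrace, RunSegments

__all__ = [
    "scrub_motion",
    "scrubbing_report",
    "intensity_adjust",
    "highpass_fourier",
    "TRANSLATION_THRESHOLD_MM",
    "ROTATION_THRESHOLD_DEG",
]

TRANSLATION_THRESHOLD_MM = 4.0
ROTATION_THRESHOLD_DEG = 5.0
MIN_RETAINED_FRACTION = 0.5


def _bad_timepoints(trace: MotionTrace, translation_thresh: float,
                    rotation_thresh: float) -> np.ndarray:
    """Boolean mask of timepoints with any supra-threshold parameter."""
    over_t = np.abs(trace.translations) > translation_thresh
    over_r = np.abs(trace.rotations) > rotation_thresh
    return over_t.any(axis=1) | over_r.any(axis=1)


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) intervals where ``mask`` is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    return list(zip(starts.tolist(), stops.tolist()))


def scrub_motion(trace: MotionTrace, acq: AcquisitionSpec,
                 translation_thresh: float = TRANSLATION_THRESHOLD_MM,
                 rotation_thresh: float = ROTATION_THRESHOLD_DEG) -> RunSegments:
    """Exclude motion-contaminated intervals and return surviving segments.

    For task runs the run is tiled into half-period bins anchored at block
    onsets; a bin is dropped if *any* of its timepoints exceeds a threshold,
    so every surviving boundary stays on a half-period boundary.  For rest
    runs single supra-threshold timepoints are dropped.  The result is
    flagged unusable when less than half the run survives.
    """
    if len(trace) != acq.n_timepoints:
        raise ValueError("motion trace length does not match the acquisition spec")
    bad = _bad_timepoints(trace, translation_thresh, rotation_thresh)

    if acq.kind == "task":
        half = acq.half_period_tp
        keep = np.ones(acq.n_timepoints, dtype=bool)
        for start in range(0, acq.n_timepoints, half):
            if bad[start:start + half].any():
                keep[start:start + half] = False
        period = acq.period_tp
    else:
        keep = ~bad
        period = None

    segments = RunSegments(_runs_of_true(keep), acq.n_timepoints, period)
    segments.usable = segments.retained_fraction >= MIN_RETAINED_FRACTION
    return segments


def scrubbing_report(trace: MotionTrace, acq: AcquisitionSpec,
                     translation_thresh: float = TRANSLATION_THRESHOLD_MM,
                     rotation_thresh: float = ROTATION_THRESHOLD_DEG) -> dict:
    """JSON-ready audit of the scrubbing decision.

    Mirrors the per-parameter mean / SD / max summaries of the retained
    timepoints alongside the thresholds and removed intervals.
    """
    segments = scrub_motion(trace, acq, translation_thresh, rotation_thresh)
    kept = segments.retained_indices()
    retained = trace.values[kept] if kept.size else np.empty((0, 6))
    removed = _runs_of_true(~np.isin(np.arange(acq.n_timepoints), kept))
    stats = {}
    for j, name in enumerate(MotionTrace.PARAMS):
        col = retained[:, j]
        stats[name] = {
            "mean": float(col.mean()) if col.size else None,
            "sd": float(col.std(ddof=1)) if col.size > 1 else None,
            "max_abs": float(np.abs(col).max()) if col.size else None,
        }
    return {
        "translation_threshold_mm": translation_thresh,
        "rotation_threshold_deg": rotation_thresh,
        "removed_intervals": [list(iv) for iv in removed],
        "retained_fraction": segments.retained_fraction,
        "usable": segments.usable,
        "retained_parameter_stats": stats,
    }


def intensity_adjust(run: BoldRun) -> BoldRun:
    """Rescale each volume so its mean equals the run's grand mean."""
    if run.n_timepoints == 0:
        raise ValueError("empty run")
    vol_means = run.data.mean(axis=(0, 1, 2))
    if np.any(vol_means == 0):
        raise ValueError("cannot adjust a zero-mean volume")
    grand = vol_means.mean()
    data = run.data * (grand / vol_means)
    return BoldRun(data, run.acq, run.voxel_size, run.condition, run.motion,
                   dict(run.meta))


def _highpass_basis(n: int, n_cycles: int) -> np.ndarray:
    t = np.arange(n)
    cols = [np.ones(n)]
    for k in range(1, n_cycles + 1):
        cols.append(np.sin(2 * np.pi * k * t / n))
        cols.append(np.cos(2 * np.pi * k * t / n))
    return np.column_stack(cols)


def highpass_fourier(series: np.ndarray, n_cycles: int = 2) -> np.ndarray:
    """Project out the constant and 1..n_cycles cycles-per-run Fourier pairs.

    Works along the first axis; the output is orthogonal to every removed
    regressor.  Applying the filter twice equals applying it once (it is a
    linear projection).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 2 * n_cycles + 1:
        raise ValueError("series too short for the requested high-pass order")
    basis = _highpass_basis(n, n_cycles)
    coef, *_ = np.linalg.lstsq(basis, series, rcond=None)
    return series - basis @ coef
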