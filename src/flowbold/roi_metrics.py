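"""ROI time-course extraction and Fourier S/N-phase statistics.

The response of a region to the periodic design is summarised by two
numbers: the signal-to-noise ratio S/N -- the amplitude at the stimulus
fundamental divided by the RMS amplitude of the two adjacent frequency bins
(S/N ~ 1 for noise) -- and the response phase, the angle of the fundamental
Fourier component.

Phase convention: 0 deg means the response is in phase with the stimulus
square wave (fundamental peaking mid-coherent-block); positive phase means
delayed, with a pure lag of tau seconds mapping to 360 * tau / period
degrees; phases are wrapped to (-180, 180].  Under this convention the
canonical 21-s block response (boxcar convolved with the default gamma HRF)
carries a phase of 64 deg -- the standard hemodynamic delay -- and a
counterphase (random-preferring) response is shifted by 180 deg.

Group phase statistics are vectorial: each subject contributes the vector
(S/N cos phase, S/N sin phase); the group resultant is the Cartesian mean,
and the phase SD derives from the 2-D normal dispersion of the points
around the resultant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AcquisitionSpec, BoldRun, Roi, RunSegments

__all__ = [
    "RoiTimecourse",
    "SnPhase",
    "PhaseGroupStats",
    "wrap_phase",
    "extract_timecourse",
    "period_average",
    "sn_phase",
    "vector_stats",
    "compare_phase_groups",
]


def wrap_phase(deg) -> np.ndarray | float:
    """Wrap degrees into (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0)
    return float(wrapped) if np.ndim(deg) == 0 else wrapped


@dataclass
class RoiTimecourse:
    """Percent-signal ROI series on the retained timepoints.

    ``timepoints`` are the original volume indices, so cycle alignment
    survives scrubbing gaps.
    """

    values: np.ndarray
    timepoints: np.ndarray
    acq: AcquisitionSpec


@dataclass
class SnPhase:
    """Per-subject, per-ROI periodic-response summary."""

    sn: float
    phase_deg: float
    n_periods: float
    subject: str | None = None
    roi: str | None = None
    tier: str | None = None       # "p<0.01" | "p<0.05" | "ns"

    @property
    def vector(self) -> np.ndarray:
        th = np.deg2rad(self.phase_deg)
        return np.array([self.sn * np.cos(th), self.sn * np.sin(th)])


@dataclass
class PhaseGroupStats:
    """Vectorial group summary of S/N-phase points."""

    resultant_phase_deg: float
    resultant_magnitude: float
    dispersion_sd: float          # SD of point distances from the resultant
    phase_sd_deg: float
    n: int


def extract_timecourse(run: BoldRun, roi: Roi,
                       segments: RunSegments | None = None) -> RoiTimecourse:
    """Voxel-mean ROI series in percent signal change about segment means."""
    if roi.n == 0:
        raise ValueError("empty ROI")
    segments = segments or RunSegments.full(run.n_timepoints, run.acq.period_tp
                                            if run.acq.kind == "task" else None)
    mean_series = run.voxel_series(roi.voxels).mean(axis=1)
    values, timepoints = [], []
    for a, b in segments.intervals:
        seg = mean_series[a:b]
        m = seg.mean()
        if m == 0:
            raise ValueError("segment mean is zero; cannot express percent signal")
        values.append(100.0 * (seg - m) / m)
        timepoints.append(np.arange(a, b))
    return RoiTimecourse(np.concatenate(values), np.concatenate(timepoints), run.acq)


def period_average(series, period: int | None = None) -> np.ndarray:
    """Pointwise mean over aligned complete stimulus cycles.

    Accepts a contiguous array (``period`` required) or a
    :class:`RoiTimecourse`, in which case only cycles fully retained after
    scrubbing enter the average.
    """
    if isinstance(series, RoiTimecourse):
        period = period or series.acq.period_tp
        values = np.full(series.acq.n_timepoints, np.nan)
        values[series.timepoints] = series.values
    else:
        if period is None:
            raise ValueError("period required for a bare array")
        values = np.asarray(series, dtype=float)
    n_complete = len(values) // period
    cycles = [values[c * period:(c + 1) * period] for c in range(n_complete)]
    cycles = [c for c in cycles if not np.isnan(c).any()]
    if not cycles:
        raise ValueError("no complete stimulus cycle retained")
    return np.mean(cycles, axis=0)


def _fourier_component(values: np.ndarray, timepoints: np.ndarray,
                       n_total: int, k: int) -> complex:
    """DFT coefficient at bin ``k`` using original time indices.

    Reduces to the standard DFT bin for a complete series; for scrubbed
    series the retained samples keep their true position in the exponent so
    the phase stays aligned to the stimulus.
    """
    w = np.exp(-2j * np.pi * k * timepoints / n_total)
    return complex(np.sum(values * w))


def sn_phase(series, acq: AcquisitionSpec | None = None,
             p_value: float | None = None, subject=None, roi=None) -> SnPhase:
    """S/N and phase of the fundamental response component.

    ``series`` is a :class:`RoiTimecourse` or a contiguous array covering
    the full run (``acq`` required).  The fundamental is the
    cycles-per-run bin; S/N divides its amplitude by the RMS amplitude of
    the two adjacent bins, so at least three cycles are needed.
    """
    if isinstance(series, RoiTimecourse):
        values, timepoints, acq = series.values, series.timepoints, series.acq
    else:
        if acq is None:
            raise ValueError("acq required for a bare array")
        values = np.asarray(series, dtype=float)
        timepoints = np.arange(len(values))
    if acq.n_cycles < 3:
        raise ValueError("need at least three cycles for adjacent noise bins")
    n_total, k = acq.n_timepoints, acq.n_cycles

    f_fund = _fourier_component(values, timepoints, n_total, k)
    amp_adj = [abs(_fourier_component(values, timepoints, n_total, k + d))
               for d in (-1, 1)]
    noise = np.sqrt(np.mean(np.square(amp_adj)))
    sn = abs(f_fund) / noise if noise > 0 else np.inf

    # -angle makes a pure delay positive; -90 deg sets the origin at the
    # stimulus square wave so the canonical response lands at 64 deg.
    phase = wrap_phase(-np.degrees(np.angle(f_fund)) - 90.0)

    tier = None
    if p_value is not None:
        tier = "p<0.01" if p_value < 0.01 else ("p<0.05" if p_value < 0.05 else "ns")
    n_periods = len(values) / (n_total / k)
    return SnPhase(float(sn), float(phase), float(n_periods), subject, roi, tier)


def _as_vectors(points) -> np.ndarray:
    vecs = []
    for p in points:
        if isinstance(p, SnPhase):
            vecs.append(p.vector)
        else:
            sn, ph = p
            th = np.deg2rad(ph)
            vecs.append([sn * np.cos(th), sn * np.sin(th)])
    return np.asarray(vecs, dtype=float)


def vector_stats(points) -> PhaseGroupStats:
    """Vectorial average of S/N-phase points with 2-D dispersion phase SD.

    The resultant is the Cartesian mean of the vectors; the dispersion is
    the standard deviation of the point cloud about the resultant -- the
    root-mean-square of the distances |v_i - resultant| (with an n-1
    denominator) -- and the phase SD converts that 2-D normal spread into
    an angle, ``atan(dispersion / |resultant|)`` in degrees.
    """
    vecs = _as_vectors(points)
    if len(vecs) < 2:
        raise ValueError("need at least two points")
    resultant = vecs.mean(axis=0)
    mag = float(np.linalg.norm(resultant))
    if mag < 1e-12:
        raise ValueError("zero resultant: group phase undefined")
    dists = np.linalg.norm(vecs - resultant, axis=1)
    sd = float(np.sqrt(np.sum(dists ** 2) / (len(vecs) - 1)))
    return PhaseGroupStats(
        resultant_phase_deg=wrap_phase(np.degrees(np.arctan2(resultant[1], resultant[0]))),
        resultant_magnitude=mag,
        dispersion_sd=sd,
        phase_sd_deg=float(np.degrees(np.arctan(sd / mag))),
        n=len(vecs),
    )


def compare_phase_groups(group_a, group_b) -> tuple[float, int, float]:
    """Two-tailed two-sample t-test between two groups' response phases.

    Each point's signed angular deviation from its own group resultant
    supplies the variance; the effect is the wrapped difference of the two
    resultant phases.  Returns (t, df, p).
    """
    stats_a, stats_b = vector_stats(group_a), vector_stats(group_b)
    dev_a = wrap_phase([_phase_of(p) - stats_a.resultant_phase_deg for p in group_a])
    dev_b = wrap_phase([_phase_of(p) - stats_b.resultant_phase_deg for p in group_b])
    na, nb = len(dev_a), len(dev_b)
    var_a, var_b = dev_a.var(ddof=1), dev_b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    if sp2 <= 0:
        raise ValueError("degenerate (zero) phase variance in both groups")
    diff = wrap_phase(stats_a.resultant_phase_deg - stats_b.resultant_phase_deg)
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def _phase_of(point) -> float:
    return point.phase_deg if isinstance(point, SnPhase) else float(point[1])
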