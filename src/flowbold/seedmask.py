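"""V1-seed selection and lagged-correlation functional masking.

The flow-vs-blank contrast defines a bilateral calcarine seed; the seed's
series is then cross-correlated with every voxel at hemodynamically
plausible delays (0 and 3 s by default) and the union of the supra-critical
|r| maps constrains the coherent-vs-random analysis.  At p < 0.05 two-tailed
with ~60 retained timepoints the critical correlation is |r| ~ 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import BoldRun, Roi, RunSegments
from .glm import GlmResult, z_threshold
from .preprocess import highpass_fourier

__all__ = [
    "SeedError",
    "CorrelationMask",
    "LaggedCorrelationMasker",
    "critical_r",
    "select_v1_seed",
    "lagged_correlation_mask",
]


class SeedError(RuntimeError):
    """No usable (bilateral) seed at the requested threshold."""


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson |r| at df = n - 2.

    r* = t* / sqrt(df + t*^2) with t* the two-tailed alpha quantile; for
    n ~ 63 at alpha 0.05 this reproduces the printed |r| = 0.25.
    """
    df = n - 2
    if df < 3:
        raise ValueError("overlap too short: need df >= 3")
    t_star = stats.t.isf(alpha / 2.0, df)
    return float(t_star / np.sqrt(df + t_star ** 2))


def select_v1_seed(result: GlmResult, threshold_p: float = 0.001,
                   layout_hint: dict[str, np.ndarray] | None = None) -> Roi:
    """Select the bilateral V1 seed from a flow-vs-blank Z map.

    Supra-threshold voxels (two-tailed ``threshold_p``) are split by
    hemisphere about the grid midline; both halves must be populated.  When
    ``layout_hint`` provides candidate voxel sets (e.g. the synthetic
    layout's V1 labels, keyed "L"/"R"), the search is restricted to them --
    the stand-in for the anatomical calcarine localisation.
    """
    if result.grid_shape is None:
        raise ValueError("GLM result carries no grid shape")
    zmap = result.z_map()
    zmin = z_threshold(threshold_p)
    supra = zmap >= zmin  # flow-vs-blank seed: strong positive response
    if layout_hint:
        restrict = np.zeros_like(supra)
        for vox in layout_hint.values():
            restrict[tuple(np.atleast_2d(vox).T)] = True
        supra &= restrict
    vox = np.argwhere(supra)
    if len(vox) == 0:
        raise SeedError(f"no supra-threshold seed voxels at p < {threshold_p}")
    mid = (result.grid_shape[0] - 1) / 2.0
    left, right = vox[vox[:, 0] < mid], vox[vox[:, 0] >= mid]
    for side, sub in (("left", left), ("right", right)):
        if len(sub) == 0:
            raise SeedError(f"seed not bilateral: no voxels in the {side} hemisphere")
    zvals = zmap[tuple(vox.T)]
    com = lambda v: v.mean(axis=0)  # noqa: E731 - per-focus average
    centre = (np.array(result.grid_shape) - 1) / 2.0
    com_mm = ((com(left) + com(right)) / 2.0 - centre)  # average of the two foci
    return Roi("V1_seed", vox, hemisphere="bilateral",
               centre_of_mass_mm=com_mm, peak_z=float(zvals.max()))


@dataclass
class CorrelationMask:
    """Union over delays of supra-critical |r| voxels."""

    r_maps: dict[float, np.ndarray]      # delay (s) -> (grid) r map
    critical: float
    mask: np.ndarray                     # boolean union over delays
    marked_fraction: dict[float, float] = field(default_factory=dict)

    @property
    def union_fraction(self) -> float:
        return float(self.mask.mean())


class LaggedCorrelationMasker(BaseEstimator):
    """Seed-to-voxel lagged correlation mask.

    For each delay d the seed series at time t is correlated with every
    voxel at t + d over the overlapping retained window; voxels whose |r|
    exceeds the two-tailed critical value at any delay enter the mask.
    Series are high-pass filtered and z-scored segment-wise first, matching
    the GLM preprocessing.

    Attributes after fit: ``mask_``, ``r_maps_``, ``critical_``.
    """

    def __init__(self, delays=(0.0, 3.0), alpha: float = 0.05,
                 highpass_cycles: int = 2):
        self.delays = delays
        self.alpha = alpha
        self.highpass_cycles = highpass_cycles

    def _clean(self, x: np.ndarray) -> np.ndarray:
        x = highpass_fourier(x, self.highpass_cycles)
        sd = x.std(axis=0)
        return (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    def fit(self, run: BoldRun, seed_series: np.ndarray,
            segments: RunSegments | None = None):
        segments = segments or RunSegments.full(run.n_timepoints)
        seed_series = np.asarray(seed_series, dtype=float)
        if len(seed_series) != run.n_timepoints:
            raise ValueError("seed series and run must share timepoints")

        series = run.timeseries()
        r_maps: dict[float, np.ndarray] = {}
        criticals: dict[float, float] = {}
        marked: dict[float, float] = {}
        mask = np.zeros(run.shape, dtype=bool)
        for delay in self.delays:
            lag = delay / run.acq.tr
            if abs(lag - round(lag)) > 1e-9:
                raise ValueError("delays must be multiples of TR")
            lag = int(round(lag))
            # correlate within retained segments so gaps never pair
            # non-contiguous samples
            parts_x, parts_y = [], []
            for a, b in segments.intervals:
                if b - a - lag < 3:
                    continue
                x = seed_series[a:b - lag]
                y = series[a + lag:b]
                parts_x.append(self._clean(x[:, None])[:, 0])
                parts_y.append(self._clean(y))
            if not parts_x:
                raise ValueError("overlap too short for the requested delay")
            x = np.concatenate(parts_x)
            y = np.vstack(parts_y)
            n = len(x)
            crit = critical_r(n, self.alpha)  # raises if df < 3
            xs = (x - x.mean()) / x.std()
            ym = y - y.mean(axis=0)
            ysd = ym.std(axis=0)
            r = (xs @ ym) / (n * np.where(ysd > 0, ysd, 1.0))
            r[ysd == 0] = 0.0
            rmap = r.reshape(run.shape)
            r_maps[delay] = rmap
            criticals[delay] = crit
            marked[delay] = float((np.abs(r) > crit).mean())
            mask |= np.abs(rmap) > crit
        self.r_maps_ = r_maps
        self.criticals_ = criticals
        self.critical_ = max(criticals.values())
        self.mask_ = mask
        self.marked_fraction_ = marked
        return self

    def result(self) -> CorrelationMask:
        return CorrelationMask(self.r_maps_, self.critical_, self.mask_,
                               self.marked_fraction_)


def lagged_correlation_mask(seed_series: np.ndarray, run: BoldRun,
                            delays=(0.0, 3.0), alpha: float = 0.05,
                            segments: RunSegments | None = None) -> CorrelationMask:
    """Build the union lagged-correlation mask for a seed series."""
    masker = LaggedCorrelationMasker(delays=delays, alpha=alpha)
    return masker.fit(run, seed_series, segments).result()
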