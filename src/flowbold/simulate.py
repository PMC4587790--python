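"""Synthetic BOLD data with known ground truth.

Task runs carry, in each labelled region, the canonical periodic response
circularly shifted so its fundamental phase equals the region's phase
parameter, scaled by the region's selectivity sign and amplitude, on top of
baseline plus AR(1)+white+drift noise.  Rest runs embed ROI-mean latent
signals drawn from a prescribed correlation matrix.  Every simulator is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import AcquisitionSpec, BoldRun, MotionTrace
from .glm import HrfParams, canonical_cycle
from .roi_metrics import wrap_phase

__all__ = [
    "Region",
    "RegionLayout",
    "NoiseSpec",
    "simulate_task_run",
    "simulate_rest_run",
    "simulate_motion_trace",
    "region_response_cycle",
    "amplitude_for_target_sn",
    "CANONICAL_PHASE_DEG",
]

#: fundamental phase (deg) of the unshifted canonical block response under
#: the package phase convention -- the "standard hemodynamic delay"
CANONICAL_PHASE_DEG = 64.0


@dataclass(frozen=True)
class Region:
    """Ground truth for one labelled region.

    ``sign`` is +1 for coherent-preferring, -1 for random-preferring, 0 for
    null; ``phase_deg`` is the fundamental phase of the region's response to
    coherent-vs-random alternation (so a random-preferring region sits near
    +/-180 minus the hemodynamic lag); ``amplitude_pct`` scales the response
    peak in percent of baseline.  ``flow_amplitude_pct`` is the (always
    positive) response to flow-vs-blank alternation used to define seeds.
    """

    voxels: np.ndarray
    sign: int = 1
    amplitude_pct: float = 1.0
    phase_deg: float = CANONICAL_PHASE_DEG
    baseline: float = 1000.0
    flow_amplitude_pct: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.atleast_2d(np.asarray(self.voxels, dtype=int)))
        if not (-180.0 < self.phase_deg <= 180.0):
            raise ValueError("phase must lie in (-180, 180]")


@dataclass
class RegionLayout:
    """Voxel grid with named, disjoint ground-truth regions."""

    shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size: float = 3.0
    regions: dict[str, Region] = field(default_factory=dict)
    background_baseline: float = 1000.0

    def __post_init__(self) -> None:
        seen = set()
        for name, reg in self.regions.items():
            for v in map(tuple, reg.voxels):
                if any(not 0 <= v[i] < self.shape[i] for i in range(3)):
                    raise ValueError(f"region {name!r} extends outside the grid")
                if v in seen:
                    raise ValueError(f"regions overlap at voxel {v}")
                seen.add(v)

    @staticmethod
    def _box(x0, x1, y0, y1, z0, z1) -> np.ndarray:
        g = np.mgrid[x0:x1, y0:y1, z0:z1]
        return g.reshape(3, -1).T

    @classmethod
    def default(cls, **region_overrides) -> "RegionLayout":
        """Desk-scale layout with the motion-network regions.

        24 x 24 x 18 grid at 3 mm; bilateral V1 near the posterior midline,
        lateral MT, dorsal-medial V6, insular PIVC, and a precuneus/cuneus
        patch.  Signs and phases follow the adult-like ground truth:
        coherent-preferring MT/V6/PCuCu at the canonical delay, random-
        preferring PIVC near counterphase, V1 null for coherent-vs-random.
        """
        box = cls._box
        regions = {
            "V1_L": Region(box(9, 12, 2, 5, 6, 9), sign=0, amplitude_pct=0.0,
                           flow_amplitude_pct=3.0),
            "V1_R": Region(box(12, 15, 2, 5, 6, 9), sign=0, amplitude_pct=0.0,
                           flow_amplitude_pct=3.0),
            "MT_L": Region(box(3, 6, 6, 9, 7, 10), sign=1, amplitude_pct=1.0),
            "MT_R": Region(box(18, 21, 6, 9, 7, 10), sign=1, amplitude_pct=1.0),
            "V6_L": Region(box(9, 12, 6, 9, 12, 15), sign=1, amplitude_pct=1.2,
                           phase_deg=82.0),
            "V6_R": Region(box(12, 15, 6, 9, 12, 15), sign=1, amplitude_pct=1.2,
                           phase_deg=82.0),
            "PIVC_L": Region(box(4, 7, 12, 15, 8, 11), sign=-1, amplitude_pct=0.8,
                             phase_deg=-146.0),
            "PIVC_R": Region(box(17, 20, 12, 15, 8, 11), sign=-1, amplitude_pct=0.8,
                             phase_deg=-146.0),
            "PCuCu": Region(box(10, 14, 10, 13, 13, 16), sign=1, amplitude_pct=0.9),
        }
        regions.update(region_overrides)
        return cls(regions=regions)

    @classmethod
    def single_region(cls, name: str = "roi", shape=(8, 8, 4), n_voxels: int = 12,
                      **region_kw) -> "RegionLayout":
        """Minimal layout with one compact region, for recovery experiments."""
        g = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].reshape(3, -1).T
        centre = (np.array(shape) - 1) / 2
        order = np.argsort(np.linalg.norm(g - centre, axis=1), kind="stable")
        return cls(shape=shape, regions={name: Region(g[order[:n_voxels]], **region_kw)})


@dataclass(frozen=True)
class NoiseSpec:
    """Additive voxel noise: white + AR(1) + slow cosine drift.

    ``white_sd_pct`` is the innovation SD in percent of baseline; the AR(1)
    coefficient shapes temporal autocorrelation; the drift is a cosine of
    ``drift_amplitude_pct`` percent with random phase per voxel.
    """

    white_sd_pct: float = 0.5
    ar1: float = 0.3
    drift_amplitude_pct: float = 0.3
    drift_period_s: float = 128.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1 <= 0.95:
            raise ValueError("AR(1) coefficient must be in [0, 0.95]")

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(white_sd_pct=0.0, ar1=0.0, drift_amplitude_pct=0.0)


def _noise_block(noise: NoiseSpec, n_voxels: int, n_tp: int, tr: float,
                 rng: np.random.Generator) -> np.ndarray:
    """(n_tp, n_voxels) noise in percent-of-baseline units."""
    out = np.zeros((n_tp, n_voxels))
    if noise.white_sd_pct > 0:
        eps = rng.normal(0.0, noise.white_sd_pct, size=(n_tp, n_voxels))
        out[0] = eps[0]
        for t in range(1, n_tp):
            out[t] = noise.ar1 * out[t - 1] + eps[t]
    if noise.drift_amplitude_pct > 0:
        t = np.arange(n_tp) * tr
        phase = rng.uniform(0, 2 * np.pi, size=n_voxels)
        out += noise.drift_amplitude_pct * np.cos(
            2 * np.pi * t[:, None] / noise.drift_period_s + phase[None, :])
    return out


def region_response_cycle(acq: AcquisitionSpec, phase_deg: float,
                          hrf: HrfParams | None = None) -> np.ndarray:
    """One-period unit-peak response whose fundamental phase is ``phase_deg``.

    The canonical boxcar-HRF cycle (phase 64 deg) is circularly shifted by
    the phase difference, demeaned, and scaled to unit peak magnitude.
    """
    cyc = canonical_cycle(acq, hrf, phase_shift_deg=phase_deg - CANONICAL_PHASE_DEG)
    cyc = cyc - cyc.mean()
    return cyc / np.abs(cyc).max()


def amplitude_for_target_sn(target_sn: float, noise: NoiseSpec,
                            acq: AcquisitionSpec, n_voxels: int,
                            phase_deg: float = CANONICAL_PHASE_DEG,
                            hrf: HrfParams | None = None) -> float:
    """Region amplitude (percent) giving an expected S/N on the ROI mean.

    From |F_fund| = (N/2) a A1 for the response and sigma sqrt(N) for each
    white-noise bin amplitude on the voxel-mean series (noise SD shrinks by
    sqrt(n_voxels)): S/N ~ a A1 sqrt(N) n_voxels^0.5 / (2 sigma), where A1
    is the fundamental cosine amplitude of the unit-peak response cycle.
    """
    cyc = region_response_cycle(acq, phase_deg, hrf)
    f1 = np.abs(np.fft.rfft(cyc)[1]) / len(cyc) * 2.0  # fundamental amplitude
    sigma_eff = noise.white_sd_pct / np.sqrt(n_voxels)
    if sigma_eff == 0:
        raise ValueError("target S/N undefined for noise-free runs")
    # AR(1) raises power near DC; adjacent-bin and fundamental bins sit at
    # the same frequency neighbourhood so the ratio is unchanged to first
    # order, but the innovation-to-spectrum factor at the fundamental enters:
    om = 2 * np.pi * acq.n_cycles / acq.n_timepoints
    ar_gain = 1.0 / np.sqrt(1 + noise.ar1 ** 2 - 2 * noise.ar1 * np.cos(om))
    return 2.0 * target_sn * sigma_eff * ar_gain / (f1 * np.sqrt(acq.n_timepoints))


def _rigid_transform(vol: np.ndarray, params: np.ndarray, voxel_size: float) -> np.ndarray:
    """Apply a 6-parameter rigid movement (mm translations, deg rotations)."""
    if not np.any(params):
        return vol
    tx, ty, tz, rx, ry, rz = params
    angles = np.deg2rad([rx, ry, rz])
    rots = []
    c, s = np.cos(angles[0]), np.sin(angles[0])
    rots.append(np.array([[1, 0, 0], [0, c, -s], [0, s, c]]))
    c, s = np.cos(angles[1]), np.sin(angles[1])
    rots.append(np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]))
    c, s = np.cos(angles[2]), np.sin(angles[2])
    rots.append(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]))
    R = rots[2] @ rots[1] @ rots[0]
    centre = (np.array(vol.shape) - 1) / 2.0
    shift_vox = np.array([tx, ty, tz]) / voxel_size
    offset = centre - R.T @ (centre + shift_vox)
    return ndimage.affine_transform(vol, R.T, offset=offset, order=1, mode="nearest")


def simulate_task_run(layout: RegionLayout, acq: AcquisitionSpec | None = None,
                      noise: NoiseSpec | None = None, hrf: HrfParams | None = None,
                      motion: MotionTrace | None = None, seed: int = 0,
                      stimulus: str = "coherent_vs_random") -> BoldRun:
    """Simulate a block-design run with region-specific selectivity.

    ``stimulus`` selects the ground truth used: ``coherent_vs_random``
    applies each region's sign, amplitude and phase; ``flow_vs_blank``
    applies the (positive) flow response amplitude at the canonical phase.
    """
    acq = acq or AcquisitionSpec.task()
    if acq.kind != "task":
        raise ValueError("task simulation needs a task acquisition spec")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    data = np.full(layout.shape + (acq.n_timepoints,), float(layout.background_baseline))
    for reg in layout.regions.values():
        if stimulus == "coherent_vs_random":
            # The delivered fundamental phase equals phase_deg exactly: a
            # random-preferring region is the negated shape built 180 deg
            # away, so negation lands it back on its phase parameter.
            gain = reg.sign * reg.amplitude_pct
            phase = wrap_phase(reg.phase_deg - (180.0 if reg.sign < 0 else 0.0))
        elif stimulus == "flow_vs_blank":
            gain, phase = reg.flow_amplitude_pct, CANONICAL_PHASE_DEG
        else:
            raise ValueError(f"unknown stimulus {stimulus!r}")
        series = np.full(acq.n_timepoints, reg.baseline, dtype=float)
        if gain != 0.0:
            cyc = region_response_cycle(acq, phase, hrf)
            series = reg.baseline * (1.0 + gain / 100.0 * np.tile(cyc, acq.n_cycles))
        idx = tuple(reg.voxels.T)
        data[idx] = series[None, :]

    if noise != NoiseSpec.off():
        flat = data.reshape(-1, acq.n_timepoints)
        pct = _noise_block(noise, flat.shape[0], acq.n_timepoints, acq.tr, rng)
        base = flat[:, :1]
        flat += base * pct.T / 100.0

    if motion is not None:
        for t in range(acq.n_timepoints):
            data[..., t] = _rigid_transform(data[..., t], motion.values[t],
                                            layout.voxel_size)

    half = acq.half_period_tp
    condition = ["coherent" if (t // half) % 2 == 0 else "control"
                 for t in range(acq.n_timepoints)]
    return BoldRun(data, acq, layout.voxel_size, condition, motion,
                   {"seed": seed, "stimulus": stimulus})


def simulate_rest_run(layout: RegionLayout, target_corr: np.ndarray,
                      acq: AcquisitionSpec | None = None,
                      noise: NoiseSpec | None = None, seed: int = 0,
                      latent_amplitude_pct: float = 1.0,
                      roi_order: list[str] | None = None) -> BoldRun:
    """Simulate a rest run whose ROI-mean latents follow ``target_corr``.

    Latent unit-variance signals with the requested population correlation
    (Cholesky construction) are written into each region at
    ``latent_amplitude_pct`` percent of baseline; independent voxel noise is
    added on top, so sample ROI-mean correlations approach the target as the
    voxel noise shrinks or region size grows.
    """
    acq = acq or AcquisitionSpec.rest()
    noise = noise or NoiseSpec()
    roi_order = roi_order or list(layout.regions)
    target = np.asarray(target_corr, dtype=float)
    k = len(roi_order)
    if target.shape != (k, k) or not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target correlation must be symmetric over the ROI set")
    if not np.allclose(np.diag(target), 1.0):
        raise ValueError("target correlation must have a unit diagonal")
    eigmin = np.linalg.eigvalsh(target).min()
    if eigmin < -1e-10:
        raise ValueError("target correlation matrix is not positive semi-definite")
    L = np.linalg.cholesky(target + np.eye(k) * max(0.0, -eigmin + 1e-12))

    rng = np.random.default_rng(seed)
    latents = (L @ rng.standard_normal((k, acq.n_timepoints)))

    data = np.full(layout.shape + (acq.n_timepoints,), float(layout.background_baseline))
    for name, z in zip(roi_order, latents):
        reg = layout.regions[name]
        idx = tuple(reg.voxels.T)
        data[idx] = reg.baseline * (1.0 + latent_amplitude_pct / 100.0 * z)[None, :]

    if noise != NoiseSpec.off():
        flat = data.reshape(-1, acq.n_timepoints)
        pct = _noise_block(noise, flat.shape[0], acq.n_timepoints, acq.tr, rng)
        flat += flat[:, :1] * pct.T / 100.0

    return BoldRun(data, acq, layout.voxel_size, ["rest"] * acq.n_timepoints,
                   None, {"seed": seed, "roi_order": roi_order})


def simulate_motion_trace(acq: AcquisitionSpec, spike_times=(), spike_magnitudes=(),
                          seed: int = 0, drift_sd_mm: float = 0.2,
                          drift_sd_deg: float = 0.2) -> MotionTrace:
    """Smooth sub-threshold baseline drift plus specified spikes.

    ``spike_times`` are timepoint indices; ``spike_magnitudes`` are applied
    to the x translation (mm).  Without spikes the trace stays well below
    the 4 mm / 5 deg scrubbing thresholds.
    """
    rng = np.random.default_rng(seed)
    n = acq.n_timepoints
    walk = np.cumsum(rng.normal(0, 1, size=(n, 6)), axis=0)
    walk = ndimage.uniform_filter1d(walk, size=9, axis=0)
    walk -= walk[0]
    scale = np.array([drift_sd_mm] * 3 + [drift_sd_deg] * 3)
    sd = walk.std(axis=0)
    vals = walk * scale / np.where(sd > 0, sd, 1.0)
    for t, m in zip(spike_times, spike_magnitudes):
        if not 0 <= t < n:
            raise ValueError("spike time outside the run")
        vals[t, 0] += m
    return MotionTrace(vals)
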