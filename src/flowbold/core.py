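"""Shared containers: acquisition geometry, 4D runs, motion traces, ROIs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionSpec", "MotionTrace", "RunSegments", "BoldRun", "Roi"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Timing of one functional series.

    Task runs alternate a coherent-flow block with a control block (blank or
    random motion), ``block_length`` seconds each, ``n_cycles`` times; the
    default is the 21-s / TR 3 s / 84-timepoint block design.  Rest runs have
    no stimulus structure.
    """

    tr: float = 3.0                 # seconds
    n_timepoints: int = 84
    block_length: float = 21.0      # seconds per condition block
    n_cycles: int = 6
    n_dummy: int = 4                # discarded leading volumes (bookkeeping only)
    kind: str = "task"              # "task" | "rest"

    def __post_init__(self) -> None:
        if self.kind == "task":
            if abs(self.n_timepoints * self.tr - self.n_cycles * 2 * self.block_length) > 1e-9:
                raise ValueError(
                    "task run timing inconsistent: n_timepoints * TR must equal "
                    "n_cycles * 2 * block_length"
                )
            if (self.block_length / self.tr) % 1 > 1e-9:
                raise ValueError("block length must be a multiple of TR")

    @classmethod
    def task(cls, **kw) -> "AcquisitionSpec":
        return cls(kind="task", **kw)

    @classmethod
    def rest(cls, n_timepoints: int = 120, **kw) -> "AcquisitionSpec":
        return cls(kind="rest", n_timepoints=n_timepoints, n_cycles=0,
                   block_length=0.0, **kw)

    @property
    def period_tp(self) -> int:
        """Stimulus period (one coherent + one control block) in timepoints."""
        return int(round(2 * self.block_length / self.tr))

    @property
    def half_period_tp(self) -> int:
        return int(round(self.block_length / self.tr))

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.tr


@dataclass
class MotionTrace:
    """Six rigid-body parameters per timepoint.

    ``values`` has shape (n_timepoints, 6): translations x, y, z in mm then
    rotations about x, y, z in degrees.
    """

    values: np.ndarray

    PARAMS = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion trace must be (n_timepoints, 6)")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclass
class RunSegments:
    """Disjoint retained intervals of a run, treated as independent samples.

    ``intervals`` are half-open (start, stop) timepoint pairs in increasing
    order.  For task runs every boundary lies on a half-period boundary, so
    each segment keeps a known alignment to the stimulus cycle.
    """

    intervals: list[tuple[int, int]]
    n_timepoints: int
    period_tp: int | None = None     # task runs only
    usable: bool = True

    def __post_init__(self) -> None:
        prev = 0
        for a, b in self.intervals:
            if not (0 <= a < b <= self.n_timepoints) or a < prev:
                raise ValueError("segments must be disjoint, ordered and inside the run")
            prev = b

    @property
    def retained_fraction(self) -> float:
        return sum(b - a for a, b in self.intervals) / self.n_timepoints

    @property
    def n_retained(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def retained_indices(self) -> np.ndarray:
        if not self.intervals:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(a, b) for a, b in self.intervals])

    def alignment_offsets(self) -> list[int]:
        """Cycle-phase offset (in timepoints) at each segment start."""
        if self.period_tp is None:
            return [0] * len(self.intervals)
        return [a % self.period_tp for a, _ in self.intervals]

    @classmethod
    def full(cls, n_timepoints: int, period_tp: int | None = None) -> "RunSegments":
        return cls([(0, n_timepoints)], n_timepoints, period_tp)


@dataclass
class BoldRun:
    """A 4D functional run on a regular voxel grid.

    ``data`` has shape (nx, ny, nz, n_timepoints); ``voxel_size`` is the
    isotropic edge in mm.  ``condition`` optionally labels each volume
    ("coherent" / "control" / "rest").
    """

    data: np.ndarray
    acq: AcquisitionSpec
    voxel_size: float = 3.0
    condition: list[str] | None = None
    motion: MotionTrace | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[3] != self.acq.n_timepoints:
            raise ValueError("data length does not match the acquisition spec")
        if self.motion is not None and len(self.motion) != self.acq.n_timepoints:
            raise ValueError("motion trace length does not match the run")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """(n_timepoints, n_voxels) view of the run."""
        return self.data.reshape(-1, self.n_timepoints).T

    def voxel_series(self, voxels: np.ndarray) -> np.ndarray:
        """(n_timepoints, len(voxels)) series for explicit voxel indices."""
        voxels = np.asarray(voxels, dtype=int)
        return self.data[voxels[:, 0], voxels[:, 1], voxels[:, 2], :].T


@dataclass
class Roi:
    """A labelled voxel set with summary geometry and peak statistic."""

    label: str
    voxels: np.ndarray               # (n, 3) integer grid indices
    hemisphere: str = "bilateral"    # "L" | "R" | "bilateral"
    centre_of_mass_mm: np.ndarray | None = None
    peak_z: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size and self.voxels.shape[1] != 3:
            raise ValueError("voxels must be (n, 3) indices")

    @property
    def n(self) -> int:
        return self.voxels.shape[0]

    def volume_mm3(self, voxel_size: float) -> float:
        return self.n * voxel_size ** 3
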