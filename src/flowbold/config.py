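"""Pipeline configuration: every threshold the analysis applies, in one
serialisable object.

Defaults are the study values: seed threshold p < 0.001, mask alpha 0.05 at
delays 0 and 3 s, ROI alpha 0.05 (Z 1.96), 81 mm^3 cluster floor, FDR
q < 0.05, scrubbing at 4 mm / 5 deg, GLM-Fourier high-pass at two cycles.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import AcquisitionSpec
from .glm import HrfParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    task_acq: AcquisitionSpec = field(default_factory=AcquisitionSpec.task)
    rest_acq: AcquisitionSpec = field(default_factory=AcquisitionSpec.rest)
    hrf: HrfParams = field(default_factory=HrfParams)
    seed_p: float = 0.001             # flow-vs-blank seed threshold
    mask_alpha: float = 0.05          # lagged-correlation mask
    mask_delays: tuple[float, ...] = (0.0, 3.0)
    roi_alpha: float = 0.05           # coherent-vs-random cluster threshold
    cluster_floor_mm3: float = 81.0   # three 3-mm voxels
    fdr_q: float = 0.05
    translation_thresh_mm: float = 4.0
    rotation_thresh_deg: float = 5.0
    highpass_cycles: int = 2
    connectivity: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_p", "mask_alpha", "roi_alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.cluster_floor_mm3 <= 0:
            raise ValueError("cluster floor must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mask_delays"] = list(self.mask_delays)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["task_acq"] = AcquisitionSpec(**d["task_acq"])
        d["rest_acq"] = AcquisitionSpec(**d["rest_acq"])
        d["hrf"] = HrfParams(**d["hrf"])
        d["mask_delays"] = tuple(d["mask_delays"])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
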