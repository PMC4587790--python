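"""Readers and writers: NIfTI-1 volumes, TSV tables, JSON sidecars.

Grids are written with a diagonal affine scaled by the voxel size, origin
at the grid centre, so reported coordinates are mm offsets from the centre
(the synthetic stand-in for the anterior-commissure origin).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AcquisitionSpec, BoldRun, MotionTrace, Roi

__all__ = [
    "write_bold_run", "read_bold_run",
    "write_motion_trace", "read_motion_trace",
    "write_roi_table", "read_roi_table",
    "write_label_volume", "write_json", "read_json",
]

ROI_TABLE_COLUMNS = ["label", "hemi", "n", "chi", "psi", "zeta", "Zpeak"]


def _affine(shape, voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size] * 3 + [1.0])
    aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel_size
    return aff


def write_bold_run(run: BoldRun, path: str | Path) -> Path:
    """Write a run as 4D NIfTI-1 plus a JSON sidecar (TR, labels, meta)."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(run.shape, run.voxel_size))
    img.header.set_zooms((run.voxel_size,) * 3 + (run.acq.tr,))
    nib.save(img, path)
    sidecar = {
        "tr": run.acq.tr,
        "kind": run.acq.kind,
        "n_timepoints": run.acq.n_timepoints,
        "block_length": run.acq.block_length,
        "n_cycles": run.acq.n_cycles,
        "n_dummy": run.acq.n_dummy,
        "voxel_size": run.voxel_size,
        "condition": run.condition,
        "meta": {k: v for k, v in run.meta.items()
                 if isinstance(v, (str, int, float, bool, list, type(None)))},
    }
    write_json(sidecar, path.with_suffix("").with_suffix(".json"))
    return path


def read_bold_run(path: str | Path, motion: MotionTrace | None = None) -> BoldRun:
    path = Path(path)
    img = nib.load(path)
    side = read_json(path.with_suffix("").with_suffix(".json"))
    acq = AcquisitionSpec(tr=side["tr"], n_timepoints=side["n_timepoints"],
                          block_length=side["block_length"], n_cycles=side["n_cycles"],
                          n_dummy=side["n_dummy"], kind=side["kind"])
    return BoldRun(np.asarray(img.dataobj, dtype=float), acq, side["voxel_size"],
                   side.get("condition"), motion, side.get("meta", {}))


def write_motion_trace(trace: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(trace.values, columns=list(MotionTrace.PARAMS)).to_csv(
        path, sep="\t", index=False)
    return path


def read_motion_trace(path: str | Path) -> MotionTrace:
    return MotionTrace(pd.read_csv(path, sep="\t")[list(MotionTrace.PARAMS)].to_numpy())


def write_roi_table(rois: list[Roi], path: str | Path) -> Path:
    """TSV mirroring the per-ROI summary: label, hemi, n, chi, psi, zeta, Zpeak."""
    rows = []
    for r in rois:
        com = r.centre_of_mass_mm if r.centre_of_mass_mm is not None else [np.nan] * 3
        rows.append({"label": r.label, "hemi": r.hemisphere, "n": r.n,
                     "chi": com[0], "psi": com[1], "zeta": com[2],
                     "Zpeak": r.peak_z})
    pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_label_volume(layout, path: str | Path) -> Path:
    """Region layout as a NIfTI label volume plus JSON legend."""
    vol = np.zeros(layout.shape, dtype=np.int16)
    legend = {}
    for i, (name, reg) in enumerate(layout.regions.items(), start=1):
        vol[tuple(reg.voxels.T)] = i
        legend[name] = {"value": i, "sign": reg.sign,
                        "amplitude_pct": reg.amplitude_pct,
                        "phase_deg": reg.phase_deg}
    path = Path(path)
    nib.save(nib.Nifti1Image(vol, _affine(layout.shape, layout.voxel_size)), path)
    write_json({"voxel_size": layout.voxel_size, "regions": legend},
               path.with_suffix("").with_suffix(".json"))
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
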