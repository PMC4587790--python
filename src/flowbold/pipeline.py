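"""End-to-end task pipeline driver.

Per subject: scrub motion, adjust volume intensities, fit the flow-vs-blank
GLM, select the bilateral V1 seed, build the lagged-correlation mask from
the seed series, fit the coherent-vs-random GLM within the mask, clusterise
the Z map, and summarise each surviving ROI's S/N and phase.  A fixed-
effects group map with FDR correction pools all subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import BoldRun, Roi, RunSegments
from .glm import (GroupResult, build_design, fit_glm, fixed_effects_group,
                  threshold_and_cluster, z_threshold)
from .preprocess import intensity_adjust, scrub_motion
from .roi_metrics import SnPhase, extract_timecourse, sn_phase
from .seedmask import lagged_correlation_mask, select_v1_seed

logger = logging.getLogger("flowbold.pipeline")

__all__ = ["SubjectData", "SubjectResult", "TaskPipelineResult", "run_task_pipeline"]


@dataclass
class SubjectData:
    """One subject's task material: flow-vs-blank and coherent-vs-random runs."""

    subject_id: str
    flow_run: BoldRun
    task_run: BoldRun
    layout_hint: dict[str, np.ndarray] | None = None  # candidate seed voxels


@dataclass
class SubjectResult:
    subject_id: str
    seed: Roi
    mask_fraction: float
    rois: list[Roi]
    sn_phase: list[SnPhase]
    retained_fraction: float


@dataclass
class TaskPipelineResult:
    subjects: list[SubjectResult]
    group: GroupResult | None
    sn_phase_table: pd.DataFrame


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def _segments_for(run: BoldRun, config: PipelineConfig) -> RunSegments:
    if run.motion is None:
        return RunSegments.full(run.n_timepoints,
                                run.acq.period_tp if run.acq.kind == "task" else None)
    return scrub_motion(run.motion, run.acq, config.translation_thresh_mm,
                        config.rotation_thresh_deg)


def _process_subject(sub: SubjectData, config: PipelineConfig) -> tuple[SubjectResult, BoldRun, object]:
    # -- conditioning ------------------------------------------------------
    flow_seg = _segments_for(sub.flow_run, config)
    task_seg = _segments_for(sub.task_run, config)
    for name, seg in (("flow", flow_seg), ("task", task_seg)):
        logger.info("%s %s run: retained fraction %.2f", sub.subject_id, name,
                    seg.retained_fraction)
        if not seg.usable:
            raise RuntimeError(f"{name} run unusable: retained fraction "
                               f"{seg.retained_fraction:.2f} < 0.5")
    flow_run = intensity_adjust(sub.flow_run)
    task_run = intensity_adjust(sub.task_run)

    # -- seed from flow-vs-blank ------------------------------------------
    flow_design = build_design(flow_run.acq, flow_seg, config.hrf,
                               flow_run.motion)
    flow_result = fit_glm(flow_run, flow_design)
    seed = select_v1_seed(flow_result, config.seed_p, sub.layout_hint)
    logger.info("%s seed: %d voxels, peak Z %.1f", sub.subject_id, seed.n, seed.peak_z)

    # -- lagged-correlation mask ------------------------------------------
    seed_series = flow_run.voxel_series(seed.voxels).mean(axis=1)
    mask = lagged_correlation_mask(seed_series, flow_run,
                                   delays=config.mask_delays,
                                   alpha=config.mask_alpha, segments=flow_seg)
    logger.info("%s mask: union fraction %.2f (critical |r| %.2f)",
                sub.subject_id, mask.union_fraction, mask.critical)

    # -- coherent-vs-random GLM within the mask ---------------------------
    task_design = build_design(task_run.acq, task_seg, config.hrf,
                               task_run.motion)
    task_result = fit_glm(task_run, task_design)
    zmap = np.where(mask.mask, task_result.z_map(), 0.0)
    rois = threshold_and_cluster(zmap, task_run.voxel_size,
                                 alpha=config.roi_alpha,
                                 min_cluster_volume_mm3=config.cluster_floor_mm3,
                                 connectivity=config.connectivity)
    logger.info("%s: %d clusters above Z %.2f and %d mm^3", sub.subject_id,
                len(rois), z_threshold(config.roi_alpha), config.cluster_floor_mm3)

    # -- ROI S/N and phase -------------------------------------------------
    points = []
    pmap = task_result.p().reshape(task_run.shape)
    for roi in rois:
        tc = extract_timecourse(task_run, roi, task_seg)
        p_roi = float(pmap[tuple(roi.voxels.T)].min())
        points.append(sn_phase(tc, p_value=p_roi, subject=sub.subject_id,
                               roi=roi.label))
    result = SubjectResult(sub.subject_id, seed, mask.union_fraction, rois,
                           points, task_seg.retained_fraction)
    return result, task_run, task_design


def run_task_pipeline(config: PipelineConfig,
                      subjects: list[SubjectData]) -> TaskPipelineResult:
    """Run the full per-subject analysis plus the fixed-effects group map."""
    if not subjects:
        raise ValueError("empty run list")
    results, runs, designs = [], [], []
    for sub in subjects:
        res, run, design = _stage(f"subject {sub.subject_id}")(_process_subject)(
            sub, config)
        results.append(res)
        runs.append(run)
        designs.append(design)

    group = None
    if len(runs) > 1:
        group = _stage("group FFX")(fixed_effects_group)(
            runs, designs, q=config.fdr_q,
            min_cluster_volume_mm3=config.cluster_floor_mm3)

    rows = [{"subject": p.subject, "roi": p.roi, "sn": p.sn,
             "phase_deg": p.phase_deg, "p_tier": p.tier}
            for r in results for p in r.sn_phase]
    table = pd.DataFrame(rows, columns=["subject", "roi", "sn", "phase_deg", "p_tier"])
    return TaskPipelineResult(results, group, table)
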