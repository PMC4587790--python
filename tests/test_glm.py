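"""Design construction, voxelwise OLS, clustering, FDR and group FFX."""

import numpy as np
import pytest
from scipy import stats

from flowbold import (AcquisitionSpec, BoldRun, HrfParams, MotionTrace,
                      PeriodicGLM, RunSegments, build_design, fit_glm,
                      fixed_effects_group, threshold_and_cluster, z_threshold)
from flowbold.glm import DesignMatrix, bh_fdr, canonical_cycle, task_regressor, z_from_t
from flowbold.simulate import NoiseSpec, RegionLayout, simulate_task_run


def make_run(data, acq):
    return BoldRun(np.asarray(data, dtype=float), acq)


class TestDesign:
    def test_full_run_shape_and_periodicity(self, task_acq):
        seg = RunSegments.full(84, task_acq.period_tp)
        d = build_design(task_acq, seg)
        assert d.matrix.shape == (84, 2)  # task + constant
        task = d.matrix[:, 0]
        # periodic with 14-TR period after the first-cycle onset transient
        assert np.allclose(task[14:28], task[70:84], atol=1e-6)

    def test_delta_hrf_reproduces_boxcar(self, task_acq):
        delta = HrfParams(onset_delay=0.0, shape=1.0, dispersion=1e-4)
        reg = task_regressor(task_acq, delta)
        boxcar = np.tile([1.0] * 7 + [0.0] * 7, 6)
        assert np.allclose(reg, boxcar, atol=1e-6)

    def test_scrubbed_design_drops_rows(self, task_acq):
        seg = RunSegments([(0, 28), (35, 84)], 84, task_acq.period_tp)
        d = build_design(task_acq, seg)
        assert d.n_rows == 77
        assert len([n for n in d.names if n.startswith("const")]) == 2

    def test_motion_columns_centered(self, task_acq, rng):
        trace = MotionTrace(rng.normal(scale=0.5, size=(84, 6)))
        d = build_design(task_acq, RunSegments.full(84, 14), trace=trace)
        motion = d.matrix[:, 1:7]
        assert np.allclose(motion.mean(axis=0), 0.0, atol=1e-12)

    def test_rank_deficient_design_rejected(self, task_acq):
        seg = RunSegments.full(84, 14)
        trace = MotionTrace(np.ones((84, 6)))  # constant columns collide
        with pytest.raises(ValueError):
            build_design(task_acq, seg, trace=trace)

    def test_hrf_families(self):
        t = np.arange(0, 30, 0.1)
        single = HrfParams().sample(t)
        double = HrfParams(family="double-gamma", shape=6.0, dispersion=1.0).sample(t)
        assert single.min() >= 0
        assert double.min() < 0 < double.max()  # undershoot present
        with pytest.raises(ValueError):
            HrfParams(family="boxcar").sample(t)


class TestOls:
    def test_beta_recovers_amplitude_exactly_on_deterministic_data(self, task_acq):
        # data built as A times the regressor itself: OLS must return A exactly
        shape = np.tile(canonical_cycle(task_acq), 6)
        X = np.column_stack([shape, np.ones(84)])
        design = DesignMatrix(X, ["task", "const"], np.arange(84), [0])
        amplitude = 1.7
        data = (amplitude * shape + 0.3)[:, None]
        est = PeriodicGLM().fit(data, design)
        assert est.betas_[0, 0] == pytest.approx(amplitude, abs=1e-6)

    def test_matches_normal_equations_oracle(self, task_acq, rng):
        seg = RunSegments.full(84, 14)
        trace = MotionTrace(rng.normal(scale=0.3, size=(84, 6)))
        d = build_design(task_acq, seg, trace=trace)
        Y = rng.normal(size=(84, 8))
        est = PeriodicGLM().fit(Y, d)
        # closed-form normal equations, computed independently
        M = d.matrix
        beta = np.linalg.solve(M.T @ M, M.T @ Y)
        resid = Y - M @ beta
        df = 84 - M.shape[1]
        sig2 = (resid ** 2).sum(0) / df
        c = np.zeros(M.shape[1]); c[0] = 1
        t_oracle = (c @ beta) / np.sqrt(sig2 * (c @ np.linalg.inv(M.T @ M) @ c))
        assert np.allclose(est.betas_, beta, atol=1e-8)
        assert np.allclose(est.t_, t_oracle, atol=1e-8)

    def test_null_type_one_error_calibrated(self, task_acq, rng):
        d = build_design(task_acq, RunSegments.full(84, 14))
        Y = rng.normal(size=(84, 10000))
        est = PeriodicGLM().fit(Y, d)
        frac = np.mean(np.abs(est.z_) >= z_threshold(0.05))
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_zero_contrast_rejected(self, task_acq):
        d = build_design(task_acq, RunSegments.full(84, 14))
        with pytest.raises(ValueError):
            PeriodicGLM(contrast=np.zeros(2)).fit(np.ones((84, 1)), d)

    def test_z_from_t_preserves_two_sided_p(self):
        t = np.array([-3.2, -0.5, 0.0, 1.0, 4.0])
        z = z_from_t(t, df=30)
        p_t = 2 * stats.t.sf(np.abs(t), 30)
        p_z = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(p_t, p_z, rtol=1e-10)
        assert np.all(np.sign(z) == np.sign(t))


def flood_fill_clusters(mask):
    """Brute-force 6-neighbour connected components (independent oracle)."""
    mask = mask.copy()
    comps = []
    while mask.any():
        seed = tuple(np.argwhere(mask)[0])
        stack, comp = [seed], set()
        while stack:
            v = stack.pop()
            if v in comp or not mask[v]:
                continue
            comp.add(v)
            x, y, z = v
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                w = (x + dx, y + dy, z + dz)
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w]:
                    stack.append(w)
        for v in comp:
            mask[v] = False
        comps.append(frozenset(comp))
    return set(comps)


class TestClustering:
    def test_alpha_005_maps_to_z_196(self):
        assert z_threshold(0.05) == pytest.approx(1.96, abs=0.005)

    def test_two_voxel_blob_below_81_mm3_floor_dropped(self):
        zmap = np.zeros((6, 6, 6))
        zmap[2, 2, 2] = zmap[2, 2, 3] = 3.0    # 54 mm^3 at 3-mm voxels
        assert threshold_and_cluster(zmap, voxel_size=3.0) == []
        zmap[2, 2, 4] = 3.0                     # 81 mm^3: exactly at floor
        rois = threshold_and_cluster(zmap, voxel_size=3.0)
        assert len(rois) == 1 and rois[0].n == 3

    def test_all_zero_map_yields_nothing(self):
        assert threshold_and_cluster(np.zeros((5, 5, 5))) == []

    def test_positive_and_negative_foci_separate(self):
        zmap = np.zeros((8, 8, 8))
        zmap[1:3, 1:3, 1:3] = 4.0
        zmap[5:7, 5:7, 5:7] = -4.0
        rois = threshold_and_cluster(zmap, voxel_size=3.0)
        labels = {r.label.split("_")[0] for r in rois}
        assert labels == {"pos", "neg"}
        neg = next(r for r in rois if r.label.startswith("neg"))
        assert neg.peak_z == -4.0

    def test_matches_flood_fill_oracle_on_random_maps(self, rng):
        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.2
            zmap = np.where(mask, 5.0, 0.0)
            rois = threshold_and_cluster(zmap, voxel_size=3.0,
                                         min_cluster_volume_mm3=27.0)
            got = {frozenset(map(tuple, r.voxels)) for r in rois}
            assert got == flood_fill_clusters(mask)

    def test_centre_of_mass_in_mm_from_grid_centre(self):
        zmap = np.zeros((5, 5, 5))
        zmap[2, 2, 2] = zmap[3, 2, 2] = zmap[1, 2, 2] = 3.0  # symmetric about centre
        roi = threshold_and_cluster(zmap, voxel_size=3.0)[0]
        assert np.allclose(roi.centre_of_mass_mm, [0.0, 0.0, 0.0])

    def test_nonfinite_map_rejected(self):
        zmap = np.zeros((4, 4, 4)); zmap[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            threshold_and_cluster(zmap)


class TestGroup:
    def test_bh_matches_hand_oracle(self):
        p = np.array([0.001, 0.01, 0.02, 0.03, 0.04, 0.2])
        reject, _ = bh_fdr(p, q=0.05)
        # hand computation: largest k with p_(k) <= k q / m is k = 5
        assert list(reject) == [True] * 5 + [False]

    def test_single_subject_ffx_equals_single_glm(self, task_acq):
        layout = RegionLayout.single_region(n_voxels=8, amplitude_pct=1.0)
        run = simulate_task_run(layout, task_acq, NoiseSpec(white_sd_pct=0.4, ar1=0.0),
                                seed=3)
        seg = RunSegments.full(84, 14)
        design = build_design(task_acq, seg)
        single = fit_glm(run, design)
        group = fixed_effects_group([run], [design])
        assert np.allclose(group.z, single.z, atol=1e-10)

    def test_group_power_exceeds_single_subject(self, task_acq):
        layout = RegionLayout.single_region(n_voxels=8, amplitude_pct=0.3)
        noise = NoiseSpec(white_sd_pct=0.5, ar1=0.0)
        runs = [simulate_task_run(layout, task_acq, noise, seed=100 + i)
                for i in range(11)]
        seg = RunSegments.full(84, 14)
        designs = [build_design(task_acq, seg) for _ in runs]
        group = fixed_effects_group(runs, designs)
        flat = np.ravel_multi_index(tuple(layout.regions["roi"].voxels.T),
                                    layout.shape)
        singles = [np.median(np.abs(fit_glm(r, d).z[flat]))
                   for r, d in zip(runs, designs)]
        assert np.median(np.abs(group.z[flat])) > np.median(singles)

    def test_grid_mismatch_rejected(self, task_acq):
        a = RegionLayout.single_region(shape=(6, 6, 4), n_voxels=4)
        b = RegionLayout.single_region(shape=(8, 8, 4), n_voxels=4)
        runs = [simulate_task_run(a, task_acq, seed=0),
                simulate_task_run(b, task_acq, seed=1)]
        seg = RunSegments.full(84, 14)
        designs = [build_design(task_acq, seg)] * 2
        with pytest.raises(ValueError):
            fixed_effects_group(runs, designs)
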