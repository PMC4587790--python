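"""Time-course extraction, period averaging, S/N-phase and vector statistics."""

import numpy as np
import pytest

from flowbold import (AcquisitionSpec, BoldRun, NoiseSpec, Roi, RunSegments,
                      compare_phase_groups, extract_timecourse, period_average,
                      sn_phase, vector_stats, wrap_phase)
from flowbold.glm import canonical_cycle
from flowbold.roi_metrics import SnPhase
from flowbold.simulate import RegionLayout, simulate_task_run

from conftest import roi_of


def run_from_series(series, acq, n_voxels=4):
    data = np.tile(np.asarray(series, dtype=float), (2, 2, 1, 1))
    return BoldRun(data, acq)


class TestExtraction:
    def test_uniform_region_returns_injected_shape(self, task_acq):
        layout = RegionLayout.single_region(sign=1, amplitude_pct=1.0)
        run = simulate_task_run(layout, task_acq, NoiseSpec.off(), seed=0)
        tc = extract_timecourse(run, roi_of(layout))
        vox = layout.regions["roi"].voxels[0]
        one = run.data[vox[0], vox[1], vox[2], :]
        expected = 100.0 * (one - one.mean()) / one.mean()
        assert np.abs(tc.values - expected).max() < 1e-9

    def test_opposite_responses_cancel(self, task_acq):
        series = np.sin(2 * np.pi * 6 * np.arange(84) / 84)
        data = np.zeros((2, 1, 1, 84))
        data[0, 0, 0] = 100.0 + series
        data[1, 0, 0] = 100.0 - series
        run = BoldRun(data, task_acq)
        roi = Roi("pair", np.array([[0, 0, 0], [1, 0, 0]]))
        tc = extract_timecourse(run, roi)
        assert np.abs(tc.values).max() < 1e-9

    def test_scrubbed_series_length_matches_retained(self, task_acq):
        layout = RegionLayout.single_region()
        run = simulate_task_run(layout, task_acq, seed=0)
        seg = RunSegments([(0, 28), (35, 84)], 84, 14)
        tc = extract_timecourse(run, roi_of(layout), seg)
        assert len(tc.values) == 77
        assert np.array_equal(tc.timepoints, seg.retained_indices())

    def test_empty_roi_rejected(self, task_acq):
        layout = RegionLayout.single_region()
        run = simulate_task_run(layout, task_acq, seed=0)
        with pytest.raises(ValueError):
            extract_timecourse(run, Roi("empty", np.empty((0, 3))))


class TestPeriodAverage:
    def test_identical_cycles_average_to_one_cycle(self):
        cycle = np.arange(14.0)
        out = period_average(np.tile(cycle, 5), period=14)
        assert np.array_equal(out, cycle)

    def test_84_point_series_gives_14_point_cycle(self, rng):
        out = period_average(rng.normal(size=84), period=14)
        assert out.shape == (14,)

    def test_noise_shrinks_with_cycle_count(self, rng):
        cycle = np.sin(2 * np.pi * np.arange(14) / 14)
        err = {}
        for k in (4, 64):
            noisy = np.tile(cycle, k) + rng.normal(scale=1.0, size=14 * k)
            err[k] = np.sqrt(np.mean((period_average(noisy, 14) - cycle) ** 2))
        assert err[64] < err[4] / 2  # ~1/sqrt(16)

    def test_scrubbed_cycles_excluded(self, task_acq):
        layout = RegionLayout.single_region(sign=1, amplitude_pct=1.0)
        run = simulate_task_run(layout, task_acq, NoiseSpec.off(), seed=0)
        # cut one whole period (28..42): cycle 2 excluded, alignment kept
        seg = RunSegments([(0, 28), (42, 84)], 84, 14)
        tc = extract_timecourse(run, roi_of(layout), seg)
        full = period_average(extract_timecourse(run, roi_of(layout)))
        partial = period_average(tc)
        assert partial.shape == (14,)
        assert np.allclose(partial, full, atol=1e-9)  # identical cycles anyway

    def test_no_complete_cycle_rejected(self):
        with pytest.raises(ValueError):
            period_average(np.arange(10.0), period=14)


class TestSnPhase:
    def test_pure_fundamental_has_huge_sn(self, task_acq):
        series = np.sin(2 * np.pi * 6 * np.arange(84) / 84)
        assert sn_phase(series, task_acq).sn > 1e6

    def test_white_noise_sn_near_analytic_expectation(self, task_acq, rng):
        # E[S/N] = E[Rayleigh] * E[1/sqrt(mean of two Rayleigh^2)] = 1.1107
        sns = [sn_phase(rng.normal(size=84), task_acq).sn for _ in range(2000)]
        assert np.mean(sns) == pytest.approx(1.1107, abs=0.05)

    def test_canonical_response_phase_is_64_degrees(self, task_acq):
        resp = np.tile(canonical_cycle(task_acq), 6)
        assert sn_phase(resp, task_acq).phase_deg == pytest.approx(64.0, abs=0.5)

    def test_circular_shift_moves_phase_proportionally(self, task_acq, rng):
        base = rng.normal(size=84)
        ref = sn_phase(base, task_acq)
        for shift in (1, 3, 7):
            moved = np.roll(base, shift)
            got = sn_phase(moved, task_acq)
            expect = wrap_phase(ref.phase_deg + 360.0 * shift / 14)
            assert abs(wrap_phase(got.phase_deg - expect)) < 1e-9
            assert got.sn == pytest.approx(ref.sn, abs=1e-9)

    def test_scale_and_offset_invariance(self, task_acq, rng):
        base = rng.normal(size=84)
        a = sn_phase(base, task_acq)
        b = sn_phase(7.3 * base + 11.0, task_acq)
        assert b.sn == pytest.approx(a.sn, rel=1e-9)
        assert b.phase_deg == pytest.approx(a.phase_deg, abs=1e-9)

    def test_negation_flips_phase_by_180(self, task_acq, rng):
        base = rng.normal(size=84)
        a, b = sn_phase(base, task_acq), sn_phase(-base, task_acq)
        assert abs(wrap_phase(b.phase_deg - a.phase_deg - 180.0)) < 1e-9

    def test_too_few_cycles_rejected(self):
        acq = AcquisitionSpec(n_timepoints=28, n_cycles=2)
        with pytest.raises(ValueError):
            sn_phase(np.ones(28), acq)

    def test_significance_tiers(self, task_acq, rng):
        s = rng.normal(size=84)
        assert sn_phase(s, task_acq, p_value=0.005).tier == "p<0.01"
        assert sn_phase(s, task_acq, p_value=0.03).tier == "p<0.05"
        assert sn_phase(s, task_acq, p_value=0.5).tier == "ns"


class TestVectorStats:
    def test_identical_points_give_common_phase_and_tiny_sd(self):
        pts = [SnPhase(2.0, 40.0, 6.0)] * 5
        vs = vector_stats(pts)
        assert vs.resultant_phase_deg == pytest.approx(40.0, abs=1e-9)
        assert vs.phase_sd_deg < 1e-6
        assert vs.n == 5

    def test_recovers_generator_mean_and_dispersion(self):
        rng = np.random.default_rng(7)
        phases = 82.0 + 40.0 * rng.standard_normal(10_000)
        pts = [(1.0, p) for p in phases]
        vs = vector_stats(pts)
        assert abs(wrap_phase(vs.resultant_phase_deg - 82.0)) < 2.0
        assert vs.phase_sd_deg == pytest.approx(40.0, abs=5.0)

    def test_matches_circular_mean_oracle_for_unit_magnitudes(self, rng):
        phases = rng.uniform(-40, 40, size=50)
        vs = vector_stats([(1.0, p) for p in phases])
        rad = np.deg2rad(phases)
        oracle = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
        assert abs(wrap_phase(vs.resultant_phase_deg - oracle)) < 1.0

    def test_antipodal_points_rejected(self):
        with pytest.raises(ValueError):
            vector_stats([(1.0, 0.0), (1.0, 180.0)])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            vector_stats([(1.0, 10.0)])


class TestPhaseGroupComparison:
    def test_identical_groups_not_different(self):
        rng = np.random.default_rng(3)
        pts = [(1.0, p) for p in 60 + 15 * rng.standard_normal(12)]
        t, df, p = compare_phase_groups(pts, list(pts))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 22
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_power_for_30_degree_separation(self):
        # groups 30 deg apart with 10 deg SD, n = 12: p < 0.001 nearly always
        hits = 0
        for rep in range(500):
            rng = np.random.default_rng(rep)
            a = [(1.0, p) for p in 50 + 10 * rng.standard_normal(12)]
            b = [(1.0, p) for p in 80 + 10 * rng.standard_normal(12)]
            _, _, p = compare_phase_groups(a, b)
            hits += p < 0.001
        assert hits >= 0.95 * 500

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            compare_phase_groups([(1.0, 10.0)], [(1.0, 20.0), (1.0, 30.0)])


def test_wrap_phase_convention():
    assert wrap_phase(180.0) == 180.0
    assert wrap_phase(-180.0) == 180.0
    assert wrap_phase(190.0) == -170.0
    assert np.allclose(wrap_phase(np.array([360.0, -90.0])), [0.0, -90.0])
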