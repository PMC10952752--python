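"""Closed-loop controller: CoM extraction, displacement estimation,
correction bookkeeping, latency and robustness."""

import numpy as np
import pytest

from fetaltrack import (
    AcquisitionConfig,
    BinaryMask,
    FOVState,
    GridGeometry,
    IntensityLocalizer,
    LoopConfig,
    MotionEvent,
    RepetitionRecord,
    apply_fov_update,
    center_of_mass,
    compute_correction,
    estimate_displacement,
    make_sphere_world,
    run_closed_loop,
    step_trajectory,
)
from fetaltrack.localizer import segment_intensity


def _record(n, fov=(0, 0, 0), com=(0, 0, 0), voxels=100):
    return RepetitionRecord(
        repetition=n,
        fov_center=tuple(float(v) for v in fov),
        com_world=None if com is None else tuple(float(v) for v in com),
        mask_voxels=voxels,
        displacement=None,
        empty_flag=com is None,
    )


class TestCenterOfMass:
    def test_two_voxel_hand_case(self):
        g = GridGeometry((3, 3, 3), 1.0, (0.0, 0.0, 0.0))
        values = np.zeros((3, 3, 3), bool)
        values[0, 0, 0] = values[2, 0, 0] = True
        com = center_of_mass(BinaryMask(g, values))
        assert tuple(com) == pytest.approx((0.0, -1.0, -1.0))

    def test_centered_sphere_com_at_origin(self, sphere_scene, geom64):
        from fetaltrack import Trajectory, analytic_target_mask

        mask = analytic_target_mask(sphere_scene, Trajectory(np.zeros((1, 3))),
                                    geom64, 0)
        com = center_of_mass(mask)
        assert np.allclose(com, (0.0, 0.0, 0.0), atol=1.5)  # half a voxel

    def test_empty_mask_signals_none(self, geom64):
        assert center_of_mass(BinaryMask(geom64, np.zeros(geom64.shape, bool))) is None


class TestEstimateDisplacement:
    def test_static_gives_zero(self):
        records = [_record(i, com=(5, 0, 0)) for i in range(3)]
        d = estimate_displacement(records, 2)
        assert d.d == pytest.approx((0.0, 0.0, 0.0))
        assert (d.from_repetition, d.to_repetition) == (0, 2)

    def test_step_seen_between_n_and_n_minus_2(self):
        records = [_record(0, com=(0, 0, 0)), _record(1, com=(0, 0, 0)),
                   _record(2, com=(9, 0, 0))]
        assert estimate_displacement(records, 2).d == pytest.approx((9.0, 0.0, 0.0))

    def test_warmup_and_missing_com_give_absent(self):
        records = [_record(0, com=None), _record(1), _record(2)]
        assert estimate_displacement(records, 1) is None  # warm-up
        assert estimate_displacement(records, 2) is None  # empty mask at n-2


class TestComputeCorrection:
    def test_centered_object_needs_none(self):
        records = [_record(0, fov=(0, 0, 0), com=(0, 0, 0))]
        corr = compute_correction(records, FOVState(), 0)
        assert corr == pytest.approx((0.0, 0.0, 0.0))

    def test_offset_recentred(self):
        records = [_record(0, fov=(0, 0, 0), com=(9, 0, 0))]
        corr = compute_correction(records, FOVState(), 0)
        assert corr == pytest.approx((9.0, 0.0, 0.0))

    def test_pending_shift_not_double_corrected(self):
        records = [_record(0, com=(9, 0, 0)), _record(1, com=(9, 0, 0))]
        state = FOVState()
        apply_fov_update(state, np.array([9.0, 0.0, 0.0]), computed_at=0, latency=2)
        corr = compute_correction(records, state, 1)
        assert corr == pytest.approx((0.0, 0.0, 0.0))

    def test_clipping(self):
        records = [_record(0, com=(500, 0, 0))]
        corr = compute_correction(records, FOVState(), 0, max_shift_mm=96.0)
        assert corr == pytest.approx((96.0, 0.0, 0.0))


class TestApplyFovUpdate:
    def test_zero_correction_queues_nothing(self):
        state = FOVState()
        apply_fov_update(state, np.zeros(3), computed_at=5, latency=2)
        assert state.pending == []

    def test_latency_two_timing(self):
        """A correction computed from repetition 7's image lands at 9."""
        state = FOVState()
        apply_fov_update(state, np.array([9.0, 0, 0]), computed_at=7, latency=2)
        center = np.zeros(3)
        centers = {}
        for rep in range(8, 11):
            center = state.next_center(rep, center)
            centers[rep] = center[0]
        assert centers[8] == 0.0
        assert centers[9] == 9.0
        assert centers[10] == 9.0

    def test_same_repetition_corrections_sum(self):
        state = FOVState()
        apply_fov_update(state, np.array([3.0, 0, 0]), computed_at=2, latency=2)
        apply_fov_update(state, np.array([0.0, 4.0, 0]), computed_at=2, latency=2)
        center = state.next_center(4, np.zeros(3))
        assert center == pytest.approx((3.0, 4.0, 0.0))


class TestClosedLoop:
    def test_static_object_keeps_fov_constant(self, sphere_scene):
        traj = step_trajectory([], 10)
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, traj, acq)
        for r in records:
            assert r.fov_center == pytest.approx((0.0, 0.0, 0.0))
            assert r.shift_applied == pytest.approx((0.0, 0.0, 0.0))

    def test_single_step_corrected_two_repetitions_later(self, sphere_scene,
                                                         step_x_trajectory):
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, step_x_trajectory, acq)
        shifts = [r.repetition for r in records
                  if np.any(np.asarray(r.shift_applied) != 0.0)]
        assert shifts == [8]  # exactly one shift, exactly latency 2 after rep 6
        # the corrected image has the object back at the grid midpoint
        for r in records[8:]:
            com_img = np.asarray(r.com_world) - np.asarray(r.fov_center)
            assert np.all(np.abs(com_img) <= 1.5)  # 0.5 voxel at 3 mm

    def test_reported_displacement_matches_motion(self, sphere_scene,
                                                  step_x_trajectory):
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, step_x_trajectory, acq)
        d = records[6].displacement
        assert d is not None and d.d == pytest.approx((9.0, 0.0, 0.0), abs=1e-6)
        assert (d.from_repetition, d.to_repetition) == (4, 6)

    def test_latency_follows_configuration(self, sphere_scene, step_x_trajectory):
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(
            sphere_scene, step_x_trajectory, acq, LoopConfig(latency_repetitions=3)
        )
        shifts = [r.repetition for r in records
                  if np.any(np.asarray(r.shift_applied) != 0.0)]
        assert shifts == [9]

    def test_world_frame_com_invariant_under_fov_shifts(self, sphere_scene):
        """A static object's world CoM does not move when the FOV does."""
        traj = step_trajectory([MotionEvent(6, (9.0, 0.0, 0.0))], 20)
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, traj, acq)
        for r in records[6:]:
            assert np.allclose(r.com_world, (9.0, 0.0, 0.0), atol=1.5)

    def test_multi_event_latency_law(self, sphere_scene):
        events = [MotionEvent(17, (9.0, 0, 0)), MotionEvent(28, (0, 9.0, 0)),
                  MotionEvent(35, (0, 0, 9.0)), MotionEvent(45, (-9.0, 0, 0))]
        traj = step_trajectory(events, 50)
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, traj, acq)
        shifts = [r.repetition for r in records
                  if np.any(np.asarray(r.shift_applied) != 0.0)]
        assert shifts == [19, 30, 37, 47]

    def test_flaky_localizer_flags_and_continues(self, sphere_scene):
        calls = {"n": 0}

        def flaky(volume):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise RuntimeError("simulated reconstruction dropout")
            return segment_intensity(volume)

        traj = step_trajectory([MotionEvent(5, (9.0, 0, 0))], 16)
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, traj, acq, localizer=flaky)
        assert len(records) == 16
        assert sum(r.empty_flag for r in records) == 4
        max_shift = float(np.max(acq.geometry().fov_extent_mm) / 2)
        for r in records:
            assert np.all(np.abs(r.shift_applied) <= max_shift)

    def test_implausible_mask_suppresses_correction(self, sphere_scene):
        traj = step_trajectory([MotionEvent(3, (9.0, 0, 0))], 10)
        acq = AcquisitionConfig(noise_sigma=0.0)
        loop = LoopConfig(min_volume_ml=1000.0)  # sphere is ~268 ml: implausible
        records = run_closed_loop(sphere_scene, traj, acq, loop)
        assert all(r.implausible_flag for r in records)
        assert all(r.shift_applied == pytest.approx((0, 0, 0)) for r in records)

    def test_audit_outputs_roundtrip(self, sphere_scene, tmp_path):
        import csv
        import json

        from fetaltrack.tracking import write_audit_csv, write_audit_json

        traj = step_trajectory([MotionEvent(3, (9.0, 0, 0))], 8)
        acq = AcquisitionConfig(noise_sigma=0.0)
        records = run_closed_loop(sphere_scene, traj, acq)
        write_audit_csv(records, tmp_path / "audit.csv")
        write_audit_json(records, tmp_path / "audit.json")
        with open(tmp_path / "audit.csv") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 8
        assert float(rows[5]["shift_x_mm"]) == pytest.approx(9.0)
        data = json.load(open(tmp_path / "audit.json"))
        assert data[5]["shift_x_mm"] == pytest.approx(9.0)

    def test_record_invariant_enforced(self):
        with pytest.raises(ValueError):
            RepetitionRecord(0, (0, 0, 0), None, 0, None, empty_flag=False)
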