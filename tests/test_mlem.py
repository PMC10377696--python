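import numpy as np
import pytest

import bnctcam as bc
from bnctcam.errors import EmptyInputError
from bnctcam.events import ComptonEvent, EventList


def on_cone_event(theta_deg=60.0, apex=(0.0, 0.0, 60.0)):
    """Synthetic event whose cone half-angle is exactly theta."""
    c = np.cos(np.radians(theta_deg))
    e2 = 478.0 / (1.0 + (478.0 / 511.0) * (1.0 - c))
    r1 = np.asarray(apex, float)
    r2 = r1 + np.array([0.0, 0.0, 6.0])  # axis = -z
    return ComptonEvent(r1, r2, 478.0 - e2, e2)


def on_cone_point(event, distance, azimuth=0.0):
    """A point exactly on the event's cone surface at the given apex
    distance."""
    cone = bc.cone_from_event(event)
    th = cone.half_angle
    # axis is -z here; rotate within the x-z plane then around the axis
    d = np.array([np.sin(th) * np.cos(azimuth), np.sin(th) * np.sin(azimuth),
                  -np.cos(th)])
    return cone.apex + distance * d


class TestSensitivity:
    def test_uniform_mode_is_all_ones(self, small_grid):
        s = bc.sensitivity_map(small_grid, model=bc.SystemModel())
        assert np.all(s.s == 1.0)

    def test_solid_angle_decreases_away_from_detector(self):
        grid = bc.VoxelGrid(25, -30.0, 30.0)
        det = bc.DetectorGeometry(distance=60.0)
        s = bc.sensitivity_map(grid, det,
                               bc.SystemModel(sensitivity_mode="solid_angle"))
        on_axis = s.s[12, 12, :]  # increasing z toward the detector
        assert np.all(np.diff(on_axis) > 0)
        assert np.all(s.s > 0)

    def test_solid_angle_mirror_symmetry(self):
        grid = bc.VoxelGrid(25, -30.0, 30.0)
        det = bc.DetectorGeometry(distance=60.0)
        s = bc.sensitivity_map(grid, det,
                               bc.SystemModel(sensitivity_mode="solid_angle"))
        assert np.allclose(s.s, s.s[::-1, :, :])  # +-x symmetric
        assert np.allclose(s.s, s.s[:, ::-1, :])  # +-y symmetric


class TestEventVoxelProbability:
    def test_on_cone_voxel_has_maximal_angular_factor(self):
        ev = on_cone_event()
        p = bc.event_voxel_probability(ev, on_cone_point(ev, 50.0))
        assert p == pytest.approx(1.0, rel=1e-9)

    def test_one_sigma_residual(self):
        ev = on_cone_event()
        model = bc.SystemModel()
        cone = bc.cone_from_event(ev)
        th = cone.half_angle + model.angular_sigma
        d = np.array([np.sin(th), 0.0, -np.cos(th)])
        p = bc.event_voxel_probability(ev, cone.apex + 50.0 * d, model)
        assert p == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_inverse_square_distance_weighting(self):
        ev = on_cone_event()
        model = bc.SystemModel(distance_weighting=True)
        p1 = bc.event_voxel_probability(ev, on_cone_point(ev, 30.0), model)
        p2 = bc.event_voxel_probability(ev, on_cone_point(ev, 60.0), model)
        assert p1 / p2 == pytest.approx(4.0, rel=1e-9)

    def test_apex_voxel_and_far_off_cone_give_zero(self):
        ev = on_cone_event()
        assert bc.event_voxel_probability(ev, ev.r1) == 0.0
        # ~90 deg residual is far below the 1e-12 floor
        assert bc.event_voxel_probability(ev, (0.0, 0.0, -60.0)) == 0.0


class TestSystemMatrix:
    def test_sparse_and_dense_assembly_agree(self, air_events, small_grid):
        sub = air_events.permuted(np.arange(25))
        s1 = bc.build_system_matrix(sub, small_grid, method="sparse",
                                    dtype=np.float64)
        s2 = bc.build_system_matrix(sub, small_grid, method="dense",
                                    dtype=np.float64)
        a1, a2 = s1.to_scipy().toarray(), s2.to_scipy().toarray()
        assert np.array_equal(a1 != 0, a2 != 0)
        assert np.allclose(a1, a2, rtol=1e-12, atol=1e-15)

    def test_matrix_matches_scalar_probability(self, small_grid):
        ev = on_cone_event()
        events = EventList(ev.r1, ev.r2, [ev.e1], [ev.e2], 478.0)
        model = bc.SystemModel(cutoff_sigmas=1e7)  # floor only, no truncation
        sm = bc.build_system_matrix(events, small_grid, model, method="dense")
        dense = sm.to_scipy().toarray()[0]
        centers = small_grid.flat_centers()
        for j in range(0, small_grid.n_voxels, 997):
            assert dense[j] == pytest.approx(
                bc.event_voxel_probability(ev, centers[j], model), rel=1e-12)


class TestMlem:
    def test_single_voxel_grid_is_fixed_point(self):
        grid = bc.VoxelGrid(1, -60.0, 60.0)
        # forward cone (theta = 0) passes through the single voxel's center
        ev = on_cone_event(theta_deg=0.0)
        events = EventList(ev.r1, ev.r2, [ev.e1], [ev.e2], 478.0)
        run = bc.mlem_reconstruct(events, grid, n_iter=3, snapshot_every=1)
        for img in run.image_history.values():
            assert img.intensity[0, 0, 0] == pytest.approx(1.0)

    def test_first_iteration_proportional_to_event_profile(self, small_grid):
        """One event, flat start, uniform sensitivity: the first iterate is
        proportional to that event's t row."""
        ev = on_cone_event()
        events = EventList(ev.r1, ev.r2, [ev.e1], [ev.e2], 478.0)
        model = bc.SystemModel()
        run = bc.mlem_reconstruct(events, small_grid, n_iter=1, model=model)
        sm = bc.build_system_matrix(events, small_grid, model)
        t_row = np.zeros(small_grid.n_voxels)
        t_row[sm.indices] = sm.data
        got = run.final.intensity.ravel()
        assert np.allclose(got, t_row / t_row.max(), rtol=1e-9, atol=1e-12)

    def test_iterates_nonnegative_and_loglikelihood_nondecreasing(self, air_events):
        grid = bc.VoxelGrid(5, -60.0, 60.0)
        sub = air_events.permuted(np.arange(8))
        model = bc.SystemModel(cutoff_sigmas=1e7)
        sm = bc.build_system_matrix(sub, grid, model)
        run = bc.mlem_reconstruct(sub, grid, n_iter=10, model=model,
                                  system=sm, snapshot_every=1,
                                  normalized=False)
        lls = []
        for it in sorted(run.image_history):
            img = run.image_history[it]
            assert np.all(img.intensity >= 0)
            lls.append(bc.poisson_loglikelihood(sm, img.intensity))
        assert np.all(np.diff(lls) >= -1e-9)

    def test_invariant_under_event_permutation(self, air_events, small_grid):
        sub = air_events.permuted(np.arange(20))
        r1 = bc.mlem_reconstruct(sub, small_grid, n_iter=3)
        perm = np.random.default_rng(2).permutation(20)
        r2 = bc.mlem_reconstruct(sub.permuted(perm), small_grid, n_iter=3)
        assert np.allclose(r1.final.intensity, r2.final.intensity,
                           rtol=1e-10, atol=1e-13)

    def test_empty_inputs_rejected(self, small_grid):
        with pytest.raises(EmptyInputError):
            bc.mlem_reconstruct(bc.EventList.empty(478.0), small_grid)

    def test_zero_initial_image_rejected(self, air_events, small_grid):
        sub = air_events.permuted(np.arange(5))
        with pytest.raises(ValueError):
            bc.mlem_reconstruct(sub, small_grid, n_iter=1,
                                initial=bc.Image3D.zeros(small_grid))


class TestGranularity:
    def test_constant_region_scores_zero(self, small_grid):
        img = bc.Image3D(small_grid, np.ones(small_grid.shape))
        assert bc.granularity_metric(img) == 0.0

    def test_balanced_checkerboard_scores_one(self):
        grid = bc.VoxelGrid(8, -60.0, 60.0)
        arr = np.zeros(grid.shape)
        k = grid.origin_index
        checker = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        arr[:, :, k] = checker
        img = bc.Image3D(grid, arr)
        assert bc.granularity_metric(img) == pytest.approx(1.0)

    def test_zero_mean_region_undefined(self, small_grid):
        img = bc.Image3D(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(bc.errors.DegenerateImageError):
            bc.granularity_metric(img)
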