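import numpy as np
import pytest

from navbus.calibration import fit_circle
from navbus.image import SectorGeometry
from navbus.segmentation import threshold_segment
from navbus.simulator import (
    CT_INTENSITY,
    STATION_LABELS,
    NoiseModel,
    build_phantom,
    default_calibration_truth,
    identity,
    render_ct,
    render_us_frame,
    simulate_calibration_session,
    simulate_ebus_session,
    simulate_tracking,
)
from navbus.transforms import RigidTransform, random_rigid_transform


class TestBuildPhantom:
    def test_default_layout(self, default_phantom):
        assert {t.label for t in default_phantom.targets} == set(STATION_LABELS)
        assert len(default_phantom.targets) == 11
        assert default_phantom.fiducials.shape == (10, 3)
        lo, hi = default_phantom.container_bounds
        for t in default_phantom.targets:
            assert np.all(t.center >= lo) and np.all(t.center <= hi)
            assert default_phantom.distance_to_centerline(t.center) <= 25.0
        centered = default_phantom.fiducials - default_phantom.fiducials.mean(axis=0)
        assert np.linalg.svd(centered, compute_uv=False)[2] > 1.0  # non-coplanar

    def test_config_echoes_explicit_target(self):
        p = build_phantom(
            {"targets": [{"label": "7", "center": (0.0, -10.0, 45.0), "radii": (5, 5, 5)}]}
        )
        assert len(p.targets) == 1
        assert p.targets[0].label == "7"
        assert np.allclose(p.targets[0].center, (0.0, -10.0, 45.0))

    def test_jittered_layout_keeps_invariants(self):
        p = build_phantom({"jitter_mm": 1.0, "seed": 3})
        assert {t.label for t in p.targets} == set(STATION_LABELS)
        lo, hi = p.container_bounds
        for t in p.targets:
            assert np.all(t.center >= lo) and np.all(t.center <= hi)
            assert p.distance_to_centerline(t.center) <= 25.0

    def test_target_outside_container_rejected(self):
        with pytest.raises(ValueError, match="outside container"):
            build_phantom(
                {"targets": [{"label": "7", "center": (500.0, 0.0, 0.0), "radii": (5, 5, 5)}]}
            )


class TestRenderCt:
    def test_intensity_classes_present(self, default_ct):
        vals = np.unique(default_ct.voxels)
        for v in CT_INTENSITY.values():
            assert v in vals

    def test_empty_phantom_has_only_background_and_lumen(self):
        p = build_phantom({"targets": [], "fiducials": np.zeros((0, 3))})
        # a fiducial-free config is allowed for rendering-only phantoms
        ct = render_ct(p, spacing=(1.5, 1.5, 1.5))
        assert set(np.unique(ct.voxels)) <= {
            CT_INTENSITY["background"],
            CT_INTENSITY["lumen"],
        }

    def test_aligned_sphere_centroid_within_half_voxel(self):
        p = build_phantom(
            {"targets": [{"label": "7", "center": (0.0, -10.0, 45.0), "radii": (5, 5, 5)}]}
        )
        ct = render_ct(p)  # (0.5, 0.5, 0.3) spacing, grid-aligned centre
        comps = threshold_segment(ct, 150.0, upper=650.0)
        target = [c for c in comps if c.n_voxels > 100]
        assert len(target) == 1
        assert np.all(np.abs(target[0].centroid - (0.0, -10.0, 45.0)) <= ct.spacing / 2)

    def test_memory_cap_enforced(self, default_phantom):
        with pytest.raises(ValueError, match="coarser spacing"):
            render_ct(default_phantom, spacing=(0.05, 0.05, 0.05))


class TestSimulateTracking:
    def test_static_pose_zero_noise_gives_40_identical_samples(self, rng):
        pose = random_rigid_transform(rng)
        stream = simulate_tracking(lambda t: pose, (0.0, 1.0), NoiseModel.zero())
        assert len(stream) == 40
        for p in stream.poses:
            assert np.array_equal(p.matrix, pose.matrix)

    def test_positional_rms_matches_stated_accuracy(self, rng):
        # Monte-Carlo check: per-axis sigma 0.48/sqrt(3) -> 3D RMS 0.48 mm
        pose = random_rigid_transform(rng)
        noise = NoiseModel(rotation_sigma_deg=0.0, seed=99)
        stream = simulate_tracking(lambda t: pose, (0.0, 250.0), noise)
        assert len(stream) == 10_000
        dev = np.array([p.translation - pose.translation for p in stream.poses])
        rms = np.sqrt(np.mean(np.sum(dev**2, axis=1)))
        assert rms == pytest.approx(0.48, rel=0.05)

    def test_linear_path_sample_spacing(self):
        direction = np.array([1.0, 0.0, 0.0])

        def path(t):
            return RigidTransform.from_rotation_translation(np.eye(3), direction * t)

        stream = simulate_tracking(path, (0.0, 10.0), NoiseModel.zero())
        assert len(stream) == 400
        steps = [
            np.linalg.norm(b.translation - a.translation)
            for a, b in zip(stream.poses[:-1], stream.poses[1:])
        ]
        assert np.allclose(steps, 0.025, atol=1e-12)

    def test_empty_span_rejected(self, rng):
        pose = random_rigid_transform(rng)
        with pytest.raises(ValueError):
            simulate_tracking(lambda t: pose, (1.0, 0.0))


class TestRenderUsFrame:
    def test_centered_target_recovered_by_circle_fit(self, coarse_geometry):
        radius = 5.75
        p = build_phantom(
            {"targets": [{"label": "7", "center": (0.0, 0.0, 45.0), "radii": [radius] * 3}]}
        )
        # probe 30 mm above the target centre, depth axis pointing at it
        rot = np.column_stack([[1, 0, 0], [0, -1, 0], [0, 0, -1]]).astype(float)
        pose = RigidTransform.from_rotation_translation(rot, (0.0, 30.0, 45.0))
        frame = render_us_frame(pose, identity(), coarse_geometry, p)
        center, fitted = fit_circle(frame.image, coarse_geometry, radius)
        assert np.allclose(center, (0.0, 30.0), atol=0.1)
        assert fitted == pytest.approx(radius, abs=0.1)

    def test_pose_far_from_targets_is_blank(self, default_phantom, coarse_geometry):
        pose = RigidTransform.from_rotation_translation(np.eye(3), (500.0, 500.0, 500.0))
        frame = render_us_frame(pose, identity(), coarse_geometry, default_phantom)
        mask = coarse_geometry.sector_mask()
        assert np.all(frame.image[mask] == frame.image[mask][0])  # uniform background

    def test_common_translation_leaves_image_unchanged(self, coarse_geometry):
        shift = np.array([5.0, -3.0, 2.0])
        base = {"label": "7", "center": (0.0, 0.0, 45.0), "radii": (5.0, 5.0, 5.0)}
        p0 = build_phantom({"targets": [base]})
        p1 = build_phantom(
            {"targets": [{**base, "center": tuple(np.asarray(base["center"]) + shift)}]}
        )
        rot = np.column_stack([[1, 0, 0], [0, -1, 0], [0, 0, -1]]).astype(float)
        pose0 = RigidTransform.from_rotation_translation(rot, (0.0, 30.0, 45.0))
        pose1 = RigidTransform.from_rotation_translation(rot, shift + (0.0, 30.0, 45.0))
        f0 = render_us_frame(pose0, identity(), coarse_geometry, p0)
        f1 = render_us_frame(pose1, identity(), coarse_geometry, p1)
        assert np.any(f0.image == 255.0)  # the target is actually in view
        assert np.array_equal(f0.image, f1.image)

    def test_ring_pixels_lie_on_sphere_surface(self, coarse_geometry):
        # ground-truth chain consistency: bright rim pixels map onto the
        # ellipsoid surface within rendering tolerance
        center = np.array([3.0, -2.0, 45.0])
        radius = 5.0
        p = build_phantom({"targets": [{"label": "7", "center": center, "radii": [radius] * 3}]})
        rot = np.column_stack([[1, 0, 0], [0, -1, 0], [0, 0, -1]]).astype(float)
        pose = RigidTransform.from_rotation_translation(rot, center + (0.0, 25.0, 0.0))
        frame = render_us_frame(pose, identity(), coarse_geometry, p)
        ring = frame.image == 255.0
        x, y = coarse_geometry.pixel_coordinates()
        pts_us = np.column_stack([x[ring], y[ring], np.zeros(int(ring.sum()))])
        pts_world = pts_us @ pose.rotation.T + pose.translation
        dist = np.linalg.norm(pts_world - center, axis=1)
        tol = 0.4 + coarse_geometry.pixel_spacing_mm / 2  # ring half-width + half pixel
        assert np.all(np.abs(dist - radius) <= tol + 1e-9)


class TestEbusSession:
    def test_default_protocol_yields_33_acquisitions(self, default_phantom, coarse_geometry):
        session = simulate_ebus_session(
            default_phantom,
            default_calibration_truth(),
            noise=NoiseModel.zero(),
            geometry=coarse_geometry,
        )
        assert len(session.acquisitions) == 33  # 11 targets x 3 repetitions
        labels = {a.target_label for a in session.acquisitions}
        assert labels == set(STATION_LABELS)

    def test_seeded_session_is_reproducible(self, coarse_geometry):
        p = build_phantom(
            {"targets": [{"label": "7", "center": (0.0, -10.0, 45.0), "radii": (5, 5, 5)}]}
        )
        kwargs = dict(
            calib_truth=default_calibration_truth(),
            noise=NoiseModel(seed=21),
            geometry=coarse_geometry,
            repetitions=1,
        )
        s1 = simulate_ebus_session(p, **kwargs)
        s2 = simulate_ebus_session(p, **kwargs)
        a1, a2 = s1.acquisitions[0], s2.acquisitions[0]
        assert np.array_equal(
            np.stack([f.image for f in a1.frames]), np.stack([f.image for f in a2.frames])
        )
        for p1, p2 in zip(a1.tracking.poses, a2.tracking.poses):
            assert np.array_equal(p1.matrix, p2.matrix)

    def test_unreachable_target_skipped_with_warning(self, coarse_geometry):
        p = build_phantom(
            {
                "targets": [
                    {"label": "7", "center": (0.0, -10.0, 45.0), "radii": (5, 5, 5)},
                    # 24.9 mm off the centerline: valid phantom, but beyond
                    # a shallow 20 mm imaging depth
                    {"label": "10L", "center": (0.0, -24.0, 48.0), "radii": (4, 4, 4)},
                ]
            }
        )
        shallow = SectorGeometry(depth_range=(3.0, 20.0), pixel_spacing_mm=0.4)
        with pytest.warns(UserWarning, match="exceeds imaging depth"):
            session = simulate_ebus_session(
                p, default_calibration_truth(), noise=NoiseModel.zero(),
                geometry=shallow, repetitions=1,
            )
        assert [a.target_label for a in session.acquisitions] == ["7"]


class TestCalibrationSession:
    def test_default_protocol_yields_18_recordings(self):
        recs, p_r, gt = simulate_calibration_session(
            default_calibration_truth(), noise=NoiseModel.zero(), sweep_halfspan=1.0
        )
        assert len(recs) == 18
        assert sorted({r.position_index for r in recs}) == list(range(1, 10))
        assert {r.direction for r in recs} == {"forward", "reverse"}

    def test_sweep_extent_frame_count_arithmetic(self):
        # 10 mm sweep at 1 mm/s -> 10 s -> 400 frames at 40 Hz
        recs, _, _ = simulate_calibration_session(
            default_calibration_truth(), noise=NoiseModel.zero(), sweep_halfspan=5.0,
            n_positions=1,
        )
        assert all(len(r.frames) == 400 for r in recs)

    def test_too_small_geometry_rejected(self):
        tiny = SectorGeometry(depth_range=(3.0, 12.0))
        with pytest.raises(ValueError, match="too small"):
            simulate_calibration_session(default_calibration_truth(), geometry=tiny)
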