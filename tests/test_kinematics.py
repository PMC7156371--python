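import numpy as np
import pytest

import chewgear as cg
from chewgear.io_formats import AnatomicalFrame, LandmarkSet, MarkerDataset
from chewgear.kinematics import (
    DegenerateConfigurationError,
    RigidTransform,
    butterworth_lowpass,
    fill_gaps,
    filter_dataset,
    fit_rigid_transform,
    fix_cranial_frame,
    gape_distance,
    mandible_transforms,
    registration_rmsd,
    transform_landmarks,
)
from conftest import random_rotation


class TestButterworth:
    def test_dc_gain_exactly_one(self):
        x = np.full(200, 7.25)
        np.testing.assert_allclose(butterworth_lowpass(x, 30, 4, 150), x, atol=1e-10)

    def test_passband_sinusoid_preserved(self):
        # 5 Hz at 150 fps, 30 Hz cutoff: two-pass |H|^2 at f/fc = 1/6 is
        # essentially unity, and zero-phase filtering must not shift the peak.
        t = np.arange(600) / 150.0
        x = np.sin(2 * np.pi * 5 * t)
        y = butterworth_lowpass(x, 30, 4, 150)
        core = slice(100, 500)
        assert abs(np.max(np.abs(y[core])) - 1.0) < 0.01
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (y[core].size - 1)
        assert lag == 0

    def test_stopband_sinusoid_suppressed(self):
        # at 2x cutoff the analog two-pass residual is 1/257 ~ 0.004; the
        # digital filter is at least that strong.
        t = np.arange(600) / 150.0
        x = np.sin(2 * np.pi * 60 * t)
        y = butterworth_lowpass(x, 30, 4, 150)
        assert np.max(np.abs(y[100:500])) < 0.01

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_lowpass(np.zeros(100), 75, 4, 150)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            butterworth_lowpass(np.zeros(10), 30, 4, 150)


class TestFillGaps:
    def test_short_gap_linearly_interpolated(self):
        arr = np.linspace(0, 9, 10)[:, None] * np.ones(3)
        arr[3:5] = np.nan
        ds = fill_gaps(MarkerDataset({"m": arr}), max_gap=5)
        np.testing.assert_allclose(ds.positions("m")[:, 0], np.linspace(0, 9, 10))

    def test_long_gap_left_missing(self):
        arr = np.ones((12, 3))
        arr[2:9] = np.nan  # 7-frame gap > max 5
        ds = fill_gaps(MarkerDataset({"m": arr}), max_gap=5)
        assert ds.missing_mask("m")[2:9].all()

    def test_boundary_gap_left_missing(self):
        arr = np.ones((6, 3))
        arr[0] = np.nan
        ds = fill_gaps(MarkerDataset({"m": arr}))
        assert ds.missing_mask("m")[0]


class TestFitRigidTransform:
    def _cloud(self, rng):
        return rng.uniform(-20, 20, (4, 3))

    def test_identity(self, rng):
        p = self._cloud(rng)
        T = fit_rigid_transform(p, p)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_pure_translation(self, rng):
        p = self._cloud(rng)
        T = fit_rigid_transform(p, p + np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, [1, 2, 3], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_known_transform_recovered(self, seed):
        rng = np.random.default_rng(seed)
        p = self._cloud(rng)
        ang = np.radians(30)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        t = np.array([5.0, -2.0, 1.0])
        q = p @ R.T + t
        T = fit_rigid_transform(p, q)
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)
        np.testing.assert_allclose(T.translation, t, atol=1e-9)
        assert registration_rmsd(T, p, q) < 1e-9

    def test_three_point_matches_frame_construction_oracle(self, rng):
        # independent oracle for 3 points: build orthonormal frames from the
        # triangles and compose them; exact for congruent noiseless triangles.
        def frame(pts):
            e1 = pts[1] - pts[0]
            e1 = e1 / np.linalg.norm(e1)
            w = pts[2] - pts[0]
            e2 = w - (w @ e1) * e1
            e2 = e2 / np.linalg.norm(e2)
            return np.column_stack([e1, e2, np.cross(e1, e2)])

        for _ in range(20):
            p = rng.uniform(-10, 10, (3, 3))
            R = random_rotation(rng)
            t = rng.uniform(-5, 5, 3)
            q = p @ R.T + t
            R_oracle = frame(q) @ frame(p).T
            T = fit_rigid_transform(p, q)
            np.testing.assert_allclose(T.rotation, R_oracle, atol=1e-6)

    def test_reflection_corrected_to_proper_rotation(self, rng):
        # near-planar cloud mirrored: least-squares favours a reflection,
        # which must be corrected to det = +1
        p = rng.uniform(-10, 10, (4, 3))
        p[:, 2] *= 0.01
        q = p * np.array([1, 1, -1])
        T = fit_rigid_transform(p, q)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid_transform(line, line)
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid_transform(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCranialFrame:
    def test_already_stationary_scene_unchanged(self):
        rec = cg.build_recording(
            cg.SyntheticScenario(noise_sigma_mm=0.0, drift_translation_mm=0.0, drift_rotation_deg=0.0)
        )
        fixed = fix_cranial_frame(rec.dataset, rec.config.cranial, 0)
        for name in rec.dataset.marker_names:
            np.testing.assert_allclose(
                fixed.positions(name), rec.dataset.positions(name), atol=1e-9
            )
        assert fixed.coordinate_frame_tag == "cranial"

    def test_scene_drift_removed_noiselessly(self, rec_noiseless):
        rec, _ = rec_noiseless
        fixed = fix_cranial_frame(rec.dataset, rec.config.cranial, 0)
        for name in rec.config.cranial:
            dev = fixed.positions(name) - fixed.positions(name)[0]
            assert np.abs(dev).max() < 1e-9

    def test_cranial_residual_under_noise(self):
        # Monte-Carlo over seeds: registration residual RMS stays within
        # twice the marker noise.
        for seed in range(3):
            rec = cg.build_recording(cg.SyntheticScenario(noise_sigma_mm=0.15, seed=seed))
            fixed = fix_cranial_frame(rec.dataset, rec.config.cranial, 0)
            devs = []
            for name in rec.config.cranial:
                x = fixed.positions(name)
                devs.append(x - x.mean(axis=0))
            rms = np.sqrt(np.mean(np.concatenate(devs) ** 2))
            assert rms <= 0.3

    def test_registration_equivariance(self, rec_noiseless, rng):
        # pre-rotating the whole lab scene rotates the cranial-frame output
        # by exactly the same rigid transform (the reference pose moves with
        # the scene), so derived geometry is unchanged
        rec, _ = rec_noiseless
        R = random_rotation(rng)
        t = np.array([30.0, -12.0, 7.0])
        rotated = rec.dataset.copy()
        for name in rotated.marker_names:
            rotated.markers[name] = rotated.markers[name] @ R.T + t
        a = fix_cranial_frame(rec.dataset, rec.config.cranial, 0)
        b = fix_cranial_frame(rotated, rec.config.cranial, 0)
        for name in rec.dataset.marker_names:
            np.testing.assert_allclose(
                b.positions(name), a.positions(name) @ R.T + t, atol=1e-8
            )

    def test_degenerate_configuration_names_frame(self, rng):
        pos = rng.uniform(-10, 10, (4, 3))
        arr = {f"c{i}": np.tile(pos[i], (5, 1)) for i in range(4)}
        arr["c0"][3] = np.nan
        arr["c1"][3] = np.nan
        ds = MarkerDataset(arr)
        with pytest.raises(DegenerateConfigurationError, match="frame 3"):
            fix_cranial_frame(ds, ("c0", "c1", "c2", "c3"), 0)


class TestMandibleTransforms:
    def test_reference_frame_is_identity(self, rec_plain):
        rec = rec_plain
        T0 = mandible_transforms(rec.dataset, rec.config.mandibular, 0)[0]
        np.testing.assert_allclose(T0.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T0.translation, 0, atol=1e-9)

    def test_rotation_angle_matches_generator(self, rec_plain):
        rec = rec_plain
        Ts = mandible_transforms(rec.dataset, rec.config.mandibular, 0)
        true_phi = np.abs(rec.truth.phi - rec.truth.phi[0])
        got = np.array([T.rotation_angle() for T in Ts])
        # arccos of the rotation trace is ill-conditioned near zero rotation,
        # so the tolerance is sqrt(eps)-limited rather than 1e-9
        np.testing.assert_allclose(got, true_phi, atol=5e-8)

    def test_marker_reconstruction_rmsd(self, rec_plain):
        rec = rec_plain
        ds = rec.dataset
        Ts = mandible_transforms(ds, rec.config.mandibular, 0)
        ref = np.stack([ds.positions(r)[0] for r in rec.config.mandibular])
        for f in (0, 50, 123, 300):
            got = Ts[f].apply(ref)
            want = np.stack([ds.positions(r)[f] for r in rec.config.mandibular])
            assert registration_rmsd(RigidTransform(np.eye(3), np.zeros(3)), got, want) < 1e-9


class TestTransformLandmarks:
    def test_identity_transforms_constant(self):
        lm = LandmarkSet({"p": np.array([1.0, 2.0, 3.0])})
        Ts = [RigidTransform.identity() for _ in range(4)]
        traj = transform_landmarks(lm, Ts)["p"]
        np.testing.assert_allclose(traj, np.tile([1, 2, 3], (4, 1)))

    def test_isometry_preserves_landmark_distances(self, rec_noiseless):
        # rigid transforms preserve distances between co-moving landmarks
        rec, res = rec_noiseless
        tip = res.landmark_trajectories["coronoid_R"]
        gon = res.landmark_trajectories["gonial_R"]
        d = np.linalg.norm(tip - gon, axis=1)
        np.testing.assert_allclose(d, d[0], atol=1e-9)

    def test_generator_coronoid_trajectory_reproduced(self, rec_plain):
        from chewgear.kinematics import transform_landmarks as tlm

        rec = rec_plain
        Ts = mandible_transforms(rec.dataset, rec.config.mandibular, 0)
        tip = tlm(rec.landmarks, Ts)["coronoid_R"]
        # truth: coronoid tip rotated by the true jaw angle (cranial frame)
        c = np.asarray(rec.scenario.rotation_center, float)
        p0 = np.asarray(rec.scenario.coronoid_tip, float)
        phi = rec.truth.phi
        want = np.stack(
            [
                [
                    np.cos(a) * (p0[0] - c[0]) + np.sin(a) * (p0[2] - c[2]) + c[0],
                    p0[1],
                    -np.sin(a) * (p0[0] - c[0]) + np.cos(a) * (p0[2] - c[2]) + c[2],
                ]
                for a in phi
            ]
        )
        np.testing.assert_allclose(tip, want, atol=1e-7)


class TestGape:
    def test_pythagorean_displacement(self):
        arr = np.zeros((3, 3))
        arr[2] = [3.0, 4.0, 0.0]
        ds = MarkerDataset({"ant": arr}, coordinate_frame_tag="cranial")
        g = gape_distance(ds, "ant", occlusion_frame=0)
        assert g.values[0] == 0.0
        assert g.values[2] == pytest.approx(5.0)

    def test_generator_gape_recovered_exactly_unfiltered(self, rec_plain):
        rec = rec_plain
        g = gape_distance(rec.dataset, "mand_ant", frame=rec.config.frame)
        np.testing.assert_allclose(g.values, rec.truth.gape, atol=1e-9)

    def test_pipeline_gape_within_filter_distortion(self, rec_noiseless):
        # the 30 Hz low-pass rounds the acceleration discontinuities at the
        # phase junctions by a few hundredths of a mm
        rec, res = rec_noiseless
        np.testing.assert_allclose(res.gape.values, rec.truth.gape, atol=0.05)

    def test_gape_invariant_to_lab_coordinates(self, rec_noiseless, rng):
        rec, _ = rec_noiseless
        R = random_rotation(rng)
        rotated = rec.dataset.copy()
        for name in rotated.marker_names:
            rotated.markers[name] = rotated.markers[name] @ R.T + np.array([5.0, 5.0, 5.0])
        res2 = cg.run_pipeline_data(rec.config, rotated, rec.landmarks)
        res1 = cg.run_pipeline_data(rec.config, rec.dataset, rec.landmarks)
        np.testing.assert_allclose(res2.gape.values, res1.gape.values, atol=1e-8)

    def test_missing_occlusion_marker_rejected(self):
        arr = np.zeros((5, 3))
        arr[1] = np.nan
        ds = MarkerDataset({"ant": arr})
        with pytest.raises(ValueError, match="occlusion"):
            gape_distance(ds, "ant", occlusion_frame=1)


class TestZeroPhaseProperty:
    def test_filtered_dataset_peaks_unshifted(self, rec_noiseless):
        rec, _ = rec_noiseless
        raw = rec.dataset.positions("mand_ant")[:, 2]
        ds = filter_dataset(rec.dataset, 30, 4)
        filt = ds.positions("mand_ant")[:, 2]
        x = raw - raw.mean()
        y = filt - filt.mean()
        lag = np.argmax(np.correlate(y, x, "full")) - (x.size - 1)
        assert lag == 0
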