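import numpy as np
import pytest

import chewgear as cg
from chewgear.architecture import (
    PipelineError,
    bulging,
    compute_agr,
    fascicle_angles,
    fascicle_length,
    instantaneous_velocity,
    loess_smooth,
    muscle_length,
    normalize_to_zero,
    per_cycle_agr,
    run_pipeline,
)
from chewgear.io_formats import AnatomicalFrame
from conftest import random_rotation


class TestLengths:
    def test_fascicle_length_pythagorean(self):
        m1 = np.zeros((1, 3))
        m2 = np.array([[0.0, 3.0, 4.0]])
        assert fascicle_length(m1, m2)[0] == pytest.approx(5.0)

    def test_coincident_markers_flagged(self):
        with pytest.warns(UserWarning, match="coincident"):
            d = fascicle_length(np.zeros((2, 3)), np.zeros((2, 3)))
        assert (d == 0).all()

    def test_muscle_length_example(self):
        tip = np.zeros((1, 3))
        m3 = np.array([[0.0, 0.0, 10.0]])
        assert muscle_length(tip, m3)[0] == pytest.approx(10.0)

    def test_generator_lengths_recovered_noiseless(self, rec_plain):
        from chewgear.kinematics import mandible_transforms, transform_landmarks

        rec = rec_plain
        ds = rec.dataset
        l = fascicle_length(ds.positions("m1"), ds.positions("m2"))
        Ts = mandible_transforms(ds, rec.config.mandibular, 0)
        tip = transform_landmarks(rec.landmarks, Ts)["coronoid_R"]
        L = muscle_length(tip, ds.positions("m3"))
        np.testing.assert_allclose(l, rec.truth.fascicle_length, atol=1e-9)
        np.testing.assert_allclose(L, rec.truth.muscle_length, atol=1e-8)

    def test_rigid_rotation_leaves_lengths_unchanged(self, rng):
        a = rng.uniform(-5, 5, (20, 3))
        b = rng.uniform(-5, 5, (20, 3))
        R = random_rotation(rng)
        t = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            muscle_length(a @ R.T + t, b @ R.T + t), muscle_length(a, b), atol=1e-10
        )

    def test_missing_frames_masked(self):
        m1 = np.zeros((3, 3))
        m2 = np.ones((3, 3))
        m2[1] = np.nan
        d = fascicle_length(m1, m2)
        assert np.isnan(d[1]) and np.isfinite(d[[0, 2]]).all()


class TestFascicleAngles:
    def test_parallel_vectors_zero_in_both_planes(self):
        m1 = np.zeros((1, 3))
        m2 = np.array([[1.0, 2.0, 3.0]])
        m3 = np.array([[2.0, 4.0, 6.0]])
        sag, cor = fascicle_angles(m1, m2, m3, AnatomicalFrame())
        assert sag[0] == pytest.approx(0.0, abs=1e-9)
        assert cor[0] == pytest.approx(0.0, abs=1e-9)

    def test_hand_projection_example(self):
        # AP = x, ML = y, SI = z; fascicle tilted 20 deg toward ML from SI:
        # coronal angle 20 deg, sagittal projection parallel to reference
        th = np.radians(20)
        m1 = np.zeros((1, 3))
        m2 = np.array([[0.0, np.sin(th), np.cos(th)]])
        m3 = np.array([[0.0, 0.0, 1.0]])
        sag, cor = fascicle_angles(m1, m2, m3, AnatomicalFrame())
        assert cor[0] == pytest.approx(20.0, abs=1e-9)
        assert sag[0] == pytest.approx(0.0, abs=1e-9)

    def test_generator_sagittal_plane_mode(self):
        # muscle line and fascicle both exactly in the sagittal plane
        # (attachment directly above the coronoid tip in ML): the sagittal
        # angle equals the prescribed pinnation, the coronal angle vanishes
        rec = cg.build_recording(
            cg.SyntheticScenario(noise_sigma_mm=0.0, coronal_tilt_deg=0.0,
                                 m3_position=(12.0, 10.0, 58.0),
                                 drift_translation_mm=0.0, drift_rotation_deg=0.0)
        )
        ds = rec.dataset
        sag, cor = fascicle_angles(
            ds.positions("m1"), ds.positions("m2"), ds.positions("m3"), AnatomicalFrame()
        )
        np.testing.assert_allclose(sag, rec.truth.theta_deg, atol=1e-6)
        np.testing.assert_allclose(cor, 0.0, atol=1e-6)
        # pipeline projections agree with the generator's truth projections
        np.testing.assert_allclose(sag, rec.truth.sagittal_deg, atol=1e-9)

    def test_degenerate_projection_masked(self):
        m1 = np.zeros((1, 3))
        m2 = np.array([[0.0, 1.0, 0.0]])  # no AP/SI components
        m3 = np.array([[0.0, 0.0, 1.0]])
        sag, _ = fascicle_angles(m1, m2, m3, AnatomicalFrame())
        assert np.isnan(sag[0])


class TestVelocity:
    def test_constant_series_zero(self):
        assert (instantaneous_velocity(np.full(10, 3.3), 150.0) == 0).all()

    def test_linear_ramp_rate(self):
        v = instantaneous_velocity(np.arange(10.0) * 2, 150.0)
        np.testing.assert_allclose(v, 300.0)

    def test_sine_taylor_remainder_bound(self):
        fr, f = 150.0, 3.0
        t = np.arange(0, 1, 1 / fr)
        v = instantaneous_velocity(np.sin(2 * np.pi * f * t), fr)
        vt = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 / fr**2 / 6
        assert np.abs(v - vt)[1:-1].max() <= bound * 1.05

    def test_masked_neighbours_mask_output(self):
        y = np.arange(10.0)
        y[4] = np.nan
        v = instantaneous_velocity(y, 1.0)
        assert np.isnan(v[3:6]).all() and np.isfinite(v[0])


class TestLoess:
    def test_exactly_linear_reproduced(self):
        x = np.linspace(0, 100, 50)
        y = 3 * x - 7
        np.testing.assert_allclose(loess_smooth(x, y, 0.25), y, atol=1e-9)
        np.testing.assert_allclose(loess_smooth(x, y, 1.0), y, atol=1e-9)

    def test_noisy_sinusoid_rmse_below_sigma(self):
        sigma = 0.5
        x = np.linspace(0, 1, 150)
        yt = np.sin(2 * np.pi * x)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ys = loess_smooth(x, yt + rng.normal(0, sigma, x.size), 0.25)
            assert np.sqrt(np.mean((ys - yt) ** 2)) < sigma

    def test_window_and_count_preconditions(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match=">= 10"):
            loess_smooth(x, x, 0.5)
        x = np.arange(12.0)
        with pytest.raises(ValueError, match="window"):
            loess_smooth(x, x, 0.1)
        with pytest.raises(ValueError, match="span"):
            loess_smooth(x, x, 1.5)


class TestAgr:
    def test_identical_series_unity(self):
        v = np.sin(np.linspace(0.3, 2.8, 40)) + 1.5
        agr, valid = compute_agr(v, v, epsilon=0.01)
        assert valid.all()
        np.testing.assert_allclose(agr, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        fv = rng.uniform(0.5, 2.0, 30)
        mv = fv * rng.uniform(0.8, 1.2, 30)
        a1, _ = compute_agr(mv, fv, 0.01)
        a2, _ = compute_agr(5 * mv, 5 * fv, 0.05)
        np.testing.assert_allclose(a1, a2)

    def test_zero_crossing_and_sign_mismatch_masked(self):
        fv = np.array([1.0, 1e-6, -1.0, 1.0])
        mv = np.array([1.0, 1.0, 1.0, 1.0])
        agr, valid = compute_agr(mv, fv, epsilon=0.01)
        assert valid.tolist() == [True, False, False, True]
        assert np.isnan(agr[1]) and np.isnan(agr[2])

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            compute_agr(np.ones(3), np.ones(3), 0.0)

    def test_constant_pinnation_closed_form_from_markers(self):
        # finite differences on emitted l(t), L(t) must match cos(theta0)
        rec = cg.build_recording(
            cg.SyntheticScenario(mode="constant_pinnation", theta_ref_deg=20.0,
                                 noise_sigma_mm=0.0, drift_translation_mm=0.0,
                                 drift_rotation_deg=0.0)
        )
        l = rec.truth.fascicle_length
        L = rec.truth.muscle_length
        dl, dL = np.gradient(l), np.gradient(L)
        sel = np.abs(dl) > 0.02 * np.abs(dl).max()
        np.testing.assert_allclose(dL[sel] / dl[sel], np.cos(np.radians(20)), atol=1e-3)

    def test_constant_thickness_closed_form_from_markers(self):
        rec = cg.build_recording(
            cg.SyntheticScenario(mode="constant_thickness", theta_ref_deg=20.0,
                                 noise_sigma_mm=0.0, drift_translation_mm=0.0,
                                 drift_rotation_deg=0.0)
        )
        l, L, th = rec.truth.fascicle_length, rec.truth.muscle_length, rec.truth.theta_deg
        dl, dL = np.gradient(l), np.gradient(L)
        sel = np.abs(dl) > 0.05 * np.abs(dl).max()
        want = 1.0 / np.cos(np.radians(th[sel]))
        np.testing.assert_allclose(dL[sel] / dl[sel], want, rtol=0.01)


class TestNormalize:
    def test_min_and_max_modes(self):
        np.testing.assert_allclose(normalize_to_zero(np.array([3.0, 4, 5]), "min"), [0, 1, 2])
        np.testing.assert_allclose(normalize_to_zero(np.array([3.0, 4, 5]), "max"), [-2, -1, 0])

    def test_velocity_invariant_to_normalization(self):
        y = np.sin(np.linspace(0, 3, 40)) * 5 + 12
        v1 = instantaneous_velocity(y, 150.0)
        v2 = instantaneous_velocity(normalize_to_zero(y, "min"), 150.0)
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_zero(np.full(5, np.nan))


class TestBulging:
    def test_stationary_marker_zero(self):
        m2 = np.ones((10, 3))
        b = bulging(m2, AnatomicalFrame(), (0, 9))
        assert b.ap_range == 0 and b.ml_range == 0

    def test_ap_only_oscillation(self):
        m2 = np.zeros((20, 3))
        m2[:, 0] = 2 * np.sin(np.linspace(0, 2 * np.pi, 20))
        b = bulging(m2, AnatomicalFrame(), (0, 19))
        assert b.ap_range == pytest.approx(4.0, rel=1e-2)
        assert b.ml_range == 0

    def test_generator_bulge_amplitude_recovered(self, rec_noiseless):
        rec, res = rec_noiseless
        # the superficial marker's true per-cycle AP excursion
        m2 = rec.truth  # truth arrays are cranial-frame
        t0 = rec.truth.transitions[0]
        row = res.cycle_table.iloc[0]
        ds = res.dataset_cranial
        seg = ds.positions("m2")[t0["start"] : t0["end"] + 1]
        want_ap = seg[:, 0].max() - seg[:, 0].min()
        assert row.bulging_ap_mm == pytest.approx(want_ap, abs=1e-6)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            bulging(np.ones((5, 3)), AnatomicalFrame(), (3, 2))


class TestPipeline:
    def test_constant_thickness_agr_matches_analytic(self, rec_noiseless):
        rec, res = rec_noiseless
        import chewgear.cycles as cyc

        t0 = rec.truth.transitions[0]
        truth_std = cyc.standardize_cycle(
            rec.truth.agr[t0["start"] : t0["end"] + 1], 50
        )
        agr = res.agr_by_food
        val = agr[agr.valid]
        rel = np.abs(val.agr.to_numpy() - truth_std[val.index.to_numpy() % 50])
        rel /= truth_std[val.index.to_numpy() % 50]
        assert rel.max() < 0.02

    def test_noisy_fascicle_length_correlation(self, rec_noisy):
        rec, res = rec_noisy
        ds = res.dataset_cranial
        l = fascicle_length(ds.positions("m1"), ds.positions("m2"))
        r = np.corrcoef(l, rec.truth.fascicle_length)[0, 1]
        assert r >= 0.99

    def test_empty_marker_file_clean_error(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        lm = tmp_path / "lm.csv"
        lm.write_text("name,x,y,z\ncoronoid_R,1,2,3\n")
        with pytest.raises(PipelineError, match="io_formats"):
            run_pipeline(cg.PipelineConfig(), str(empty), str(lm))

    def test_hypothesis1_pattern_on_generator_data(self, rec_noiseless):
        # fascicle length minimal and angles maximal at minimum gape when the
        # generator prescribes monotone theta(gape)
        rec, res = rec_noiseless
        food = next(iter(res.food_curves))
        cur = res.food_curves[food]
        i_min = int(np.argmin(cur["gape"][0]))
        assert abs(int(np.argmin(cur["fascicle_length"][0])) - i_min) <= 1
        assert abs(int(np.argmin(cur["muscle_length"][0])) - i_min) <= 1
        assert abs(int(np.argmax(cur["sagittal_angle"][0])) - i_min) <= 1
        i_max = int(np.argmax(cur["gape"][0]))
        l = cur["fascicle_length"][0]
        assert l[i_min] < l[i_max]

    def test_masked_agr_fraction_reported(self, rec_noiseless):
        _, res = rec_noiseless
        assert "masked_agr_fraction" in res.log
        assert 0 <= res.log["masked_agr_fraction"] < 0.5

    def test_per_cycle_agr_matches_mode(self, rec_noiseless):
        rec, res = rec_noiseless
        agr, valid = per_cycle_agr(res.per_cycle[0])
        med = np.nanmedian(agr[valid])
        t0 = rec.truth.transitions[0]
        truth_med = np.median(rec.truth.agr[t0["start"] : t0["end"] + 1])
        assert med == pytest.approx(truth_med, rel=0.02)
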