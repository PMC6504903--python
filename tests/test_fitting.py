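"""Cross-section extraction, pose initialisation and the constrained
eight-spot global fit."""

import math

import numpy as np
import pytest

from conftest import seeds_from_truth
from torusalign.fitting import (
    FitConfig,
    RingFitError,
    TiltedRingModel,
    extract_cross_sections,
    fit_quality,
    initialize_pose,
)
from torusalign.geometry import RingPose
from torusalign.io import ParticleSeed, VolumeImage
from torusalign.simulate import SceneSpec, simulate_toroid_volume


class TestExtractCrossSections:
    def test_constant_volume_gives_constant_sections(self):
        v = VolumeImage(np.full((10, 64, 64), 7.0), (120, 40, 40))
        cs = extract_cross_sections(v, (31.5, 31.5), 20)
        for img in cs.images.values():
            np.testing.assert_allclose(img, 7.0, atol=1e-9)
            assert img.shape[0] == 10  # z extent preserved

    def test_two_pixel_averaging(self):
        # plane y=c bright (2), plane y=c+1 dark (0): the 0-degree strip
        # centered between them averages to 1
        data = np.zeros((6, 64, 64))
        data[:, 30, :] = 2.0
        v = VolumeImage(data, (120, 40, 40))
        cs = extract_cross_sections(v, (31.5, 30.5), 20)
        np.testing.assert_allclose(cs.images["yz"], 1.0, atol=1e-9)

    def test_linearity_in_source(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (8, 48, 48))
        b = rng.uniform(0, 1, (8, 48, 48))
        vox = (120, 40, 40)
        g, h = (23.5, 23.5), 12
        cs_a = extract_cross_sections(VolumeImage(a, vox), g, h)
        cs_b = extract_cross_sections(VolumeImage(b, vox), g, h)
        cs_ab = extract_cross_sections(VolumeImage(a + b, vox), g, h)
        for k in cs_a.images:
            np.testing.assert_allclose(
                cs_ab.images[k], cs_a.images[k] + cs_b.images[k], atol=1e-9
            )

    def test_strip_exiting_volume_rejected(self):
        v = VolumeImage(np.zeros((4, 32, 32)), (120, 40, 40))
        with pytest.raises(ValueError, match="crop"):
            extract_cross_sections(v, (16, 16), 30)

    def test_toroid_spot_separation(self, standard_scene):
        # a fitted toroid's 0-degree section shows two peaks ~2r apart
        _, vol, truth = standard_scene
        cs = extract_cross_sections(
            vol, (truth.pose.xc, truth.pose.yc), 1.5 * truth.pose.r
        )
        img = cs.images["yz"]
        prof = img.sum(axis=0)
        mid = prof.size // 2
        t1 = cs.t_coords[int(np.argmax(prof[:mid]))]
        t2 = cs.t_coords[mid + int(np.argmax(prof[mid:]))]
        # projected chord of the tilted ring on the x axis
        expected = 2 * truth.pose.r * math.sqrt(
            1 - (math.sin(truth.pose.theta) * math.cos(truth.pose.phi)) ** 2
        )
        assert abs((t2 - t1) - expected) <= 2.0


class TestInitializePose:
    def test_exact_seed_geometry(self):
        data = np.zeros((9, 128, 128))
        data[4] = 1.0  # z profile peaks at slice 4
        v = VolumeImage(data, (120, 40, 40))
        seed = ParticleSeed(
            "p", "c",
            [[63.5 + 40, 63.5], [63.5, 63.5 + 40],
             [63.5 - 40, 63.5], [63.5, 63.5 - 40]],
        )
        pose = initialize_pose(seed, v)
        assert pose.r == pytest.approx(40.0)
        assert pose.xc == pytest.approx(63.5)
        assert pose.yc == pytest.approx(63.5)
        assert pose.zc / v.aspect == pytest.approx(4)
        assert pose.theta == 0.0

    def test_degenerate_seeds_rejected(self):
        v = VolumeImage(np.zeros((4, 64, 64)), (120, 40, 40))
        with pytest.raises(ValueError, match="degenerate"):
            initialize_pose(
                ParticleSeed("p", "c",
                             [[10, 10], [20, 20], [30, 30], [40, 40]]), v
            )
        with pytest.raises(ValueError, match="degenerate"):
            initialize_pose(
                ParticleSeed("p", "c",
                             [[10, 10], [10, 10], [10, 10], [10, 10]]), v
            )

    def test_perturbed_seeds_bracket_radius(self, standard_scene):
        _, vol, truth = standard_scene
        rng = np.random.default_rng(3)
        seed = seeds_from_truth(truth.pose, rng, jitter=2.0)
        pose = initialize_pose(seed, vol)
        assert 36 <= pose.r <= 44


class TestFitRing:
    def test_noiseless_recovery(self, noiseless_scene):
        _, vol, truth = noiseless_scene
        seed = seeds_from_truth(truth.pose, np.random.default_rng(1))
        res = TiltedRingModel.from_volume(vol, seed).fit()
        assert abs(res.pose.r - truth.pose.r) < 0.5
        assert abs(math.degrees(res.pose.theta - truth.pose.theta)) < 2.0
        dphi = abs(
            (math.degrees(res.pose.phi - truth.pose.phi) + 180) % 360 - 180
        )
        assert dphi <= 10.0 + 1e-6

    def test_noisy_recovery_and_quality(self, standard_fit):
        _, res, truth = standard_fit
        assert abs(res.pose.r - truth.pose.r) / truth.pose.r < 0.02
        assert abs(math.degrees(res.pose.theta - truth.pose.theta)) < 3.0
        q = fit_quality(res)
        assert q.passed and q.n_spots == 8

    def test_linked_sigmas_exact(self, standard_fit):
        _, res, _ = standard_fit
        sl = {g.sigma_lateral for g in res.gaussians}
        sz = {g.sigma_z for g in res.gaussians}
        assert len(sl) == 1 and len(sz) == 1

    def test_amplitude_pairs_within_factor_two(self, standard_fit):
        _, res, _ = standard_fit
        for i in range(4):
            a1, a2 = res.amplitudes[i]
            assert 0.5 - 1e-9 <= a1 / a2 <= 2.0 + 1e-9

    def test_phi_grid_optimality(self, standard_fit):
        _, res, _ = standard_fit
        best_phi = round(math.degrees(res.pose.phi), 3) % 360
        costs = res.phi_grid_profile
        assert costs[best_phi] <= min(costs.values()) + 1e-9

    def test_flat_ring_flags_phi_undetermined(self):
        spec = SceneSpec(diameter_nm=160, theta_deg=0.0, phi_deg=0.0, seed=4,
                         poisson=False, read_noise_sd=0.0)
        vol, truth = simulate_toroid_volume(spec)
        seed = seeds_from_truth(truth.pose, np.random.default_rng(2))
        res = TiltedRingModel.from_volume(vol, seed).fit()
        assert math.degrees(res.pose.theta) <= 2.0
        assert "phi_undetermined" in res.constraint_flags

    def test_radius_bound_activation(self, standard_scene):
        # init radius forced to 2.5x truth: the factor-2 radius constraint
        # clamps the fit, and the active bound is flagged
        _, vol, truth = standard_scene
        init = RingPose(
            truth.pose.xc, truth.pose.yc, truth.pose.zc,
            2.5 * truth.pose.r, 0.0, 0.0,
        )
        cs = extract_cross_sections(vol, (init.xc, init.yc), 70)
        res = TiltedRingModel(cs, init).fit()
        assert "radius_bound" in res.constraint_flags
        assert res.pose.r == pytest.approx(1.25 * truth.pose.r, rel=1e-3)

    def test_negative_control_fails_quality(self, standard_scene):
        # a model frozen far from the truth leaves large residuals
        _, vol, truth = standard_scene
        seed = seeds_from_truth(truth.pose, np.random.default_rng(2))
        model = TiltedRingModel.from_volume(vol, seed)
        res = model.fit()
        bad = res
        # simulate "wrong model": rebuild result with residuals of a far pose
        collect = {}
        far = np.array([
            res.pose.xc, res.pose.yc, res.pose.zc, res.pose.r * 0.55,
            0.0, res.sigma_lateral, res.sigma_z,
        ])
        r = model._varpro_residual(far, res.pose.phi, collect=collect)
        rms = float(np.sqrt(np.mean(r**2)))
        assert rms > 3 * res.residual_rms

    def test_translation_equivariance(self, standard_scene):
        _, vol, truth = standard_scene
        shift = (6, -4)  # (dx, dy) integer pixels
        data = np.roll(vol.data, (shift[1], shift[0]), axis=(1, 2))
        vol2 = VolumeImage(data, vol.voxel_size)
        seed = seeds_from_truth(truth.pose, np.random.default_rng(5))
        seed2 = ParticleSeed("p", "sim", seed.points + np.array(shift))
        res1 = TiltedRingModel.from_volume(vol, seed).fit()
        res2 = TiltedRingModel.from_volume(vol2, seed2).fit()
        assert res2.pose.xc - res1.pose.xc == pytest.approx(shift[0], abs=0.1)
        assert res2.pose.yc - res1.pose.yc == pytest.approx(shift[1], abs=0.1)
        assert res2.pose.r == pytest.approx(res1.pose.r, abs=0.1)
        assert math.degrees(abs(res2.pose.theta - res1.pose.theta)) < 0.5

    def test_too_few_crossings_rejected(self, standard_scene):
        _, vol, truth = standard_scene
        cs = extract_cross_sections(vol, (truth.pose.xc, truth.pose.yc), 50)
        init = RingPose(truth.pose.xc + 100, truth.pose.yc, truth.pose.zc,
                        30.0, 0.0, 0.0)
        with pytest.raises(RingFitError, match="crossings"):
            TiltedRingModel(cs, init)

    def test_summary_and_plot(self, standard_fit, tmp_path):
        _, res, _ = standard_fit
        text = res.summary()
        assert "radius" in text and "tilt" in text
        res.plot_cross_sections(tmp_path / "fit.png")
        assert (tmp_path / "fit.png").exists()

    def test_fast_centers_match_geometry_module(self, standard_fit):
        # the optimiser's inlined crossing solver must agree with the
        # public plane_crossings implementation
        from torusalign.geometry import PLANE_ANGLES, plane_crossings

        model, res, _ = standard_fit
        rng = np.random.default_rng(8)
        for _ in range(25):
            xc = model.init.xc + rng.uniform(-5, 5)
            yc = model.init.yc + rng.uniform(-5, 5)
            zc = model.init.zc + rng.uniform(-2, 2)
            r = model.init.r * rng.uniform(0.6, 1.6)
            th = rng.uniform(0, 0.75)
            ph = rng.uniform(0, 2 * math.pi)
            fast = model._spot_centers(xc, yc, zc, r, th, ph)
            pose = RingPose(xc, yc, zc, r, th, ph)
            guess = model._guess3()
            for key, (t_fast, z_fast) in fast.items():
                c = plane_crossings(pose, key, guess)
                alpha = math.radians(PLANE_ANGLES[key])
                u = np.array([math.cos(alpha), math.sin(alpha)])
                t_ref = (c.points[:, :2] - guess[:2]) @ u
                z_ref = c.points[:, 2] / model.cs.aspect
                np.testing.assert_allclose(t_fast, t_ref, atol=1e-8)
                np.testing.assert_allclose(z_fast, z_ref, atol=1e-8)
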