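"""Radial profiles, two-Gaussian diameter fits, Monte Carlo errors,
fiducial normalization, significance tests and flux partitioning."""

import math

import numpy as np
import pytest

from torusalign.averaging import AverageMap
from torusalign.io import VolumeImage
from torusalign.metrics import (
    AnnulusMask,
    DiameterResolutionError,
    SectorMask,
    _fit_two_gauss,
    compare_diameters,
    diameter_from_average,
    monte_carlo_error,
    normalize_diameters,
    radial_profile,
    toroid_bridge_fraction,
)

VOX = (6.0, 2.0, 2.0)  # nm; 2 nm lateral pixels as in the simulator


def ring_image(radius_px, sigma=2.0, size=121, amp=100.0, nz=5):
    """Synthetic flat averaged-ring volume: blurred annulus in every slice
    (vectorised analytic model, independent of the simulator)."""
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    ang = np.linspace(0, 2 * math.pi, 720, endpoint=False)
    img = np.zeros((size, size))
    for a in ang:
        img += np.exp(
            -(
                (xx - c - radius_px * math.cos(a)) ** 2
                + (yy - c - radius_px * math.sin(a)) ** 2
            )
            / (2 * sigma**2)
        )
    img *= amp / img.max()
    return VolumeImage(np.repeat(img[None], nz, axis=0), VOX)


class TestRadialProfile:
    def test_constant_image_constant_profile(self):
        v = VolumeImage(np.full((3, 41, 41), 3.5), VOX)
        rp = radial_profile(v)
        np.testing.assert_allclose(rp.mean_intensity, 3.5, atol=1e-9)
        assert rp.radii_px[0] == 0 and np.all(np.diff(rp.radii_px) > 0)

    def test_blurred_annulus_argmax(self):
        v = ring_image(20.0, sigma=1.0, size=81)
        rp = radial_profile(v)
        assert abs(rp.argmax_radius_px - 20.0) <= 1.0

    def test_simulated_truth_42_5_px(self):
        v = ring_image(42.5, sigma=2.0, size=131)
        rp = radial_profile(v)
        assert abs(rp.argmax_radius_px - 42.5) <= 1.0

    def test_center_outside_rejected(self):
        v = VolumeImage(np.zeros((3, 11, 11)), VOX)
        with pytest.raises(ValueError):
            radial_profile(v, center=(99, 0))


class TestTwoGaussFit:
    def test_exact_recovery(self):
        x = np.arange(201, dtype=float)
        p_true = np.array([100 - 42.5, 100 + 42.5, 30.0, 30.0, 12.5, 2.0])
        from torusalign.metrics import _two_gauss

        f = _fit_two_gauss(x, _two_gauss(x, p_true))
        np.testing.assert_allclose(f.params, p_true, rtol=1e-6, atol=1e-6)
        assert f.separation_px == pytest.approx(85.0, abs=1e-6)

    def test_unresolved_profile_raises(self):
        x = np.arange(101, dtype=float)
        y = 10 * np.exp(-((x - 50.0) ** 2) / (2 * 8.0**2))
        with pytest.raises(DiameterResolutionError):
            _fit_two_gauss(x, y)


class TestDiameterFromAverage:
    def test_symmetric_ring(self):
        v = ring_image(42.5, sigma=2.0, size=131)
        est = diameter_from_average(v)
        # 42.5 px * 2 nm/px * 2 = 170 nm
        assert est.diameter_nm == pytest.approx(170.0, rel=0.01)
        assert est.symmetric

    def test_asymmetric_components_reported(self):
        # elliptical ring: vertical and horizontal pairs differ by ~15%
        size = 161
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size]
        ang = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        img = np.zeros((size, size))
        rv, rh = 48.5, 41.75
        for a in ang:
            img += np.exp(
                -(
                    (xx - c - rh * math.cos(a)) ** 2
                    + (yy - c - rv * math.sin(a)) ** 2
                )
                / 8.0
            )
        v = VolumeImage(np.repeat(img[None], 3, axis=0), VOX)
        est = diameter_from_average(v)
        assert not est.symmetric
        assert est.vertical_nm == pytest.approx(2 * rv * 2, rel=0.02)
        assert est.horizontal_nm == pytest.approx(2 * rh * 2, rel=0.02)

    def test_unimodal_map_raises(self):
        data = np.zeros((3, 61, 61))
        yy, xx = np.mgrid[0:61, 0:61]
        data[:] = np.exp(-((xx - 30) ** 2 + (yy - 30) ** 2) / 50.0)
        with pytest.raises(DiameterResolutionError):
            diameter_from_average(VolumeImage(data, VOX))


class TestMonteCarlo:
    def test_zero_residual_zero_se(self):
        v = ring_image(42.5, sigma=2.0, size=131)
        est = monte_carlo_error(diameter_from_average(v), n_reps=50, seed=0)
        assert est.se_nm < 1e-6 * est.diameter_nm
        assert est.mc_distribution.size == 50

    def test_warns_for_tiny_reps(self):
        v = ring_image(42.5, sigma=2.0, size=131)
        with pytest.warns(UserWarning, match="n_reps"):
            monte_carlo_error(diameter_from_average(v), n_reps=5, seed=0)

    def test_se_calibrated_and_scales_with_noise(self):
        # empirical SD over independent noisy maps vs the bootstrap SE,
        # at two noise levels
        rng = np.random.default_rng(42)
        base = ring_image(33.75, sigma=2.0, size=111)
        # positive pedestal so additive noise is never clipped at zero
        base = VolumeImage(base.data + 20.0, VOX)
        results = {}
        for noise_sd in (0.5, 1.0):
            diams = []
            for _ in range(150):
                noisy = VolumeImage(
                    base.data + rng.normal(0, noise_sd, base.data.shape), VOX
                )
                diams.append(diameter_from_average(noisy).diameter_nm)
            emp_sd = float(np.std(diams, ddof=1))
            noisy0 = VolumeImage(
                base.data + rng.normal(0, noise_sd, base.data.shape), VOX
            )
            est = monte_carlo_error(
                diameter_from_average(noisy0), n_reps=200, seed=1
            )
            results[noise_sd] = (est.se_nm, emp_sd)
            assert est.se_nm == pytest.approx(emp_sd, rel=0.3)
        ratio = results[1.0][0] / results[0.5][0]
        assert ratio == pytest.approx(2.0, rel=0.25)


class TestNormalizeAndCompare:
    def _est(self, d, se=None):
        from torusalign.metrics import DiameterEstimate

        return DiameterEstimate(
            diameter_nm=d, vertical_nm=d, horizontal_nm=d, symmetric=True,
            asymmetry_tol=0.05, se_nm=se,
        )

    def test_identity_when_fiducial_matches_reference(self):
        out = normalize_diameters(self._est(140.0), self._est(170.0), 170.0)
        assert out.diameter_nm == pytest.approx(140.0)

    def test_stated_arithmetic(self):
        out = normalize_diameters(self._est(140.0), self._est(180.0), 170.0)
        assert out.diameter_nm == pytest.approx(140 * 170 / 180, abs=0.01)
        assert out.diameter_nm == pytest.approx(132.22, abs=0.01)

    def test_self_normalization_gives_reference(self):
        fid = self._est(181.3)
        out = normalize_diameters(fid, fid, 170.0)
        assert out.diameter_nm == pytest.approx(170.0)

    def test_error_propagation_quadrature(self):
        out = normalize_diameters(
            self._est(140.0, se=1.4), self._est(170.0, se=1.7), 170.0
        )
        rel = math.hypot(1.4 / 140, 1.7 / 170)
        assert out.se_nm == pytest.approx(out.diameter_nm * rel)

    def test_nonpositive_fiducial_rejected(self):
        with pytest.raises(ValueError):
            normalize_diameters(self._est(140.0), self._est(0.0), 170.0)

    def test_identical_distributions_p_near_one(self):
        a = np.random.default_rng(0).normal(170, 1, 100)
        t, p = compare_diameters(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_separated_distributions_reject(self):
        rng = np.random.default_rng(1)
        a = rng.normal(170, 1, 100)
        b = rng.normal(135, 1, 100)
        t, p = compare_diameters(a, b)
        assert p < 1e-10
        t2, p2 = compare_diameters(b, a)
        assert t2 == pytest.approx(-t)
        assert p2 == pytest.approx(p)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_diameters(np.ones(100), np.ones(100))
        with pytest.raises(ValueError):
            compare_diameters(np.ones(5), np.ones(100))


class TestToroidBridgeFraction:
    def _ring_with_bridge(self, ring_flux, bridge_flux):
        size = 161
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size]
        ang = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        ring = np.zeros((size, size))
        for a in ang:
            ring += np.exp(
                -(
                    (xx - c - 30 * math.cos(a)) ** 2
                    + (yy - c - 30 * math.sin(a)) ** 2
                )
                / 8.0
            )
        ring *= ring_flux / ring.sum()
        bridge = np.exp(-((xx - c - 55) ** 2 + (yy - c) ** 2) / (2 * 6.0**2))
        bridge *= bridge_flux / bridge.sum()
        return VolumeImage((ring + bridge)[None], VOX), c

    def test_all_flux_in_ring(self):
        v, c = self._ring_with_bridge(1000.0, 0.0)
        fr, fb = toroid_bridge_fraction(
            v,
            AnnulusMask(c, c, 18, 42),
            SectorMask(c, c, 43, 80, 0.0, 30.0),
        )
        assert fr == pytest.approx(1.0, abs=0.01)
        assert fb == pytest.approx(0.0, abs=0.01)

    def test_45_55_partition(self):
        v, c = self._ring_with_bridge(450.0, 550.0)
        fr, fb = toroid_bridge_fraction(
            v,
            AnnulusMask(c, c, 18, 42),
            SectorMask(c, c, 43, 80, 0.0, 30.0),
        )
        assert fr + fb == pytest.approx(1.0)
        assert fr == pytest.approx(0.45, abs=0.03)

    def test_overlapping_masks_rejected(self):
        v, c = self._ring_with_bridge(1.0, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            toroid_bridge_fraction(
                v, AnnulusMask(c, c, 10, 50), SectorMask(c, c, 45, 80, 0, 30)
            )

    def test_empty_mask_rejected(self):
        v, c = self._ring_with_bridge(1.0, 1.0)
        with pytest.raises(ValueError, match="no pixels"):
            toroid_bridge_fraction(
                v, AnnulusMask(c, c, 18, 42),
                np.zeros((161, 161), dtype=bool),
            )

    def test_mask_permutation_consistency(self):
        v, c = self._ring_with_bridge(450.0, 550.0)
        ring_m = AnnulusMask(c, c, 18, 42)
        bridge_m = SectorMask(c, c, 43, 80, 0.0, 30.0)
        fr, fb = toroid_bridge_fraction(v, ring_m, bridge_m)
        fb2, fr2 = toroid_bridge_fraction(v, bridge_m, ring_m)
        assert fr == pytest.approx(fr2) and fb == pytest.approx(fb2)
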