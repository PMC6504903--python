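"""End-to-end validation experiments on synthetic scenes.

Each function runs one self-contained experiment — simulate scenes with
known ground truth, run the corresponding pipeline stage(s), and summarise
recovery — and returns a plain dict of numbers.  They back both the
acceptance tests and ``scripts/acceptance.py``.

Problem sizes (pose-recovery over 50 scenes, 20 particles per averaging
condition, 200 Monte Carlo replicates/maps, 100 FRET spots per group) are
the package's standard validation conditions; see docs/methods.md.
"""

from __future__ import annotations

import math

import numpy as np

from .averaging import average_particles, flatten_transform
from .fitting import TiltedRingModel
from .fret import fret_efficiency, measure_bleach_pair
from .geometry import (
    PLANES,
    RingPose,
    brute_force_crossings,
    flat_circle_crossings,
    plane_crossings,
    ring_point,
)
from .io import ParticleSeed, VolumeImage
from .metrics import (
    AnnulusMask,
    SectorMask,
    compare_diameters,
    diameter_from_average,
    monte_carlo_error,
    toroid_bridge_fraction,
)
from .simulate import SceneSpec, simulate_fret_series, simulate_toroid_volume

NM_PER_PX = 2.0  # lateral scale of the standard validation scenes


def _seed_points(pose: RingPose, rng, jitter: float = 2.0) -> ParticleSeed:
    pts = ring_point(
        pose, np.array([0.0, math.pi / 2, math.pi, 3 * math.pi / 2])
    )[:, :2]
    pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    return ParticleSeed("sim", "sim", pts)


def _circ_err_deg(a_deg, b_deg):
    return abs((a_deg - b_deg + 180.0) % 360.0 - 180.0)


def crossing_solver_agreement(n_poses: int = 500, seed: int = 0,
                              n_grid: int = 1 << 16) -> dict:
    """Analytic plane-crossing solver vs the brute-force oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_poses):
        pose = RingPose(
            rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(-3, 3),
            rng.uniform(30, 60), rng.uniform(0, math.radians(44)),
            rng.uniform(0, 2 * math.pi),
        )
        for plane in PLANES:
            a = plane_crossings(pose, plane, (0, 0, 0))
            b = brute_force_crossings(pose, plane, (0, 0, 0), n_grid=n_grid)
            if a.ok and b.ok:
                d = np.abs(
                    (a.rhos - b.rhos + math.pi) % (2 * math.pi) - math.pi
                )
                worst = max(worst, float(d.max()))
    return {"max_rho_discrepancy_rad": worst, "n_poses": n_poses}


def flat_limit_agreement(n_phi: int = 24, seed: int = 0) -> dict:
    """Crossings of flat rings vs the closed-form chord solution."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(20):
        pose0 = dict(
            xc=rng.uniform(-6, 6), yc=rng.uniform(-6, 6),
            zc=rng.uniform(-3, 3), r=rng.uniform(25, 60),
        )
        for phi in np.linspace(0, 2 * math.pi, n_phi, endpoint=False):
            pose = RingPose(theta=0.0, phi=float(phi), **pose0)
            for plane in PLANES:
                a = plane_crossings(pose, plane, (0, 0, 0))
                f = flat_circle_crossings(pose, plane, (0, 0, 0))
                if a.ok:
                    worst = max(
                        worst, float(np.abs(a.points - f.points).max())
                    )
    return {"max_point_error_px": worst}


def parameter_recovery(n_scenes: int = 50, seed: int = 0) -> dict:
    """Fit 50 simulated toroids (r 30-60 px, tilt 0-40 deg, SNR >= 10)."""
    rng = np.random.default_rng(seed)
    r_err, th_err, phi_ok, phi_all = [], [], [], []
    for k in range(n_scenes):
        r_px = rng.uniform(30, 60)
        theta = rng.uniform(0, 40)
        phi = rng.uniform(0, 360)
        spec = SceneSpec(
            diameter_nm=2 * r_px * NM_PER_PX, theta_deg=theta, phi_deg=phi,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, truth = simulate_toroid_volume(spec)
        res = TiltedRingModel.from_volume(
            vol, _seed_points(truth.pose, rng)
        ).fit()
        r_err.append(abs(res.pose.r - truth.pose.r) / truth.pose.r * 100)
        th_err.append(
            abs(math.degrees(res.pose.theta) - theta)
        )
        dphi = _circ_err_deg(math.degrees(res.pose.phi), phi)
        phi_all.append(dphi)
        if theta > 10.0:
            phi_ok.append(dphi <= 10.0 + 1e-6)
    return {
        "median_radius_error_pct": float(np.median(r_err)),
        "median_tilt_error_deg": float(np.median(th_err)),
        "phi_within_grid_step_frac": float(np.mean(phi_ok)) if phi_ok else 1.0,
        "n_scenes": n_scenes,
    }


def end_to_end_metrology(
    diameters_nm=(90.0, 135.0, 170.0),
    n_particles: int = 20,
    seed: int = 0,
    mc_reps: int = 200,
) -> dict:
    """simulate -> fit -> flatten -> average -> diameter for each condition,
    plus the Monte Carlo t-test between the 135 and 170 nm conditions."""
    rng = np.random.default_rng(seed)
    out = {}
    mc = {}
    for D in diameters_nm:
        r_px = D / 2 / NM_PER_PX
        L = int(round(2.5 * 2 * r_px)) | 1
        canvas = (41, L, L)
        parts = []
        for _ in range(n_particles):
            spec = SceneSpec(
                diameter_nm=D,
                theta_deg=rng.uniform(5, 35),
                phi_deg=rng.uniform(0, 360),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, truth = simulate_toroid_volume(spec)
            res = TiltedRingModel.from_volume(
                vol, _seed_points(truth.pose, rng)
            ).fit()
            parts.append(
                flatten_transform(vol, res.pose, canvas_shape=canvas)
            )
        avg = average_particles(parts)
        est = monte_carlo_error(
            diameter_from_average(avg), n_reps=mc_reps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mc[D] = est.mc_distribution
        out[D] = {
            "recovered_nm": est.diameter_nm,
            "error_pct": abs(est.diameter_nm - D) / D * 100,
            "mc_se_nm": est.se_nm,
        }
    if 135.0 in mc and 170.0 in mc:
        _, p = compare_diameters(mc[135.0], mc[170.0])
        out["p_135_vs_170"] = p
    return out


def _ring_map(radius_px: float, sigma: float = 2.0, size: int = 111,
              amp: float = 100.0, pedestal: float = 20.0) -> np.ndarray:
    """Analytic flat averaged-ring image (for noise-calibration runs)."""
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
    return img * (amp / img.max()) + pedestal


def monte_carlo_calibration(
    n_maps: int = 200, seed: int = 0, noise_sds=(0.5, 1.0), mc_reps: int = 200
) -> dict:
    """Bootstrap SE vs the empirical SD of diameters over independently
    noised averaged maps, at two injected noise levels."""
    rng = np.random.default_rng(seed)
    base = _ring_map(33.75)
    vox = (6.0, NM_PER_PX, NM_PER_PX)
    out = {}
    ses = {}
    for noise_sd in noise_sds:
        diams = []
        for _ in range(n_maps):
            noisy = VolumeImage(
                np.clip(base + rng.normal(0, noise_sd, base.shape), 0, None)[
                    None
                ],
                vox,
            )
            diams.append(diameter_from_average(noisy).diameter_nm)
        emp_sd = float(np.std(diams, ddof=1))
        one = VolumeImage(
            np.clip(base + rng.normal(0, noise_sd, base.shape), 0, None)[None],
            vox,
        )
        est = monte_carlo_error(
            diameter_from_average(one), n_reps=mc_reps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ses[noise_sd] = est.se_nm
        out[noise_sd] = {
            "mc_se_nm": est.se_nm,
            "empirical_sd_nm": emp_sd,
            "ratio": est.se_nm / emp_sd,
        }
    lo, hi = min(noise_sds), max(noise_sds)
    out["se_scaling_vs_noise"] = ses[hi] / ses[lo] / (hi / lo)
    return out


def bridge_partition_recovery(n_scenes: int = 20, seed: int = 0) -> dict:
    """Recover the 45/55 ring/bridge flux split from Mps3-like scenes."""
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_scenes):
        spec = SceneSpec(
            diameter_nm=160.0, theta_deg=10.0, phi_deg=0.0,
            bridge_fraction=0.55,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, truth = simulate_toroid_volume(spec)
        r = truth.pose.r
        cx, cy = truth.pose.xc, truth.pose.yc
        ring_m = AnnulusMask(cx, cy, 0.0, 1.25 * r)
        off = spec.bridge_offset_nm / NM_PER_PX
        bridge_m = SectorMask(cx, cy, 1.25 * r + 0.5, off + 4 * r,
                              direction_deg=0.0, half_angle_deg=35.0)
        fr, fb = toroid_bridge_fraction(vol, ring_m, bridge_m)
        fracs.append(fr)
    fracs = np.asarray(fracs)
    return {
        "true_ring_fraction": 0.45,
        "mean_recovered_ring_fraction": float(fracs.mean()),
        "max_abs_error": float(np.abs(fracs - 0.45).max()),
        "n_scenes": n_scenes,
    }


def fret_recovery(seed: int = 0, n_spots: int = 100,
                  true_e: float = 0.40, bleach: float = 0.05) -> dict:
    """Close the loop: simulated bleach series -> measured efficiencies."""
    pre, post, truth = simulate_fret_series(
        true_e, n_spots, donor_only_bleach=bleach, seed=seed
    )
    cpre, cpost, _ = simulate_fret_series(
        0.0, n_spots, donor_only_bleach=bleach, seed=seed + 1
    )
    res = fret_efficiency(
        measure_bleach_pair(pre, post), measure_bleach_pair(cpre, cpost)
    )
    # donor-only vs donor-only: relative efficiency should sit at zero
    dpre, dpost, _ = simulate_fret_series(
        0.0, n_spots, donor_only_bleach=bleach, seed=seed + 2
    )
    res0 = fret_efficiency(
        measure_bleach_pair(dpre, dpost), measure_bleach_pair(cpre, cpost)
    )
    return {
        "true_efficiency": true_e,
        "corrected_efficiency": res.corrected_efficiency,
        "relative_efficiency": res.relative_efficiency,
        "p_value_vs_control": res.p_value,
        "donor_only_relative": res0.relative_efficiency,
        "donor_only_corrected": res0.corrected_efficiency,
        "n_pair": res.n_pair,
        "n_control": res.n_control,
    }


def conservation_and_determinism(n_scenes: int = 10, seed: int = 0) -> dict:
    """Intensity conservation of the flattening resample and bit-level
    reproducibility of the seeded generators."""
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_scenes):
        spec = SceneSpec(
            diameter_nm=rng.uniform(120, 200),
            theta_deg=rng.uniform(0, 38),
            phi_deg=rng.uniform(0, 360),
            seed=int(rng.integers(0, 2**31 - 1)),
            poisson=False, read_noise_sd=0.0,
        )
        vol, truth = simulate_toroid_volume(spec)
        ap = flatten_transform(vol, truth.pose)
        ratios.append(float(ap.volume.data.sum() / vol.data.sum()))
    s = int(rng.integers(0, 2**31 - 1))
    a, _ = simulate_toroid_volume(SceneSpec(seed=s))
    b, _ = simulate_toroid_volume(SceneSpec(seed=s))
    ratios = np.asarray(ratios)
    return {
        "worst_conservation_deviation": float(np.abs(ratios - 1.0).max()),
        "scenes_bit_reproducible": bool(np.array_equal(a.data, b.data)),
        "n_scenes": n_scenes,
    }
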