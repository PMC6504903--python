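"""Constrained global fit of a tilted ring to four angled cross sections.

The measurement model: a ring pierces each of four vertical cross-sectional
planes (strips at 0/45/90/135 degrees through a guessed center) at two
points, and each piercing appears as an asymmetric 2D Gaussian spot whose
lateral width reflects the lateral resolution and whose vertical width the
axial resolution.  The eight spot centers are *not* free parameters: they are
the analytic plane crossings of the current pose, so the fit couples all
eight spots through (xc, yc, zc, r, theta, phi).

Fitting strategy (``TiltedRingModel.fit``):

* the azimuth phi is poorly behaved as a free parameter near theta=0, so it
  is gridded (10-degree steps by default) and a bounded least-squares fit is
  run at each grid value;
* per grid value the fit uses variable projection: amplitudes and per-section
  baselines are solved exactly by linear least squares inside the residual,
  leaving 7 nonlinear parameters (center, radius, tilt, two linked sigmas);
* the best grid value gets a final fully parameterised bounded fit in which
  the two amplitudes of each section are expressed as pair-mean x ratio with
  the ratio bounded to [1/2, 2].

Constraints (all recorded as flags when active at the solution): center
within 20% of the guess radius of its initialisation, radius within 2x of its
initialisation, z center within one slice, tilt below 45 degrees, linked
sigmas across all eight spots, amplitude pairs within 2x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .geometry import PLANE_ANGLES, RingPose, plane_crossings
from .io import ParticleSeed, VolumeImage

SECTION_KEYS = ("yz", "45", "xz", "135")  # strips at 0, 45, 90, 135 degrees


class RingFitError(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Tunable fit settings; defaults follow docs/methods.md."""

    phi_step_deg: float = 10.0
    center_bound_frac: float = 0.2  # of guess radius, per axis
    radius_bound_factor: float = 2.0
    z_bound_slices: float = 1.0
    theta_max_deg: float = 45.0
    sigma_init: tuple = (2.0, 4.0)  # (lateral px, z slices)
    sigma_bounds: tuple = (0.5, 30.0)
    amp_ratio_bounds: tuple = (0.5, 2.0)
    half_length_factor: float = 1.5  # strip half-length in units of r0
    coarse_max_nfev: int = 250
    final_max_nfev: int = 800
    xtol: float = 1e-10
    phi_flat_tol: float = 0.01  # relative cost spread below which phi is undetermined
    quality_threshold: float = 0.3  # residual rms / peak amplitude


@dataclass
class CrossSectionSet:
    """Four 2-pixel-wide averaged cross sections through a guess center.

    ``images[key]`` has shape (nz, n_lateral); rows are z slices, columns the
    lateral coordinate ``t_coords`` (lateral px, relative to the guess, along
    the strip direction).  Extraction is linear in the source volume.
    """

    images: dict
    t_coords: np.ndarray
    center_guess: np.ndarray  # (x, y) px
    aspect: float  # dz/dx of the source volume
    nz: int
    voxel_size: tuple

    @property
    def z_coords(self) -> np.ndarray:
        return np.arange(self.nz, dtype=float)


def extract_cross_sections(
    volume: VolumeImage, center_guess, half_length: float
) -> CrossSectionSet:
    """Extract the 0/45/90/135-degree strips, each averaged over a 2-pixel
    width, with bilinear interpolation.  ``half_length`` is in lateral px."""
    gx, gy = float(center_guess[0]), float(center_guess[1])
    nz, ny, nx = volume.shape
    h = int(math.floor(half_length))
    t = np.arange(-h, h + 1, dtype=float)
    # worst-case reach of any strip sample from the guess
    reach = h + 0.5
    if (
        gx - reach < -0.5 or gx + reach > nx - 0.5
        or gy - reach < -0.5 or gy + reach > ny - 0.5
    ):
        raise ValueError(
            f"cross-sectional strips of half-length {h} px exit the volume "
            f"({nx}x{ny} laterally, guess at ({gx:.1f}, {gy:.1f})); use a "
            "larger crop around the particle"
        )
    images = {}
    zz = np.arange(nz, dtype=float)
    for key in SECTION_KEYS:
        alpha = math.radians(PLANE_ANGLES[key])
        ux, uy = math.cos(alpha), math.sin(alpha)
        nxv, nyv = -math.sin(alpha), math.cos(alpha)
        acc = np.zeros((nz, t.size))
        for off in (-0.5, +0.5):
            xs = gx + t * ux + off * nxv
            ys = gy + t * uy + off * nyv
            cz = np.repeat(zz, t.size)
            cy = np.tile(ys, nz)
            cx = np.tile(xs, nz)
            acc += map_coordinates(
                volume.data, np.array([cz, cy, cx]), order=1, mode="nearest"
            ).reshape(nz, t.size)
        images[key] = acc / 2.0
    return CrossSectionSet(
        images=images,
        t_coords=t,
        center_guess=np.array([gx, gy]),
        aspect=volume.aspect,
        nz=nz,
        voxel_size=volume.voxel_size,
    )


def initialize_pose(seed: ParticleSeed, volume: VolumeImage) -> RingPose:
    """Initial pose from the four clicked crossing points.

    Radius: half the mean of the two opposite-point distances.  Lateral
    center: centroid of the four points.  z center: the maximum-intensity
    slice of the averaged z profiles sampled at the four points.  Tilt
    starts flat (theta = 0).
    """
    seed.validate_bounds(volume)
    pts = seed.points
    d1 = float(np.linalg.norm(pts[0] - pts[2]))
    d2 = float(np.linalg.norm(pts[1] - pts[3]))
    r0 = (d1 + d2) / 4.0
    if min(d1, d2) < 2.0 or r0 <= 1.0:
        raise ValueError(
            f"seed {seed.particle_id}: degenerate (coincident) crossing points"
        )
    x = pts[:, 0]
    y = pts[:, 1]
    area = 0.5 * abs(
        np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    )
    if area < 0.1 * r0 * r0:
        raise ValueError(
            f"seed {seed.particle_id}: degenerate (collinear) crossing points"
        )
    cx, cy = pts.mean(axis=0)
    nz = volume.shape[0]
    zz = np.arange(nz, dtype=float)
    prof = np.zeros(nz)
    for px, py in pts:
        coords = np.array([zz, np.full(nz, py), np.full(nz, px)])
        prof += map_coordinates(volume.data, coords, order=1, mode="nearest")
    prof /= 4.0
    if seed.z_hint is not None:
        lo = max(0, seed.z_hint - 5)
        hi = min(nz, seed.z_hint + 6)
        z0 = lo + int(np.argmax(prof[lo:hi]))
    else:
        z0 = int(np.argmax(prof))
    return RingPose(float(cx), float(cy), z0 * volume.aspect, r0, 0.0, 0.0)


@dataclass
class AsymGauss2D:
    """One cross-sectional spot: an asymmetric 2D Gaussian."""

    section: str
    center_lateral: float  # lateral px along the strip, relative to the guess
    center_z: float  # slice index
    sigma_lateral: float
    sigma_z: float
    amplitude: float
    baseline: float


@dataclass
class RingFitResults:
    """Results of the constrained global ring fit.

    Carries the fitted pose, the eight spot Gaussians, the phi-grid cost
    profile, active-constraint flags and observed/model cross sections.
    """

    pose: RingPose
    init_pose: RingPose
    gaussians: list
    sigma_lateral: float
    sigma_z: float
    amplitudes: np.ndarray  # (4, 2)
    baselines: np.ndarray  # (4,)
    residual_rms: float
    cost: float
    phi_grid_profile: dict  # phi degrees -> cost (sum of squared residuals)
    constraint_flags: set
    observed: dict  # section key -> image
    model: dict  # section key -> image
    aspect: float
    voxel_size: tuple
    nfev: int = 0

    @property
    def quality_images(self) -> dict:
        return {k: (self.observed[k], self.model[k]) for k in self.observed}

    def pose_nm(self) -> dict:
        """Pose converted to nm using the source voxel size."""
        dx = self.voxel_size[2]
        return {
            "xc_nm": self.pose.xc * dx,
            "yc_nm": self.pose.yc * dx,
            "zc_nm": self.pose.zc * dx,
            "r_nm": self.pose.r * dx,
            "diameter_nm": 2 * self.pose.r * dx,
            "theta_deg": math.degrees(self.pose.theta),
            "phi_deg": math.degrees(self.pose.phi),
        }

    def summary(self) -> str:
        p = self.pose
        lines = [
            "Tilted-ring fit results",
            "=" * 54,
            f"{'center (x, y) [px]':30s} ({p.xc:8.2f}, {p.yc:8.2f})",
            f"{'center z [slice]':30s} {p.zc / self.aspect:8.2f}",
            f"{'radius [px]':30s} {p.r:8.2f}",
            f"{'diameter [nm]':30s} {2 * p.r * self.voxel_size[2]:8.1f}",
            f"{'tilt theta [deg]':30s} {math.degrees(p.theta):8.2f}",
            f"{'rotation phi [deg]':30s} {math.degrees(p.phi):8.1f}",
            f"{'sigma lateral [px]':30s} {self.sigma_lateral:8.2f}",
            f"{'sigma z [slices]':30s} {self.sigma_z:8.2f}",
            f"{'residual rms':30s} {self.residual_rms:8.4g}",
            f"{'active constraints':30s} "
            + (", ".join(sorted(self.constraint_flags)) or "none"),
            "-" * 54,
            f"{'section':8s}{'t1':>8s}{'t2':>8s}{'amp1':>10s}{'amp2':>10s}"
            f"{'base':>10s}",
        ]
        for i, key in enumerate(SECTION_KEYS):
            g1, g2 = self.gaussians[2 * i], self.gaussians[2 * i + 1]
            lines.append(
                f"{key:8s}{g1.center_lateral:8.2f}{g2.center_lateral:8.2f}"
                f"{g1.amplitude:10.3g}{g2.amplitude:10.3g}"
                f"{self.baselines[i]:10.3g}"
            )
        return "\n".join(lines)

    def plot_cross_sections(self, path=None):
        """Observed vs model cross sections (matplotlib figure)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 4, figsize=(12, 5))
        for j, key in enumerate(SECTION_KEYS):
            for i, (img, label) in enumerate(
                [(self.observed[key], "observed"), (self.model[key], "model")]
            ):
                ax = axes[i, j]
                ax.imshow(img, origin="lower", aspect="auto", cmap="magma")
                ax.set_title(f"{key} {label}", fontsize=8)
                ax.set_xticks([])
                ax.set_yticks([])
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class TiltedRingModel:
    """Model object binding cross-sectional data to the tilted-ring fit.

    Parameters
    ----------
    cross_sections : CrossSectionSet
    init : RingPose
        From :func:`initialize_pose`; its center anchors the crossing planes.
    config : FitConfig, optional
    """

    def __init__(self, cross_sections, init, config=None):
        self.cs = cross_sections
        self.init = init
        self.config = config or FitConfig()
        if init.r <= 0:
            raise RingFitError("initial pose has non-positive radius")
        # spots predicted at the init pose must exist on all four planes
        n = 0
        for key in SECTION_KEYS:
            c = plane_crossings(init, key, self._guess3())
            n += c.rhos.size
        if n < 8:
            raise RingFitError(
                f"only {n} real plane crossings at the initial pose; "
                "the ring must cross all four section planes"
            )

    @classmethod
    def from_volume(cls, volume, seed, config=None):
        config = config or FitConfig()
        init = initialize_pose(seed, volume)
        cs = extract_cross_sections(
            volume, (init.xc, init.yc), config.half_length_factor * init.r
        )
        return cls(cs, init, config)

    # -- internals ---------------------------------------------------------

    def _guess3(self):
        return np.array(
            [self.cs.center_guess[0], self.cs.center_guess[1], self.init.zc]
        )

    def _spot_centers(self, xc, yc, zc, r, theta, phi):
        """(t, z_slice) of both spots per section; None if any crossing
        vanishes (cannot occur inside the constraint box).

        Inlined, vectorised equivalent of :func:`geometry.plane_crossings`
        over all four planes (agreement asserted in the test suite); the
        hot path of the fit.
        """
        gx, gy = self.cs.center_guess
        st, ct = math.sin(theta), math.cos(theta)
        sp, cp = math.sin(phi), math.cos(phi)
        dx, dy = xc - gx, yc - gy
        # harmonic coefficients A sin(rho) + B cos(rho) + C = 0, in the
        # SECTION_KEYS order (yz, 45, xz, 135)
        A = np.array([r * ct * sp, r * ct * (cp - sp),
                      r * ct * cp, r * ct * (cp + sp)])
        B = np.array([r * cp, -r * (sp + cp), -r * sp, r * (cp - sp)])
        C = np.array([dy, dx - dy, dx, dx + dy])
        R = np.hypot(A, B)
        s = -C / R
        if np.any(np.abs(s) > 1.0):
            return None
        delta = np.arctan2(B, A)
        base = np.arcsin(s)
        rhos = np.stack([base - delta, math.pi - base - delta])  # (2, 4)
        srho, crho = np.sin(rhos), np.cos(rhos)
        px = xc - r * crho * sp + r * srho * ct * cp
        py = yc + r * crho * cp + r * srho * ct * sp
        pz = zc - r * srho * st
        # lateral coordinate along each strip direction
        ang = np.radians([0.0, 45.0, 90.0, 135.0])
        t = (px - gx) * np.cos(ang)[None, :] + (py - gy) * np.sin(ang)[None, :]
        zsl = pz / self.cs.aspect
        swap = t[0] < t[1]  # positive-half crossing first
        t0 = np.where(swap, t[1], t[0])
        t1 = np.where(swap, t[0], t[1])
        z0 = np.where(swap, zsl[1], zsl[0])
        z1 = np.where(swap, zsl[0], zsl[1])
        order = {"yz": 0, "45": 1, "xz": 2, "135": 3}
        return {
            key: (np.array([t0[i], t1[i]]), np.array([z0[i], z1[i]]))
            for key, i in order.items()
        }

    def _section_stats(self):
        if not hasattr(self, "_stats"):
            stats = {}
            for key in SECTION_KEYS:
                img = self.cs.images[key]
                stats[key] = (
                    img, float(img.size), float(img.sum()),
                    float(np.sum(img * img)),
                )
            self._stats = stats
        return self._stats

    def _varpro_cost(self, p, phi):
        """Sum-of-squares cost with amplitudes/baselines projected out.

        Identical to ``sum(_varpro_residual(p, phi)**2)`` but computed from
        separable inner products only (no model images) and batched over all
        eight spots, which makes the phi-grid search cheap.
        """
        xc, yc, zc, r, theta, sl, sz = p
        centers = self._spot_centers(xc, yc, zc, r, theta, phi)
        stats = self._section_stats()
        if centers is None:
            return float(
                sum(st[3] - st[2] ** 2 / st[1] for st in stats.values())
            )
        t = self.cs.t_coords
        z = self.cs.z_coords
        # spots 2i, 2i+1 belong to section i (SECTION_KEYS order)
        t0 = np.concatenate([centers[k][0] for k in SECTION_KEYS])
        z0 = np.concatenate([centers[k][1] for k in SECTION_KEYS])
        GL = np.exp(-((t[None, :] - t0[:, None]) ** 2) / (2 * sl * sl))
        GZ = np.exp(-((z[None, :] - z0[:, None]) ** 2) / (2 * sz * sz))
        if not hasattr(self, "_img_stack"):
            self._img_stack = np.stack(
                [self.cs.images[k] for k in SECTION_KEYS]
            )
        IMG = self._img_stack
        # per-spot projections r_s = gz_s @ IMG[sec(s)] @ gl_s
        sec = np.repeat(np.arange(4), 2)
        proj = np.einsum("sjk,sk->sj", IMG[sec], GL, optimize=True)
        r_s = np.einsum("sj,sj->s", proj, GZ)
        gl_dot = GL @ GL.T  # (8, 8) lateral inner products
        gz_dot = GZ @ GZ.T
        gl_sum = GL.sum(axis=1)
        gz_sum = GZ.sum(axis=1)
        cost = 0.0
        for i, key in enumerate(SECTION_KEYS):
            _, npx, img_sum, img_ss = stats[key]
            a_, b_ = 2 * i, 2 * i + 1
            s11 = gz_dot[a_, a_] * gl_dot[a_, a_]
            s22 = gz_dot[b_, b_] * gl_dot[b_, b_]
            s12 = gz_dot[a_, b_] * gl_dot[a_, b_]
            s1o = gz_sum[a_] * gl_sum[a_]
            s2o = gz_sum[b_] * gl_sum[b_]
            M = np.array(
                [[s11 + 1e-9, s12, s1o],
                 [s12, s22 + 1e-9, s2o],
                 [s1o, s2o, npx + 1e-9]]
            )
            rhs = np.array([r_s[a_], r_s[b_], img_sum])
            try:
                a = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:  # pragma: no cover
                a = np.array([0.0, 0.0, img_sum / npx])
            cost += img_ss - float(a @ rhs)
        return cost

    def _varpro_residual(self, p, phi, collect=None):
        xc, yc, zc, r, theta, sl, sz = p
        centers = self._spot_centers(xc, yc, zc, r, theta, phi)
        t = self.cs.t_coords
        z = self.cs.z_coords
        res = []
        for key in SECTION_KEYS:
            img, npx, img_sum, _ = self._section_stats()[key]
            if centers is None:
                # out-of-model pose: baseline-only fallback keeps the
                # optimizer moving back into the feasible region
                res.append((img - img.mean()).ravel())
                continue
            (t0, z0) = centers[key]
            gl1 = np.exp(-((t - t0[0]) ** 2) / (2 * sl * sl))
            gl2 = np.exp(-((t - t0[1]) ** 2) / (2 * sl * sl))
            gz1 = np.exp(-((z - z0[0]) ** 2) / (2 * sz * sz))
            gz2 = np.exp(-((z - z0[1]) ** 2) / (2 * sz * sz))
            # separable inner products for the 3x3 normal equations
            s11 = (gz1 @ gz1) * (gl1 @ gl1)
            s22 = (gz2 @ gz2) * (gl2 @ gl2)
            s12 = (gz1 @ gz2) * (gl1 @ gl2)
            s1o = gz1.sum() * gl1.sum()
            s2o = gz2.sum() * gl2.sum()
            r1 = gz1 @ img @ gl1
            r2 = gz2 @ img @ gl2
            M = np.array(
                [[s11, s12, s1o], [s12, s22, s2o], [s1o, s2o, npx]]
            )
            rhs = np.array([r1, r2, img_sum])
            try:
                a1, a2, b = np.linalg.solve(M + 1e-9 * np.eye(3), rhs)
            except np.linalg.LinAlgError:  # pragma: no cover
                a1 = a2 = 0.0
                b = img.mean()
            model = b + a1 * np.outer(gz1, gl1) + a2 * np.outer(gz2, gl2)
            if collect is not None:
                collect[key] = (np.array([a1, a2]), b, model)
            res.append((model - img).ravel())
        return np.concatenate(res)

    def _full_residual(self, p, phi, collect=None):
        xc, yc, zc, r, theta, sl, sz = p[:7]
        m = p[7:11]
        q = p[11:15]
        b = p[15:19]
        centers = self._spot_centers(xc, yc, zc, r, theta, phi)
        t = self.cs.t_coords
        z = self.cs.z_coords
        res = []
        for i, key in enumerate(SECTION_KEYS):
            img = self._section_stats()[key][0]
            if centers is None:
                res.append((img - img.mean()).ravel())
                continue
            (t0, z0) = centers[key]
            sq = math.sqrt(q[i])
            a1, a2 = m[i] * sq, m[i] / sq
            g1 = np.outer(
                np.exp(-((z - z0[0]) ** 2) / (2 * sz * sz)),
                np.exp(-((t - t0[0]) ** 2) / (2 * sl * sl)),
            )
            g2 = np.outer(
                np.exp(-((z - z0[1]) ** 2) / (2 * sz * sz)),
                np.exp(-((t - t0[1]) ** 2) / (2 * sl * sl)),
            )
            model = b[i] + a1 * g1 + a2 * g2
            if collect is not None:
                collect[key] = (np.array([a1, a2]), b[i], model)
            res.append((model - img).ravel())
        return np.concatenate(res)

    def _bounds7(self):
        cfg = self.config
        r0 = self.init.r
        cb = cfg.center_bound_frac * r0
        zb = cfg.z_bound_slices * self.cs.aspect
        lo = [
            self.init.xc - cb, self.init.yc - cb, self.init.zc - zb,
            r0 / cfg.radius_bound_factor, 0.0,
            cfg.sigma_bounds[0], cfg.sigma_bounds[0],
        ]
        hi = [
            self.init.xc + cb, self.init.yc + cb, self.init.zc + zb,
            r0 * cfg.radius_bound_factor,
            math.radians(cfg.theta_max_deg) - 1e-9,
            cfg.sigma_bounds[1], cfg.sigma_bounds[1],
        ]
        return np.array(lo), np.array(hi)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> RingFitResults:
        cfg = self.config
        lo, hi = self._bounds7()
        x0 = np.array(
            [
                self.init.xc, self.init.yc, self.init.zc, self.init.r,
                math.radians(2.0),  # start just off the flat boundary
                cfg.sigma_init[0], cfg.sigma_init[1],
            ]
        )
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        # coarse radius scan: a badly initialised radius leaves the spot
        # model with no overlap (zero gradient), so start in the best basin
        r_grid = np.linspace(lo[3], hi[3], 25)
        r_costs = []
        for rv in r_grid:
            xr = x0.copy()
            xr[3] = rv
            r_costs.append(self._varpro_cost(xr, 0.0))
        x0[3] = r_grid[int(np.argmin(r_costs))]
        phis = np.radians(np.arange(0.0, 360.0, cfg.phi_step_deg))
        profile = {}
        best = None
        nfev = 0
        from scipy.optimize import minimize

        bnds = list(zip(lo, hi))
        x_warm = x0
        for phi in phis:
            try:
                solc = minimize(
                    self._varpro_cost, x_warm, args=(phi,), method="L-BFGS-B",
                    bounds=bnds,
                    options={"maxiter": cfg.coarse_max_nfev, "ftol": 1e-11},
                )
                x_warm = solc.x  # neighbouring phi values share a basin
                cost = float(solc.fun)
                xbest = solc.x
            except Exception:  # pragma: no cover
                profile[round(math.degrees(phi), 3)] = float("inf")
                continue
            nfev += solc.nfev
            profile[round(math.degrees(phi), 3)] = cost
            if best is None or cost < best[0]:
                best = (cost, phi, xbest)
        if best is None or not np.isfinite(best[0]):
            raise RingFitError(
                f"no phi grid value produced a converged fit; costs: {profile}"
            )
        _, phi_best, x_best = best

        # precise variable-projection polish at the winning phi
        sol = least_squares(
            self._varpro_residual, x_best, args=(phi_best,),
            bounds=(lo, hi), method="trf",
            max_nfev=cfg.coarse_max_nfev, xtol=cfg.xtol, ftol=1e-12,
            gtol=1e-14, x_scale=[1, 1, 1, 1, 0.05, 0.5, 0.5],
        )
        nfev += sol.nfev
        profile[round(math.degrees(phi_best), 3)] = min(
            best[0], 2.0 * sol.cost
        )

        # final fully parameterised constrained fit at the winning phi
        collect = {}
        self._varpro_residual(sol.x, phi_best, collect=collect)
        m0, q0, b0 = [], [], []
        for key in SECTION_KEYS:
            (a, bline, _) = collect[key]
            a1, a2 = max(a[0], 1e-12), max(a[1], 1e-12)
            ratio = min(max(a1 / a2, cfg.amp_ratio_bounds[0] + 1e-9),
                        cfg.amp_ratio_bounds[1] - 1e-9)
            m0.append(math.sqrt(a1 * a2))
            q0.append(ratio)
            b0.append(bline)
        x0f = np.concatenate([sol.x, m0, q0, b0])
        lof = np.concatenate(
            [lo, np.zeros(4), np.full(4, cfg.amp_ratio_bounds[0]),
             np.full(4, -np.inf)]
        )
        hif = np.concatenate(
            [hi, np.full(4, np.inf), np.full(4, cfg.amp_ratio_bounds[1]),
             np.full(4, np.inf)]
        )
        x0f = np.clip(x0f, lof + 1e-12, np.where(np.isfinite(hif), hif - 1e-12, x0f))
        amp_scale = max(float(np.mean(m0)), 1e-6)
        solf = least_squares(
            self._full_residual, x0f, args=(phi_best,),
            bounds=(lof, hif), method="trf", max_nfev=cfg.final_max_nfev,
            xtol=cfg.xtol, ftol=1e-10, gtol=1e-12,
            x_scale=[1, 1, 1, 1, 0.05, 0.5, 0.5] + [amp_scale] * 4
            + [0.2] * 4 + [amp_scale * 0.1] * 4,
        )
        nfev += solf.nfev
        collect = {}
        res = self._full_residual(solf.x, phi_best, collect=collect)
        cost = float(res @ res)
        rms = math.sqrt(cost / res.size)

        xc, yc, zc, r, theta, sl, sz = solf.x[:7]
        pose = RingPose(xc, yc, zc, r, theta, phi_best)
        flags = self._constraint_flags(solf.x, lo, hi)
        costs = np.array([v for v in profile.values() if np.isfinite(v)])
        if costs.size and (costs.max() - costs.min()) < (
            self.config.phi_flat_tol * max(costs.mean(), 1e-300)
        ):
            flags.add("phi_undetermined")

        centers = self._spot_centers(xc, yc, zc, r, theta, phi_best)
        gaussians = []
        amps = np.zeros((4, 2))
        bases = np.zeros(4)
        for i, key in enumerate(SECTION_KEYS):
            (a, bline, _) = collect[key]
            amps[i] = a
            bases[i] = bline
            t0, z0 = centers[key]
            for jj in range(2):
                gaussians.append(
                    AsymGauss2D(
                        section=key,
                        center_lateral=float(t0[jj]),
                        center_z=float(z0[jj]),
                        sigma_lateral=float(sl),
                        sigma_z=float(sz),
                        amplitude=float(a[jj]),
                        baseline=float(bline),
                    )
                )
        return RingFitResults(
            pose=pose,
            init_pose=self.init,
            gaussians=gaussians,
            sigma_lateral=float(sl),
            sigma_z=float(sz),
            amplitudes=amps,
            baselines=bases,
            residual_rms=rms,
            cost=cost,
            phi_grid_profile=profile,
            constraint_flags=flags,
            observed={k: self.cs.images[k] for k in SECTION_KEYS},
            model={k: collect[k][2] for k in SECTION_KEYS},
            aspect=self.cs.aspect,
            voxel_size=self.cs.voxel_size,
            nfev=nfev,
        )

    def _constraint_flags(self, x, lo, hi) -> set:
        cfg = self.config
        flags = set()
        eps = 1e-6

        def at_bound(v, lo_v, hi_v, scale):
            return (v - lo_v) < eps * scale or (hi_v - v) < eps * scale

        r0 = self.init.r
        if at_bound(x[0], lo[0], hi[0], r0) or at_bound(x[1], lo[1], hi[1], r0):
            flags.add("center_bound")
        if at_bound(x[2], lo[2], hi[2], self.cs.aspect):
            flags.add("z_bound")
        if at_bound(x[3], lo[3], hi[3], r0):
            flags.add("radius_bound")
        if (hi[4] - x[4]) < 1e-4:
            flags.add("theta_bound")
        for qv in x[11:15]:
            if at_bound(qv, cfg.amp_ratio_bounds[0], cfg.amp_ratio_bounds[1], 1.0):
                flags.add("amp_ratio_bound")
        return flags


def fit_ring(cs: CrossSectionSet, init: RingPose, config=None) -> RingFitResults:
    """Functional wrapper: constrained global fit of the eight spots."""
    return TiltedRingModel(cs, init, config).fit()


def fit_particle(volume: VolumeImage, seed: ParticleSeed, config=None) -> RingFitResults:
    """Initialise from a seed, extract cross sections and fit."""
    return TiltedRingModel.from_volume(volume, seed, config).fit()


@dataclass
class QualityReport:
    """Machine surrogate for visual inspection of a fit."""

    residual_rms: float
    peak_amplitude: float
    relative_residual: float
    threshold: float
    passed: bool
    n_spots: int
    images: dict  # section -> (observed, simulated)


def fit_quality(result: RingFitResults, threshold: float | None = None) -> QualityReport:
    """Observed-vs-model comparison with a pass/fail residual criterion.

    The fit passes when the residual rms is below ``threshold`` times the
    peak fitted spot amplitude.
    """
    thr = threshold if threshold is not None else FitConfig().quality_threshold
    peak = float(np.max(result.amplitudes)) if result.amplitudes.size else 0.0
    rel = result.residual_rms / peak if peak > 0 else math.inf
    return QualityReport(
        residual_rms=result.residual_rms,
        peak_amplitude=peak,
        relative_residual=rel,
        threshold=thr,
        passed=bool(rel < thr),
        n_spots=len(result.gaussians),
        images=result.quality_images,
    )
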