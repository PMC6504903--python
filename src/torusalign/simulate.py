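"""Synthetic toroid scenes and acceptor-photobleaching FRET series.

The toroid simulator renders a uniform line emitter along the tilted-ring
model, convolves with an anisotropic Gaussian PSF (the axial width exceeding
the lateral one, as in structured-illumination volumes), optionally adds a
bridge blob offset in the ring plane and point-like background puncta, and
applies Poisson photon noise plus Gaussian read noise.  Every stage is driven
by one integer-seeded generator, so scenes are bit-reproducible per seed.

Default scene conditions
------------------------
Scenes are pixel-scaled: lateral voxel 2 nm, axial voxel 6 nm, PSF sigmas
(4 nm lateral, 36 nm axial) = (2 lateral px, 6 slices).  Ring diameters of
90-170 nm then span radii of 22.5-42.5 lateral px, so a single scene carries
enough voxels for the eight-spot cross-sectional fit to be well posed.  See
docs/methods.md for what these scenes do and do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import RingPose, ring_point
from .io import VolumeImage

DEFAULT_VOXEL = (6.0, 2.0, 2.0)  # (dz, dy, dx) nm
DEFAULT_PSF = (4.0, 36.0)  # (lateral, axial) sigma, nm


@dataclass
class SceneSpec:
    """Ground-truth description of a synthetic toroid scene.

    All lengths in nm.  ``bridge_offset_nm``/``bridge_extent_nm`` default to
    1.75x and 0.2x the ring radius (a compact lobe just outside the ring,
    like the half-bridge domain next to the SPB toroid).
    """

    diameter_nm: float = 160.0
    theta_deg: float = 20.0
    phi_deg: float = 60.0
    voxel_size_nm: tuple = DEFAULT_VOXEL
    psf_sigma_nm: tuple = DEFAULT_PSF  # (lateral, axial)
    photon_budget: float = 4e6
    bridge_fraction: float = 0.0
    bridge_offset_nm: float | None = None
    bridge_extent_nm: float | None = None
    n_puncta: int = 0
    puncta_flux: float = 0.0
    read_noise_sd: float = 3.0
    poisson: bool = True
    seed: int = 0
    shape: tuple | None = None  # (nz, ny, nx); auto-sized when None

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        if not (0.0 <= self.bridge_fraction <= 1.0):
            raise ValueError("bridge_fraction must be in [0, 1]")
        lat, ax = self.psf_sigma_nm
        if ax < lat:
            raise ValueError(
                "axial PSF sigma must be >= lateral (anisotropic microscope)"
            )
        if self.bridge_offset_nm is None:
            self.bridge_offset_nm = 1.75 * self.diameter_nm / 2
        if self.bridge_extent_nm is None:
            self.bridge_extent_nm = 0.2 * self.diameter_nm / 2


@dataclass
class GroundTruth:
    """Oracle record for a simulated scene (pixel-unit pose, fluxes)."""

    pose: RingPose  # lateral-pixel units; zc = slice * aspect
    voxel_size_nm: tuple
    ring_flux: float
    bridge_flux: float
    bridge_center_px: np.ndarray | None  # (x, y, z_latpx)
    puncta_px: np.ndarray  # (n, 3) of (x, y, z_latpx)
    clean_total: float = 0.0


def _auto_shape(spec: SceneSpec) -> tuple:
    dz, dy, dx = spec.voxel_size_nm
    aspect = dz / dx
    r_px = spec.diameter_nm / 2 / dx
    s_lat = spec.psf_sigma_nm[0] / dx
    s_ax_sl = spec.psf_sigma_nm[1] / dz
    half_lat = math.ceil(1.6 * r_px + 3 * s_lat + 4)
    if spec.bridge_fraction > 0:
        half_lat = math.ceil(
            max(half_lat,
                (spec.bridge_offset_nm + 3 * spec.bridge_extent_nm) / dx
                + 3 * s_lat + 4)
        )
    z_amp_sl = r_px * math.sin(math.radians(spec.theta_deg)) / aspect
    half_z = math.ceil(z_amp_sl + 3 * s_ax_sl + 4)
    return (2 * half_z + 1, 2 * half_lat + 1, 2 * half_lat + 1)


def _splat(volume: np.ndarray, zyx: np.ndarray, weights: np.ndarray) -> None:
    """Trilinear deposition of point emitters into a (z,y,x) volume."""
    nz, ny, nx = volume.shape
    base = np.floor(zyx).astype(int)
    frac = zyx - base
    for dzi in (0, 1):
        for dyi in (0, 1):
            for dxi in (0, 1):
                w = (
                    (frac[:, 0] if dzi else 1 - frac[:, 0])
                    * (frac[:, 1] if dyi else 1 - frac[:, 1])
                    * (frac[:, 2] if dxi else 1 - frac[:, 2])
                ) * weights
                iz, iy, ix = base[:, 0] + dzi, base[:, 1] + dyi, base[:, 2] + dxi
                ok = (
                    (iz >= 0) & (iz < nz)
                    & (iy >= 0) & (iy < ny)
                    & (ix >= 0) & (ix < nx)
                )
                np.add.at(volume, (iz[ok], iy[ok], ix[ok]), w[ok])


def simulate_toroid_volume(spec: SceneSpec, return_clean: bool = False):
    """Render one toroid scene.

    Returns ``(VolumeImage, GroundTruth)`` (plus the noise-free volume when
    ``return_clean``).  The ring is integrated with sub-pixel arc sampling
    (>= 64 samples per pixel of arc length) so the rendered truth is far
    below the fit tolerances.
    """
    rng = np.random.default_rng(spec.seed)
    dz, dy, dx = spec.voxel_size_nm
    aspect = dz / dx
    shape = spec.shape or _auto_shape(spec)
    nz, ny, nx = shape
    r_px = spec.diameter_nm / 2 / dx
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2 * aspect])
    pose = RingPose(
        center[0], center[1], center[2], r_px,
        math.radians(spec.theta_deg), math.radians(spec.phi_deg),
    )
    # bounds check: the full circle must fall inside the volume
    probe = ring_point(pose, np.linspace(0, 2 * math.pi, 256, endpoint=False))
    zi = probe[:, 2] / aspect
    margin = 1.0
    if (
        probe[:, 0].min() < margin or probe[:, 0].max() > nx - 1 - margin
        or probe[:, 1].min() < margin or probe[:, 1].max() > ny - 1 - margin
        or zi.min() < margin or zi.max() > nz - 1 - margin
    ):
        raise ValueError(
            f"ring (r={r_px:.1f} px, theta={spec.theta_deg} deg) exceeds "
            f"volume bounds {shape}; enlarge the canvas"
        )

    clean = np.zeros(shape, dtype=np.float64)
    ring_flux = spec.photon_budget * (1.0 - spec.bridge_fraction)
    bridge_flux = spec.photon_budget * spec.bridge_fraction
    n_samp = max(1024, int(64 * 2 * math.pi * r_px))
    rho = (np.arange(n_samp) + 0.5) * (2 * math.pi / n_samp)
    pts = ring_point(pose, rho)
    zyx = np.column_stack([pts[:, 2] / aspect, pts[:, 1], pts[:, 0]])
    _splat(clean, zyx, np.full(n_samp, ring_flux / n_samp))

    bridge_center = None
    if spec.bridge_fraction > 0:
        # in-plane radial direction that maps onto +x after flattening
        st, ct = math.sin(pose.theta), math.cos(pose.theta)
        sp, cp = math.sin(pose.phi), math.cos(pose.phi)
        e2 = np.array([ct * cp, ct * sp, -st])
        bridge_center = center + (spec.bridge_offset_nm / dx) * e2
        sigma_px = spec.bridge_extent_nm / dx
        n_b = 4096
        cloud = bridge_center[None, :] + rng.normal(0, sigma_px, (n_b, 3))
        zyx_b = np.column_stack([cloud[:, 2] / aspect, cloud[:, 1], cloud[:, 0]])
        _splat(clean, zyx_b, np.full(n_b, bridge_flux / n_b))

    puncta = np.empty((0, 3))
    if spec.n_puncta > 0:
        lo = np.array([3.0, 3.0, 3.0 * aspect])
        hi = np.array([nx - 4.0, ny - 4.0, (nz - 4.0) * aspect])
        puncta = rng.uniform(lo, hi, (spec.n_puncta, 3))
        zyx_p = np.column_stack(
            [puncta[:, 2] / aspect, puncta[:, 1], puncta[:, 0]]
        )
        _splat(clean, zyx_p, np.full(spec.n_puncta, spec.puncta_flux))

    s_lat_px = spec.psf_sigma_nm[0] / dx
    s_ax_sl = spec.psf_sigma_nm[1] / dz
    if s_lat_px > 0 or s_ax_sl > 0:
        clean = gaussian_filter(clean, (s_ax_sl, s_lat_px, s_lat_px),
                                mode="constant", truncate=5.0)

    noisy = clean
    if spec.poisson:
        noisy = rng.poisson(noisy).astype(np.float64)
    if spec.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.read_noise_sd, shape)
    noisy = np.clip(noisy, 0.0, None)

    truth = GroundTruth(
        pose=pose,
        voxel_size_nm=spec.voxel_size_nm,
        ring_flux=ring_flux,
        bridge_flux=bridge_flux,
        bridge_center_px=bridge_center,
        puncta_px=puncta,
        clean_total=float(clean.sum()),
    )
    vol = VolumeImage(noisy, spec.voxel_size_nm, channel_name="sim")
    if return_clean:
        return vol, truth, clean
    return vol, truth


def predicted_peak_snr(spec: SceneSpec) -> float:
    """Expected peak signal-to-noise of a scene.

    Peak ring intensity for a line emitter under a normalised 3D Gaussian
    PSF is lambda / (2*pi*sigma_lat*sigma_z) with lambda the flux per unit
    arc length; the noise at the peak is Poisson + read noise.
    """
    dz, _, dx = spec.voxel_size_nm
    r_px = spec.diameter_nm / 2 / dx
    lam = spec.photon_budget * (1 - spec.bridge_fraction) / (2 * math.pi * r_px)
    peak = lam / (2 * math.pi * (spec.psf_sigma_nm[0] / dx)
                  * (spec.psf_sigma_nm[1] / dz))
    noise = math.sqrt((peak if spec.poisson else 0.0) + spec.read_noise_sd**2)
    return peak / noise


PRESETS = {
    # diameters from the biological targets these scenes emulate
    "diploid-ndc1": dict(diameter_nm=160.0, theta_deg=20.0, phi_deg=60.0),
    "haploid": dict(diameter_nm=100.0, theta_deg=15.0, phi_deg=30.0),
    "nbp1-like": dict(diameter_nm=135.0, theta_deg=20.0, phi_deg=60.0),
    "fiducial-170": dict(diameter_nm=170.0, theta_deg=20.0, phi_deg=60.0),
    "mps3-like": dict(diameter_nm=160.0, theta_deg=10.0, phi_deg=0.0,
                      bridge_fraction=0.55),
    "npc-background": dict(diameter_nm=160.0, theta_deg=20.0, phi_deg=60.0,
                           n_puncta=12, puncta_flux=2e4),
}


def preset_scene(name: str, seed: int = 0, **overrides) -> SceneSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SceneSpec(seed=seed, **kw)


# ---------------------------------------------------------------------------
# FRET bleach series
# ---------------------------------------------------------------------------

@dataclass
class FretSeriesTruth:
    positions: np.ndarray  # (n, 2) of (x, y)
    efficiency: float
    donor_only_bleach: float
    pre_flux: np.ndarray
    post_flux: np.ndarray
    expected_raw_e: float  # (E - b) / (1 - b) under the bleach model


def simulate_fret_series(
    true_efficiency: float,
    n_spots: int,
    donor_only_bleach: float = 0.0,
    noise: bool = True,
    seed: int = 0,
    spot_flux: float = 4000.0,
    spot_sigma: float = 2.0,
    background: float = 20.0,
    read_noise_sd: float = 2.0,
    shift: tuple = (0.0, 0.0),
    cell_px: int = 24,
):
    """Paired pre-/post-bleach donor images with known FRET efficiency.

    Acceptor photobleaching releases the donor from quenching, so donor
    intensity rises by 1/(1-E); a fraction ``donor_only_bleach`` of the donor
    itself is destroyed during the acceptor bleach, attenuating the rise by
    (1-b).  Spots are laid on a jittered grid (one per ``cell_px`` cell) so
    they stay resolvable; ``shift`` translates the post image (y, x) to
    exercise registration.
    """
    if not (0.0 <= true_efficiency < 1.0):
        raise ValueError("efficiency must be in [0, 1)")
    if not (0.0 <= donor_only_bleach < 1.0):
        raise ValueError("donor_only_bleach must be in [0, 1)")
    rng = np.random.default_rng(seed)
    per_side = math.ceil(math.sqrt(n_spots))
    size = per_side * cell_px + 2 * cell_px
    jitter = cell_px / 2 - 4 * spot_sigma / 2 - 1
    jitter = max(jitter, 1.0)
    cells = [(i, j) for i in range(per_side) for j in range(per_side)][:n_spots]
    pos = np.array(
        [
            [
                cell_px + (j + 0.5) * cell_px + rng.uniform(-jitter, jitter),
                cell_px + (i + 0.5) * cell_px + rng.uniform(-jitter, jitter),
            ]
            for i, j in cells
        ]
    )  # (x, y)
    d0 = spot_flux * rng.uniform(0.7, 1.3, n_spots)  # unquenched donor flux
    pre_flux = d0 * (1.0 - true_efficiency)
    post_flux = d0 * (1.0 - donor_only_bleach)

    yy, xx = np.mgrid[0:size, 0:size]

    def render(flux, dx_off=0.0, dy_off=0.0):
        img = np.full((size, size), float(background))
        for (x, y), f in zip(pos, flux):
            x, y = x + dx_off, y + dy_off
            r2 = (xx - x) ** 2 + (yy - y) ** 2
            img += f / (2 * math.pi * spot_sigma**2) * np.exp(
                -r2 / (2 * spot_sigma**2)
            )
        return img

    pre = render(pre_flux)
    post = render(post_flux, dx_off=shift[1], dy_off=shift[0])
    if noise:
        pre = rng.poisson(pre).astype(float) + rng.normal(0, read_noise_sd, pre.shape)
        post = rng.poisson(post).astype(float) + rng.normal(0, read_noise_sd, post.shape)
        pre = np.clip(pre, 0, None)
        post = np.clip(post, 0, None)
    b = donor_only_bleach
    truth = FretSeriesTruth(
        positions=pos,
        efficiency=true_efficiency,
        donor_only_bleach=b,
        pre_flux=pre_flux,
        post_flux=post_flux,
        expected_raw_e=(true_efficiency - b) / (1.0 - b),
    )
    return pre, post, truth
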