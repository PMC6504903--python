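"""Metrology on averaged toroid maps.

Radial profiles by arc-length sampling on expanding circles; ring diameters
from two-Gaussian fits to vertical/horizontal line profiles; Monte Carlo
(residual-calibrated parametric bootstrap) standard errors; fiducial
normalization across strains; two-tailed t-tests on Monte Carlo diameter
distributions; and toroid/bridge fluorescence partitioning.

The Monte Carlo procedure: the per-point noise SD is estimated from the
residuals of the two-Gaussian fit, replicate profiles are synthesized as
fitted model + Gaussian noise of that SD, each replicate is refitted, and
the SD of the refitted diameters is reported as the error bar.  Reported
"+/-" values are therefore the SD of the bootstrap diameter distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .averaging import AverageMap
from .io import VolumeImage


def _as_volume(obj) -> VolumeImage:
    return obj.volume if isinstance(obj, AverageMap) else obj


def _central_image(vol: VolumeImage, z="central") -> np.ndarray:
    """A 2D (y, x) view of the volume: central slice, index, or max/sum
    projection."""
    if z == "central":
        return vol.data[vol.shape[0] // 2]
    if z == "max":
        return vol.data.max(axis=0)
    if z == "sum":
        return vol.data.sum(axis=0)
    return vol.data[int(z)]


@dataclass
class RadialProfile:
    radii_px: np.ndarray
    mean_intensity: np.ndarray
    counts: np.ndarray
    nm_per_px: float

    @property
    def radii_nm(self) -> np.ndarray:
        return self.radii_px * self.nm_per_px

    @property
    def argmax_radius_px(self) -> float:
        return float(self.radii_px[int(np.argmax(self.mean_intensity))])


def radial_profile(avg, center=None, z="central", r_max=None) -> RadialProfile:
    """Mean intensity on expanding circles around ``center``.

    Each circle of integer radius rho is sampled at ~1-pixel arc spacing by
    bilinear interpolation and averaged.
    """
    vol = _as_volume(avg)
    img = _central_image(vol, z)
    ny, nx = img.shape
    if center is None:
        center = ((nx - 1) / 2, (ny - 1) / 2)
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError("center outside image")
    if r_max is None:
        r_max = int(min(cx, cy, nx - 1 - cx, ny - 1 - cy))
    radii = np.arange(0, r_max + 1)
    means = np.empty(radii.size)
    counts = np.empty(radii.size, dtype=int)
    for i, rho in enumerate(radii):
        n = max(1, int(round(2 * math.pi * rho)))
        ang = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        xs = cx + rho * np.cos(ang)
        ys = cy + rho * np.sin(ang)
        vals = map_coordinates(img, np.array([ys, xs]), order=1, mode="nearest")
        means[i] = vals.mean()
        counts[i] = n
    return RadialProfile(radii.astype(float), means, counts, vol.nm_per_px())


class DiameterResolutionError(RuntimeError):
    """The ring profile has no resolvable intensity pair."""


@dataclass
class _ProfileFit:
    """One line profile and its two-Gaussian fit (internal record)."""

    coords: np.ndarray  # px
    values: np.ndarray
    params: np.ndarray  # c1, c2, a1, a2, sigma, baseline
    residual_sd: float

    @property
    def separation_px(self) -> float:
        return float(abs(self.params[1] - self.params[0]))


@dataclass
class DiameterEstimate:
    """Ring diameter with Monte Carlo error.

    ``diameter_nm`` averages the vertical and horizontal components when the
    ring is symmetric (within ``asymmetry_tol``); otherwise both components
    are reported separately and ``symmetric`` is False.  ``se_nm`` is the SD
    of the Monte Carlo diameter distribution (None before
    :func:`monte_carlo_error` runs).
    """

    diameter_nm: float
    vertical_nm: float
    horizontal_nm: float
    symmetric: bool
    asymmetry_tol: float
    se_nm: float | None = None
    vertical_se_nm: float | None = None
    horizontal_se_nm: float | None = None
    mc_distribution: np.ndarray | None = None
    nm_per_px: float = 1.0
    fits: dict = field(default_factory=dict)  # "vertical"/"horizontal" -> _ProfileFit

    def summary(self) -> str:
        lines = ["Ring diameter estimate", "=" * 40]
        if self.symmetric:
            se = f" +/- {self.se_nm:.1f}" if self.se_nm is not None else ""
            lines.append(f"diameter: {self.diameter_nm:.1f}{se} nm "
                         "(mean of vertical and horizontal)")
        else:
            lines.append("asymmetric ring; components reported separately")
        for name, v, s in (
            ("vertical", self.vertical_nm, self.vertical_se_nm),
            ("horizontal", self.horizontal_nm, self.horizontal_se_nm),
        ):
            se = f" +/- {s:.1f}" if s is not None else ""
            lines.append(f"  {name}: {v:.1f}{se} nm")
        if self.mc_distribution is not None:
            lines.append(f"Monte Carlo replicates: {self.mc_distribution.size}"
                         " (errors are the SD of the replicate diameters)")
        return "\n".join(lines)


def _two_gauss(x, p):
    c1, c2, a1, a2, s, b = p
    return (
        b
        + a1 * np.exp(-((x - c1) ** 2) / (2 * s * s))
        + a2 * np.exp(-((x - c2) ** 2) / (2 * s * s))
    )


def _fit_two_gauss(x, y, init=None) -> _ProfileFit:
    """Two Gaussians with a shared width and constant baseline."""
    n = x.size
    if init is None:
        mid = n // 2
        b0 = float(np.percentile(y, 10))
        i1 = int(np.argmax(y[:mid]))
        i2 = mid + int(np.argmax(y[mid:]))
        c1, c2 = float(x[i1]), float(x[i2])
        if abs(c2 - c1) < 2.0:
            raise DiameterResolutionError(
                "profile peaks unresolved: diameter below resolution"
            )
        a1 = max(float(y[i1] - b0), 1e-12)
        a2 = max(float(y[i2] - b0), 1e-12)
        s0 = max(1.5, 0.1 * abs(c2 - c1))
        init = np.array([c1, c2, a1, a2, s0, b0])
    span = float(x[-1] - x[0])
    lo = [x[0], x[0], 0.0, 0.0, 0.5, -np.inf]
    hi = [x[-1], x[-1], np.inf, np.inf, span, np.inf]
    sol = least_squares(
        lambda p: _two_gauss(x, p) - y, np.clip(init, lo, hi),
        bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=2000,
    )
    p = sol.x
    if p[0] > p[1]:  # canonical order: left center first
        p = p[[1, 0, 3, 2, 4, 5]]
    resid = _two_gauss(x, p) - y
    sd = float(np.std(resid, ddof=min(6, resid.size - 1)))
    sep = abs(p[1] - p[0])
    if sep < 1.2 * p[4] or sep < 1.0:
        raise DiameterResolutionError(
            f"fitted peak separation {sep:.2f} px below the resolvable limit "
            f"(sigma {p[4]:.2f} px): diameter below resolution"
        )
    return _ProfileFit(coords=x, values=y, params=p, residual_sd=sd)


def _line_profiles(vol: VolumeImage, center, z, band_width: int):
    """Vertical and horizontal band-averaged profiles through the center."""
    img = _central_image(vol, z)
    ny, nx = img.shape
    if center is None:
        center = ((nx - 1) / 2, (ny - 1) / 2)
    cx, cy = int(round(center[0])), int(round(center[1]))
    half = band_width // 2
    rows = slice(max(0, cy - half), min(ny, cy + half + 1))
    cols = slice(max(0, cx - half), min(nx, cx + half + 1))
    horizontal = img[rows, :].mean(axis=0)
    vertical = img[:, cols].mean(axis=1)
    return (
        (np.arange(ny, dtype=float), vertical),
        (np.arange(nx, dtype=float), horizontal),
    )


def diameter_from_average(
    avg,
    center=None,
    z="central",
    band_width: int = 3,
    asymmetry_tol: float = 0.05,
) -> DiameterEstimate:
    """Ring diameter from two-Gaussian fits to the central line profiles.

    Vertical and horizontal profiles (``band_width``-pixel averaged bands
    through the center) are each fit to two Gaussians with shared width; a
    component diameter is the distance between the fitted centers.  If the
    components agree within ``asymmetry_tol`` (relative), their average is
    reported with the ring flagged symmetric; otherwise both components
    stand on their own (asymmetric rings such as half-bridge-biased ones).
    """
    vol = _as_volume(avg)
    (xv, yv), (xh, yh) = _line_profiles(vol, center, z, band_width)
    fit_v = _fit_two_gauss(xv, yv)
    fit_h = _fit_two_gauss(xh, yh)
    nmpp = vol.nm_per_px()
    dv = fit_v.separation_px * nmpp
    dh = fit_h.separation_px * nmpp
    mean_d = 0.5 * (dv + dh)
    symmetric = abs(dv - dh) <= asymmetry_tol * mean_d
    return DiameterEstimate(
        diameter_nm=mean_d,
        vertical_nm=dv,
        horizontal_nm=dh,
        symmetric=symmetric,
        asymmetry_tol=asymmetry_tol,
        nm_per_px=nmpp,
        fits={"vertical": fit_v, "horizontal": fit_h},
    )


def monte_carlo_error(
    estimate: DiameterEstimate, n_reps: int = 200, seed: int = 0
) -> DiameterEstimate:
    """Residual-calibrated parametric bootstrap of the diameter fit.

    Replicate profiles are the fitted model plus Gaussian noise at the
    residual SD; each is refitted and the SD of the replicate diameters is
    the reported error.  Component errors propagate to the combined
    diameter as independent errors of a mean (quadrature / 2).
    """
    if not estimate.fits:
        raise ValueError("estimate carries no profile fits to resample")
    if n_reps < 20:
        warnings.warn(
            f"n_reps={n_reps} gives a poorly determined Monte Carlo error",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    comp = {}
    for name in ("vertical", "horizontal"):
        f = estimate.fits[name]
        model = _two_gauss(f.coords, f.params)
        seps = []
        for _ in range(n_reps):
            y_rep = model + rng.normal(0.0, f.residual_sd, model.size)
            try:
                fr = _fit_two_gauss(f.coords, y_rep, init=f.params.copy())
            except DiameterResolutionError:
                continue
            seps.append(fr.separation_px)
        if len(seps) < max(2, n_reps // 2):
            raise RuntimeError(
                f"Monte Carlo refits failed for the {name} profile"
            )
        comp[name] = np.asarray(seps) * estimate.nm_per_px
    nv, nh = comp["vertical"].size, comp["horizontal"].size
    n = min(nv, nh)
    combined = 0.5 * (comp["vertical"][:n] + comp["horizontal"][:n])
    se_v = float(np.std(comp["vertical"], ddof=1))
    se_h = float(np.std(comp["horizontal"], ddof=1))
    return replace(
        estimate,
        se_nm=float(np.std(combined, ddof=1)),
        vertical_se_nm=se_v,
        horizontal_se_nm=se_h,
        mc_distribution=combined,
    )


def normalize_diameters(
    sample: DiameterEstimate,
    fiducial: DiameterEstimate,
    fiducial_reference_nm: float,
) -> DiameterEstimate:
    """Rescale a diameter by a co-imaged fiducial's known reference size.

    ``scaled = sample * reference / fiducial``; relative errors of sample
    and fiducial combine in quadrature.
    """
    if fiducial.diameter_nm <= 0:
        raise ValueError("fiducial diameter must be positive")
    scale = fiducial_reference_nm / fiducial.diameter_nm
    rel = 0.0
    if sample.se_nm is not None and sample.diameter_nm > 0:
        rel += (sample.se_nm / sample.diameter_nm) ** 2
    if fiducial.se_nm is not None:
        rel += (fiducial.se_nm / fiducial.diameter_nm) ** 2
    new_d = sample.diameter_nm * scale
    return replace(
        sample,
        diameter_nm=new_d,
        vertical_nm=sample.vertical_nm * scale,
        horizontal_nm=sample.horizontal_nm * scale,
        se_nm=new_d * math.sqrt(rel) if rel > 0 else sample.se_nm,
        mc_distribution=(
            sample.mc_distribution * scale
            if sample.mc_distribution is not None else None
        ),
    )


def compare_diameters(a: np.ndarray, b: np.ndarray):
    """Two-sample two-tailed t-test on Monte Carlo diameter distributions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 20 or b.size < 20:
        raise ValueError("need at least 20 Monte Carlo draws per group")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("zero variance in both distributions")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# toroid / bridge partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnulusMask:
    """Annular mask around a center, radii in px."""

    cx: float
    cy: float
    r_in: float
    r_out: float

    def to_mask(self, shape) -> np.ndarray:
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        r2 = (xx - self.cx) ** 2 + (yy - self.cy) ** 2
        return (r2 >= self.r_in**2) & (r2 <= self.r_out**2)


@dataclass(frozen=True)
class SectorMask:
    """Wedge between two radii, centered on ``direction_deg`` (from +x),
    spanning +/- ``half_angle_deg``."""

    cx: float
    cy: float
    r_in: float
    r_out: float
    direction_deg: float = 0.0
    half_angle_deg: float = 45.0

    def to_mask(self, shape) -> np.ndarray:
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        dx, dy = xx - self.cx, yy - self.cy
        r2 = dx**2 + dy**2
        ang = np.degrees(np.arctan2(dy, dx))
        dang = (ang - self.direction_deg + 180.0) % 360.0 - 180.0
        return (
            (r2 >= self.r_in**2)
            & (r2 <= self.r_out**2)
            & (np.abs(dang) <= self.half_angle_deg)
        )


def _resolve_mask(mask, shape) -> np.ndarray:
    m = mask.to_mask(shape) if hasattr(mask, "to_mask") else np.asarray(mask, bool)
    if m.shape != tuple(shape):
        raise ValueError("mask shape does not match image")
    return m


def toroid_bridge_fraction(particle_or_avg, ring_mask, bridge_mask):
    """Fraction of background-subtracted flux in the ring vs bridge mask.

    Works on the z-projected image.  The background level is the histogram
    mode of pixels outside both masks.  Masks must be non-empty and
    disjoint; the two fractions sum to 1 by construction.
    """
    vol = _as_volume(particle_or_avg)
    img = vol.data.sum(axis=0)
    m_ring = _resolve_mask(ring_mask, img.shape)
    m_bridge = _resolve_mask(bridge_mask, img.shape)
    if not m_ring.any() or not m_bridge.any():
        raise ValueError("mask spec selects no pixels")
    if (m_ring & m_bridge).any():
        raise ValueError("ring and bridge masks overlap")
    outside = ~(m_ring | m_bridge)
    if outside.any():
        vals = img[outside]
        lo, hi = np.percentile(vals, [0.5, 99.5])
        if hi <= lo:
            bg = float(vals.mean())
        else:
            hist, edges = np.histogram(vals, bins=128, range=(lo, hi))
            bg = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    else:
        bg = 0.0
    flux_ring = max(float((img[m_ring] - bg).sum()), 0.0)
    flux_bridge = max(float((img[m_bridge] - bg).sum()), 0.0)
    total = flux_ring + flux_bridge
    if total <= 0:
        raise ValueError("no flux above background in either mask")
    return flux_ring / total, flux_bridge / total
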