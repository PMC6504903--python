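"""Tilted-ring geometry: the parametric circle model and its plane crossings.

The central object is a circle of radius ``r`` in 3D, tilted from the image
plane by ``theta`` and rotated about the optical (z) axis by ``phi``.  A point
at travel angle ``rho`` along the ring is

    x(rho) = xc - r cos(rho) sin(phi) + r sin(rho) cos(theta) cos(phi)
    y(rho) = yc + r cos(rho) cos(phi) + r sin(rho) cos(theta) sin(phi)
    z(rho) = zc - r sin(rho) sin(theta)

All geometry here lives in isotropic *lateral-pixel* units: callers working
with anisotropic z sampling convert slice indices via ``z_px = z_slice*dz/dx``
before entering this module.

Cross-sectional fitting needs the two travel angles at which the ring pierces
each of four vertical planes through a guessed center: the plane x=0
(conventionally the "xz" crossings), y=0 ("yz"), x=y ("45") and x=-y ("135").
Each reduces to a harmonic equation ``A sin(rho) + B cos(rho) + C = 0`` that is
solved in closed form; the dimensionless intermediates ``a_P``/``c_P`` of the
classical tan^-1 formulation are reported alongside for reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

#: plane key -> in-plane strip direction angle (degrees from +x axis)
PLANE_ANGLES = {"yz": 0.0, "45": 45.0, "xz": 90.0, "135": 135.0}
PLANES = ("xz", "yz", "45", "135")


@dataclass(frozen=True)
class RingPose:
    """Pose of a tilted ring, in isotropic lateral-pixel units.

    Parameters
    ----------
    xc, yc, zc : float
        Ring center.  ``zc`` is in lateral-pixel units (slice index times
        the z/xy voxel aspect).
    r : float
        Ring radius (> 0).
    theta : float
        Tilt from the image plane, radians, in [0, pi/2).
    phi : float
        Rotation about the z axis, radians; stored wrapped to [0, 2*pi).
    """

    xc: float
    yc: float
    zc: float
    r: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise ValueError(f"ring radius must be positive, got {self.r}")
        if not (0.0 <= self.theta < math.pi / 2):
            raise ValueError(
                f"tilt theta must lie in [0, pi/2), got {self.theta}"
            )
        object.__setattr__(self, "phi", self.phi % TWO_PI)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.xc, self.yc, self.zc], dtype=float)

    def zc_slice(self, aspect: float) -> float:
        """Ring-center z as a slice index given aspect = dz/dx."""
        return self.zc / aspect


def ring_point(pose: RingPose, rho) -> np.ndarray:
    """Evaluate the ring model at travel angle(s) ``rho``.

    Returns an array of shape ``rho.shape + (3,)`` with (x, y, z) columns.
    Every returned point is at distance ``pose.r`` from the ring center.
    """
    rho = np.asarray(rho, dtype=float)
    st, ct = math.sin(pose.theta), math.cos(pose.theta)
    sp, cp = math.sin(pose.phi), math.cos(pose.phi)
    r = pose.r
    x = pose.xc - r * np.cos(rho) * sp + r * np.sin(rho) * ct * cp
    y = pose.yc + r * np.cos(rho) * cp + r * np.sin(rho) * ct * sp
    z = pose.zc - r * np.sin(rho) * st
    return np.stack([x, y, z], axis=-1)


def _plane_coefficients(pose: RingPose, plane: str, center_guess) -> tuple:
    """Harmonic coefficients (A, B, C) of the plane-crossing equation.

    The plane passes through ``center_guess``; in guess-relative coordinates
    the four planes are x=0 ("xz"), y=0 ("yz"), x=y ("45"), x=-y ("135") and
    substituting the ring model yields ``A sin(rho) + B cos(rho) + C = 0``.
    """
    gx, gy = float(center_guess[0]), float(center_guess[1])
    st, ct = math.sin(pose.theta), math.cos(pose.theta)
    sp, cp = math.sin(pose.phi), math.cos(pose.phi)
    r = pose.r
    dx, dy = pose.xc - gx, pose.yc - gy
    if plane == "xz":  # x_rel = 0
        return r * ct * cp, -r * sp, dx
    if plane == "yz":  # y_rel = 0
        return r * ct * sp, r * cp, dy
    if plane == "45":  # x_rel - y_rel = 0
        return r * ct * (cp - sp), -r * (sp + cp), dx - dy
    if plane == "135":  # x_rel + y_rel = 0
        return r * ct * (cp + sp), r * (cp - sp), dx + dy
    raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")


def _classic_intermediates(pose: RingPose, plane: str, center_guess) -> tuple:
    """The dimensionless (a_P, c_P) of the tan^-1 formulation.

    These are the harmonic coefficients divided by the plane-specific factor
    ``r*cos(theta)*cos(phi)`` (and analogues); NaN where that factor vanishes.
    """
    A, B, C = _plane_coefficients(pose, plane, center_guess)
    if abs(A) < 1e-12:
        return math.nan, math.nan
    # sign conventions follow the printed forms: a multiplies -cos(rho) for
    # the x=0 plane and +cos(rho) for the others
    sign = -1.0 if plane == "xz" else 1.0
    return sign * B / A, C / A


@dataclass
class PlaneCrossings:
    """Crossings of a ring with one vertical plane through a guess center."""

    plane: str
    a: float
    c: float
    rhos: np.ndarray  # shape (2,) when real, (0,) otherwise
    points: np.ndarray  # shape (2, 3) or (0, 3)
    status: str = "ok"  # "ok" | "no_crossing" | "degenerate"
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _order_pair(plane: str, rhos, points, center_guess) -> tuple:
    """Stable ordering: the crossing in the plane's positive half-axis first.

    The positive half is the strip direction (cos(alpha), sin(alpha)) for the
    section angle alpha of the plane; ties break by increasing rho.  This is
    what keeps paired spots from being swapped between fit iterations.
    """
    alpha = math.radians(PLANE_ANGLES[plane])
    u = np.array([math.cos(alpha), math.sin(alpha)])
    t = (points[:, :2] - np.asarray(center_guess[:2], dtype=float)) @ u
    order = np.lexsort((rhos, -t))
    return rhos[order], points[order], t[order]


def plane_crossings(
    pose: RingPose, plane: str, center_guess, tol: float = 1e-6
) -> PlaneCrossings:
    """Solve for the two travel angles where the ring pierces ``plane``.

    Candidates from both solution branches are verified by substitution into
    the ring model (plane equation satisfied to ``tol`` pixels) and returned
    in [0, 2*pi), ordered with the positive-half crossing first.
    """
    A, B, C = _plane_coefficients(pose, plane, center_guess)
    a, c = _classic_intermediates(pose, plane, center_guess)
    R = math.hypot(A, B)
    empty = (np.empty(0), np.empty((0, 3)))
    if R < 1e-12 * max(pose.r, 1.0):
        return PlaneCrossings(
            plane, a, c, *empty, status="degenerate",
            message="plane equation independent of rho (degenerate pose)",
        )
    s = -C / R
    if abs(s) > 1.0 + 1e-12:
        return PlaneCrossings(
            plane, a, c, *empty, status="no_crossing",
            message=f"ring does not cross plane {plane} "
                    f"(|C|/R = {abs(s):.3f} > 1)",
        )
    s = min(1.0, max(-1.0, s))
    delta = math.atan2(B, A)
    base = math.asin(s)
    rhos = np.array([(base - delta) % TWO_PI,
                     (math.pi - base - delta) % TWO_PI])
    points = ring_point(pose, rhos)
    # substitution check against the plane equation, in pixels
    resid = A * np.sin(rhos) + B * np.cos(rhos) + C
    keep = np.abs(resid) <= tol * max(1.0, R)
    if not np.all(keep):  # pragma: no cover - closed form is exact
        rhos, points = rhos[keep], points[keep]
    if rhos.size < 2:  # tangency collapses to a double root
        rhos = np.repeat(rhos, 2)[:2]
        points = ring_point(pose, rhos)
    rhos, points, _ = _order_pair(plane, rhos, points, center_guess)
    return PlaneCrossings(plane, a, c, rhos, points)


def brute_force_crossings(
    pose: RingPose,
    plane: str,
    center_guess,
    n_grid: int = 1 << 20,
    refine_tol: float = 1e-12,
) -> PlaneCrossings:
    """Independent crossing solver by dense sampling plus bisection.

    Samples the signed plane equation on an ``n_grid``-point rho grid, finds
    sign changes and refines each bracket by bisection.  Shares the contract
    and ordering of :func:`plane_crossings`; intended as a test oracle.
    """
    A, B, C = _plane_coefficients(pose, plane, center_guess)
    a, c = _classic_intermediates(pose, plane, center_guess)

    def f(rho):
        return A * np.sin(rho) + B * np.cos(rho) + C

    grid = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    vals = f(grid)
    nxt = np.roll(vals, -1)
    idx = np.nonzero(np.sign(vals) * np.sign(nxt) < 0)[0]
    roots = []
    step = TWO_PI / n_grid
    for i in idx:
        lo, hi = grid[i], grid[i] + step
        flo = f(np.array([lo]))[0]
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            fm = f(np.array([mid]))[0]
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        roots.append(0.5 * (lo + hi) % TWO_PI)
    if not roots:
        return PlaneCrossings(
            plane, a, c, np.empty(0), np.empty((0, 3)),
            status="no_crossing", message="no sign change on dense grid",
        )
    rhos = np.array(sorted(roots))
    if rhos.size == 1:
        rhos = np.repeat(rhos, 2)
    points = ring_point(pose, rhos)
    rhos, points, _ = _order_pair(plane, rhos, points, center_guess)
    return PlaneCrossings(plane, a, c, rhos, points)


def flat_circle_crossings(pose: RingPose, plane: str, center_guess) -> PlaneCrossings:
    """Closed-form crossings for a flat ring (theta == 0).

    For theta = 0 the ring is a plain circle in the plane z = zc, and its
    intersection with a vertical plane through the guess center is a chord:
    with u the strip direction and d the in-plane center offset,
    ``t = u.d +/- sqrt(r^2 - (d - (u.d)u)^2)``.  Independent of phi.
    """
    if abs(pose.theta) > 1e-12:
        raise ValueError("flat_circle_crossings requires theta == 0")
    a, c = _classic_intermediates(pose, plane, center_guess)
    alpha = math.radians(PLANE_ANGLES[plane])
    u = np.array([math.cos(alpha), math.sin(alpha)])
    g = np.asarray(center_guess[:2], dtype=float)
    d = np.array([pose.xc, pose.yc]) - g
    proj = float(u @ d)
    perp2 = float(d @ d) - proj * proj
    disc = pose.r**2 - perp2
    if disc < 0:
        return PlaneCrossings(
            plane, a, c, np.empty(0), np.empty((0, 3)),
            status="no_crossing", message="circle does not reach the plane",
        )
    root = math.sqrt(disc)
    ts = np.array([proj + root, proj - root])
    pts = g[None, :] + ts[:, None] * u[None, :]
    points = np.column_stack([pts, np.full(2, pose.zc)])
    # recover rho from the in-plane parameterisation
    sp, cp = math.sin(pose.phi), math.cos(pose.phi)
    rel = pts - np.array([pose.xc, pose.yc])
    sin_rho = (rel @ np.array([cp, sp])) / pose.r
    cos_rho = (rel @ np.array([-sp, cp])) / pose.r
    rhos = np.mod(np.arctan2(sin_rho, cos_rho), TWO_PI)
    rhos, points, _ = _order_pair(plane, rhos, points, center_guess)
    return PlaneCrossings(plane, a, c, rhos, points)


@dataclass
class CrossingSet:
    """The eight ring/plane crossing points used by the global spot fit."""

    pose: RingPose
    center_guess: np.ndarray
    crossings: dict = field(default_factory=dict)  # plane -> PlaneCrossings

    @property
    def n_real(self) -> int:
        return sum(c.rhos.size for c in self.crossings.values())

    @property
    def all_points(self) -> np.ndarray:
        pts = [c.points for c in self.crossings.values() if c.ok]
        return np.concatenate(pts, axis=0) if pts else np.empty((0, 3))


def crossing_set(pose: RingPose, center_guess, solver=plane_crossings) -> CrossingSet:
    """Crossings for all four planes through ``center_guess``."""
    guess = np.asarray(center_guess, dtype=float)
    return CrossingSet(
        pose=pose,
        center_guess=guess,
        crossings={p: solver(pose, p, guess) for p in PLANES},
    )


def flatten_rotation(theta: float, phi: float) -> np.ndarray:
    """Rotation matrix (xyz convention) taking the tilted ring flat.

    Composition Ry(-theta) @ Rz(-phi): first undo the azimuthal rotation,
    then the tilt about the in-plane (y) axis.  Applied to ring-frame
    vectors it maps the ring's plane onto z = const.
    """
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    rz = np.array([[cp, sp, 0.0], [-sp, cp, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
    return ry @ rz


def inplane_rotation(angle: float) -> np.ndarray:
    """Rotation about z by ``angle`` (xyz convention, right-handed)."""
    ca, sa = math.cos(angle), math.sin(angle)
    return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
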