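"""Realign fitted toroids (flatten, rotate), normalize and average them.

A fitted particle is resampled so its ring lies flat at the center of a
fresh canvas: the volume is rigidly rotated by -phi about z then -theta
about the in-plane axis, about the fitted center, and the center is moved
to the canvas center.  Rotations act in physical space, so anisotropic z
sampling is handled by scaling slice indices by the voxel aspect before
rotating and back after.  Resampling is trilinear, which keeps the whole
stage linear in the input and conserves integrated intensity for content
away from the canvas edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, map_coordinates

from .geometry import RingPose, flatten_rotation, inplane_rotation, ring_point
from .io import VolumeImage


@dataclass
class AlignedParticle:
    """A particle volume resampled so its toroid is flat and centered."""

    volume: VolumeImage
    source_pose: RingPose
    rotation_applied: float = 0.0  # in-plane, radians
    brightness_scale: float = 1.0

    @property
    def center(self) -> np.ndarray:
        """(x, y, z_slice) canvas center, where the ring center sits."""
        nz, ny, nx = self.volume.shape
        return np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])


@dataclass
class AverageMap:
    """Voxelwise average of aligned particles, with provenance."""

    volume: VolumeImage
    n: int
    provenance: list = field(default_factory=list)  # (index, brightness_scale)


def _resample(data, matrix_xyz, center_in_xyz, center_out_xyz, aspect,
              output_shape, order=1):
    """Resample ``data`` (z,y,x) through an xyz-space rotation.

    ``matrix_xyz`` maps output physical offsets to input physical offsets
    (i.e. it is the inverse of the rotation being applied to the image).
    Physical units are lateral pixels; slice indices scale by ``aspect``.
    """
    S = np.diag([1.0, 1.0, aspect])  # index (x, y, z_slice) -> physical
    Sinv = np.diag([1.0, 1.0, 1.0 / aspect])
    A_xyz = Sinv @ matrix_xyz @ S
    # convert to (z, y, x) index convention
    J = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    A = J @ A_xyz @ J
    c_in = np.array([center_in_xyz[2], center_in_xyz[1], center_in_xyz[0]])
    c_out = np.array([center_out_xyz[2], center_out_xyz[1], center_out_xyz[0]])
    offset = c_in - A @ c_out
    return affine_transform(
        data, A, offset=offset, output_shape=output_shape, order=order,
        mode="constant", cval=0.0, prefilter=(order > 1),
    )


def flatten_transform(
    volume: VolumeImage,
    pose: RingPose,
    canvas_scale: float = 2.5,
    canvas_shape: tuple | None = None,
    order: int = 1,
) -> AlignedParticle:
    """Resample so the fitted toroid is flat at the canvas center.

    The lateral canvas is an odd square of ``canvas_scale`` times the fitted
    diameter (so "the center" is a single voxel); the z extent keeps the
    source slice count (odd-ified).  Raises if the ring leaves the source
    volume's support.
    """
    nz, ny, nx = volume.shape
    aspect = volume.aspect
    # the ring itself must be inside the resampling support
    probe = ring_point(pose, np.linspace(0, 2 * math.pi, 256, endpoint=False))
    zi = probe[:, 2] / aspect
    if (
        probe[:, 0].min() < 0 or probe[:, 0].max() > nx - 1
        or probe[:, 1].min() < 0 or probe[:, 1].max() > ny - 1
        or zi.min() < 0 or zi.max() > nz - 1
    ):
        raise ValueError(
            "fitted ring extends outside the volume; cannot realign"
        )
    if canvas_shape is None:
        L = int(round(canvas_scale * 2 * pose.r))
        L += (L + 1) % 2  # odd
        Lz = nz if nz % 2 == 1 else nz - 1
        canvas_shape = (Lz, L, L)
    out_nz, out_ny, out_nx = canvas_shape
    R = flatten_rotation(pose.theta, pose.phi)
    # affine maps output coords back to input: inverse rotation.
    # centers are index coordinates (x, y, z_slice).
    aligned = _resample(
        volume.data, R.T,
        center_in_xyz=(pose.xc, pose.yc, pose.zc / aspect),
        center_out_xyz=((out_nx - 1) / 2, (out_ny - 1) / 2, (out_nz - 1) / 2),
        aspect=aspect, output_shape=canvas_shape, order=order,
    )
    out = VolumeImage(
        np.clip(aligned, 0.0, None), volume.voxel_size,
        channel_name=volume.channel_name,
    )
    return AlignedParticle(volume=out, source_pose=pose)


def _rotate_inplane_volume(vol: VolumeImage, angle: float, order: int = 1):
    """Rotate a volume in the xy plane about its lateral center."""
    nz, ny, nx = vol.shape
    c = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    R = inplane_rotation(angle)
    data = _resample(
        vol.data, R.T, center_in_xyz=c, center_out_xyz=c,
        aspect=vol.aspect, output_shape=vol.shape, order=order,
    )
    return VolumeImage(np.clip(data, 0.0, None), vol.voxel_size,
                       channel_name=vol.channel_name)


def orient_by_secondary(
    p: AlignedParticle, reference_point, target: str = "up"
) -> AlignedParticle:
    """In-plane rotation so the center-to-reference vector points +y ("up")
    or +x ("sideways").

    ``reference_point`` is an (x, y) location in the aligned frame, e.g. the
    centroid of a secondary-channel lobe whose direction should be
    standardised before averaging.
    """
    if target not in ("up", "sideways"):
        raise ValueError("target must be 'up' or 'sideways'")
    cx, cy, _ = p.center
    vx, vy = float(reference_point[0]) - cx, float(reference_point[1]) - cy
    norm = math.hypot(vx, vy)
    if norm < 1e-9:
        raise ValueError("reference point coincides with the center")
    current = math.atan2(vy, vx)
    goal = math.pi / 2 if target == "up" else 0.0
    angle = goal - current
    vol = _rotate_inplane_volume(p.volume, angle)
    return AlignedParticle(
        volume=vol, source_pose=p.source_pose,
        rotation_applied=(p.rotation_applied + angle) % (2 * math.pi),
        brightness_scale=p.brightness_scale,
    )


def randomize_rotation(p: AlignedParticle, seed: int) -> AlignedParticle:
    """Uniform random in-plane rotation (reproducible per seed)."""
    angle = float(np.random.default_rng(seed).uniform(0.0, 2 * math.pi))
    vol = _rotate_inplane_volume(p.volume, angle)
    return AlignedParticle(
        volume=vol, source_pose=p.source_pose,
        rotation_applied=(p.rotation_applied + angle) % (2 * math.pi),
        brightness_scale=p.brightness_scale,
    )


def average_particles(
    particles, normalize_outliers: bool = False, outlier_factor: float = 3.0
) -> AverageMap:
    """Voxelwise mean of aligned particles.

    With ``normalize_outliers``, a particle whose integrated intensity
    exceeds ``outlier_factor`` times the median of the *other* particles'
    integrals is rescaled to that median before averaging, so one bright
    particle cannot dominate the average.
    """
    particles = list(particles)
    if not particles:
        raise ValueError("need at least one particle")
    shape0 = particles[0].volume.shape
    for q in particles[1:]:
        if q.volume.shape != shape0:
            raise ValueError(
                f"particle shapes differ: {shape0} vs {q.volume.shape}"
            )
    integrals = np.array([float(q.volume.data.sum()) for q in particles])
    scales = np.ones(len(particles))
    if normalize_outliers and len(particles) > 1:
        for i in range(len(particles)):
            others = np.delete(integrals, i)
            med = float(np.median(others))
            if med > 0 and integrals[i] > outlier_factor * med:
                scales[i] = med / integrals[i]
    acc = np.zeros(shape0, dtype=np.float64)
    prov = []
    for i, q in enumerate(particles):
        acc += scales[i] * q.volume.data
        prov.append((i, float(scales[i])))
    acc /= len(particles)
    vol = VolumeImage(acc, particles[0].volume.voxel_size,
                      channel_name=particles[0].volume.channel_name)
    return AverageMap(volume=vol, n=len(particles), provenance=prov)
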