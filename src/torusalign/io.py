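"""Volumes, seeds and configuration I/O.

Conventions (fixed across the package):

* volumes are indexed ``(z, y, x)``, 0-based, voxel-center origin;
* lateral sampling is isotropic (``dy == dx``; rejected otherwise);
* voxel sizes are in nanometres;
* all geometry downstream works in isotropic lateral-pixel units.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class ChannelError(KeyError):
    """Requested channel absent from the channel map."""


@dataclass
class VolumeImage:
    """A single-channel 3D volume with physical voxel metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative finite intensities.
    voxel_size : (dz, dy, dx)
        Voxel edges in nm; ``dy`` must equal ``dx``.
    channel_name : str
    """

    data: np.ndarray
    voxel_size: tuple
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z,y,x), got {self.data.ndim}D")
        dz, dy, dx = (float(v) for v in self.voxel_size)
        if min(dz, dy, dx) <= 0:
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if not np.isclose(dy, dx, rtol=1e-6):
            raise ValueError(
                f"lateral sampling must be isotropic (dy == dx), got dy={dy}, dx={dx}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("volume contains negative values")
        self.voxel_size = (dz, dy, dx)

    @property
    def aspect(self) -> float:
        """z anisotropy dz/dx: one slice equals this many lateral pixels."""
        dz, _, dx = self.voxel_size
        return dz / dx

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def nm_per_px(self) -> float:
        return self.voxel_size[2]


@dataclass
class ParticleSeed:
    """Four clicked (x, y) points at the approximate 0/90/180/270-degree
    ring crossings, plus an optional z hint."""

    particle_id: str
    channel: str
    points: np.ndarray  # shape (4, 2), (x, y) pixel pairs
    z_hint: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (4, 2):
            raise ValueError(
                f"a seed needs exactly four (x, y) points, got {self.points.shape}"
            )

    def validate_bounds(self, volume: VolumeImage) -> None:
        nz, ny, nx = volume.shape
        x, y = self.points[:, 0], self.points[:, 1]
        if np.any(x < 0) or np.any(x > nx - 1) or np.any(y < 0) or np.any(y > ny - 1):
            raise ValueError(
                f"seed {self.particle_id}: points outside image bounds "
                f"({nx}x{ny} laterally)"
            )
        if self.z_hint is not None and not (0 <= self.z_hint <= nz - 1):
            raise ValueError(f"seed {self.particle_id}: z_hint outside stack")


def _parse_ome_voxel_size(ome_xml: str):
    """PhysicalSizeX/Y/Z from OME-XML, converted to nm; None if absent."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    unit_to_nm = {"nm": 1.0, "µm": 1e3, "um": 1e3, "mm": 1e6, None: 1e3}
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            out = []
            for ax in ("Z", "Y", "X"):
                v = el.get(f"PhysicalSize{ax}")
                if v is None:
                    return None
                unit = el.get(f"PhysicalSize{ax}Unit")
                out.append(float(v) * unit_to_nm.get(unit, 1e3))
            return tuple(out)
    return None


def write_stack(volumes, path) -> None:
    """Write channel volumes to one OME-TIFF; lossless roundtrip with
    :func:`read_stack`.  All volumes must share a shape and voxel size."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes to write")
    shape0, vox0 = volumes[0].shape, volumes[0].voxel_size
    for v in volumes[1:]:
        if v.shape != shape0:
            raise ValueError(
                f"all volumes must share a shape; got {shape0} and {v.shape}"
            )
        if v.voxel_size != vox0:
            raise ValueError("all volumes must share a voxel size")
    data = np.stack([v.data for v in volumes], axis=0)  # (C, Z, Y, X)
    dz, dy, dx = vox0
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "nm",
            "PhysicalSizeY": dy, "PhysicalSizeYUnit": "nm",
            "PhysicalSizeX": dx, "PhysicalSizeXUnit": "nm",
            "Channel": {"Name": [v.channel_name or f"ch{i}"
                                 for i, v in enumerate(volumes)]},
        },
    )


def read_stack(path, channel_map, channels=None, voxel_size=None):
    """Read an OME-TIFF/TIFF z-stack into per-channel :class:`VolumeImage`.

    Parameters
    ----------
    path : path-like
    channel_map : dict name -> channel index
    channels : optional list of names to load (defaults to all in the map)
    voxel_size : optional (dz, dy, dx) nm override; required when the file
        carries no physical pixel-size metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta_vox = _parse_ome_voxel_size(tif.ome_metadata) if tif.ome_metadata else None
    if arr.ndim == 3:
        arr = arr[None]  # single channel
    elif arr.ndim != 4:
        raise ValueError(f"expected a (C)ZYX stack, got shape {arr.shape}")
    vox = tuple(float(v) for v in voxel_size) if voxel_size is not None else meta_vox
    if vox is None:
        raise ValueError(
            f"{path}: no voxel-size metadata found and no override given; "
            "pass voxel_size=(dz, dy, dx) in nm"
        )
    wanted = list(channel_map) if channels is None else list(channels)
    out = []
    for name in wanted:
        if name not in channel_map:
            raise ChannelError(
                f"channel {name!r} not in channel map; available: "
                f"{sorted(channel_map)}"
            )
        idx = channel_map[name]
        if not (0 <= idx < arr.shape[0]):
            raise ChannelError(
                f"channel {name!r} maps to index {idx} but the stack has "
                f"{arr.shape[0]} channel(s)"
            )
        out.append(VolumeImage(arr[idx].astype(np.float64), vox, channel_name=name))
    return out


SEED_COLUMNS = ["x0", "y0", "x90", "y90", "x180", "y180", "x270", "y270"]


def read_seeds(path) -> list:
    """Particle seeds from CSV: one row per particle, 8 coordinate columns
    (x/y at the 0/90/180/270-degree crossings) plus optional z_hint."""
    df = pd.read_csv(path)
    missing = [c for c in ["particle_id", "channel", *SEED_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"seed CSV missing columns: {missing}")
    seeds = []
    for _, row in df.iterrows():
        pts = np.array(
            [[row[f"x{a}"], row[f"y{a}"]] for a in (0, 90, 180, 270)], dtype=float
        )
        z_hint = None
        if "z_hint" in df.columns and not pd.isna(row["z_hint"]):
            z_hint = int(row["z_hint"])
        seeds.append(
            ParticleSeed(str(row["particle_id"]), str(row["channel"]), pts, z_hint)
        )
    return seeds


def write_seeds(seeds, path) -> None:
    rows = []
    for s in seeds:
        row = {"particle_id": s.particle_id, "channel": s.channel}
        for (a, (x, y)) in zip((0, 90, 180, 270), s.points):
            row[f"x{a}"], row[f"y{a}"] = x, y
        row["z_hint"] = s.z_hint
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class Config:
    """Analysis configuration (YAML-backed).

    Fields mirror the knobs documented in docs/methods.md; everything has a
    default so an empty file is valid.
    """

    voxel_size: tuple | None = None  # (dz, dy, dx) nm override
    channel_map: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    average: dict = field(default_factory=dict)
    fret: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        vox = raw.get("voxel_size")
        return cls(
            voxel_size=tuple(vox) if vox else None,
            channel_map=raw.get("channel_map", {}),
            fit=raw.get("fit", {}),
            average=raw.get("average", {}),
            fret=raw.get("fret", {}),
        )
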