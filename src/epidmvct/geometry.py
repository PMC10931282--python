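"""Acquisition geometry, image/volume containers and exact cone-beam ray tracing.

World coordinate convention (fixed and used throughout the package):
isocenter at the origin, x = patient left, y = anterior→posterior,
z = superior→inferior.  At gantry 0° the source sits on +y at distance SAD and
the beam travels toward −y; the flat detector is perpendicular to the beam at
distance SID from the source.  Detector in-plane axes are u (the rotated x
axis, increasing with column index) and v (= z, increasing with row index).
Voxel indexing is 0-based; the world position of a voxel center is
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import _kernels

#: default gantry angles: 10 views evenly spaced over [0°, 180°) at 18° steps
DEFAULT_ANGLES = tuple(float(a) for a in range(0, 180, 18))


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Linac + EPID acquisition geometry (distances in mm, angles in degrees)."""

    sad: float = 1000.0
    sid: float = 1540.0
    gantry_angles: tuple = DEFAULT_ANGLES
    detector_rows: int = 1280
    detector_cols: int = 1280
    detector_pitch: float = 0.336
    field_size: tuple = (200.0, 200.0)
    beam: str = "cone"  # "cone" (point source) or "parallel" (oracle tests)

    def __post_init__(self):
        if not (self.sid > self.sad > 0):
            raise ValueError(f"require SID > SAD > 0, got SAD={self.sad}, SID={self.sid}")
        if self.detector_pitch <= 0:
            raise ValueError("detector_pitch must be positive")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise ValueError("detector grid must be at least 1x1")
        for a in self.gantry_angles:
            if not (0.0 <= a < 360.0):
                raise ValueError(f"gantry angle {a} outside [0, 360)")
        if self.beam not in ("cone", "parallel"):
            raise ValueError("beam must be 'cone' or 'parallel'")

    @property
    def magnification(self) -> float:
        """Isocenter-plane → detector-plane scale factor SID/SAD."""
        return self.sid / self.sad

    def source_position(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return self.sad * np.array([np.sin(th), np.cos(th), 0.0])

    def detector_center(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return (self.sad - self.sid) * np.array([np.sin(th), np.cos(th), 0.0])

    def detector_axes(self, angle_deg: float):
        """Unit vectors (u, v) spanning the detector plane at this angle."""
        th = np.deg2rad(angle_deg)
        u = np.array([np.cos(th), -np.sin(th), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return u, v

    def beam_direction(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return -np.array([np.sin(th), np.cos(th), 0.0])


def pixel_uv(rows: int, cols: int, pitch: float, center_uv=(0.0, 0.0)):
    """(u, v) mm coordinates of pixel centers for a detector-plane grid.

    Row index maps to v, column index to u; the grid is centered on
    ``center_uv`` relative to the beam axis."""
    v = (np.arange(rows) - (rows - 1) / 2.0) * pitch + center_uv[1]
    u = (np.arange(cols) - (cols - 1) / 2.0) * pitch + center_uv[0]
    return u, v


def ray_endpoints(geometry: AcquisitionGeometry, angle_deg: float,
                  rows: int, cols: int, pitch: float, center_uv=(0.0, 0.0)):
    """World endpoints (p0, p1) for every pixel of a detector-plane grid.

    Returns arrays of shape (rows*cols, 3) in row-major pixel order.  For the
    cone beam p0 is the point source; for the parallel toggle p0 lies 2·SID
    upstream of each pixel along the beam axis."""
    u_ax, v_ax = geometry.detector_axes(angle_deg)
    center = geometry.detector_center(angle_deg)
    u, v = pixel_uv(rows, cols, pitch, center_uv)
    uu, vv = np.meshgrid(u, v)  # shape (rows, cols)
    pts = (center[None, :]
           + uu.reshape(-1, 1) * u_ax[None, :]
           + vv.reshape(-1, 1) * v_ax[None, :])
    if geometry.beam == "parallel":
        b = geometry.beam_direction(angle_deg)
        p0 = pts - 2.0 * geometry.sid * b[None, :]
    else:
        p0 = np.broadcast_to(geometry.source_position(angle_deg), pts.shape).copy()
    return np.ascontiguousarray(p0), np.ascontiguousarray(pts)


@dataclass
class VolumeImage:
    """3D scalar grid (attenuation, HU-like planning CT, MVCT or dose).

    ``values[ix, iy, iz]``; ``origin`` is the world mm position of the corner
    of voxel (0, 0, 0)."""

    values: np.ndarray
    voxel_size: tuple
    origin: tuple
    modality: str = "attenuation"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VolumeImage requires a 3D array")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def centered(cls, values, voxel_size, modality="attenuation"):
        """Grid whose physical footprint is centered on the isocenter."""
        values = np.asarray(values, dtype=np.float64)
        vs = np.asarray(voxel_size, dtype=float)
        origin = -(np.array(values.shape) * vs) / 2.0
        return cls(values, tuple(vs), tuple(origin), modality)

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def copy(self) -> "VolumeImage":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class CouchShift:
    """Rigid translation (mm) of the phantom/patient relative to the plan."""

    sx: float = 0.0
    sy: float = 0.0
    sz: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite([self.sx, self.sy, self.sz])):
            raise ValueError("couch shift components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.sx, self.sy, self.sz], dtype=float)


@dataclass
class RayPath:
    """Ordered (voxel index, intersection length mm) pairs for one ray."""

    indices: np.ndarray  # (n, 3) int
    lengths: np.ndarray  # (n,) mm

    def __len__(self):
        return len(self.lengths)

    def raysum(self, volume: VolumeImage) -> float:
        if len(self) == 0:
            return 0.0
        i = self.indices
        return float(np.sum(volume.values[i[:, 0], i[:, 1], i[:, 2]] * self.lengths))


def trace_ray(geometry: AcquisitionGeometry, angle_deg: float,
              detector_pixel, volume: VolumeImage,
              pitch: float | None = None, rows: int | None = None,
              cols: int | None = None, center_uv=(0.0, 0.0)) -> RayPath:
    """Exact Siddon path of the ray source → one detector pixel (row, col).

    Pixel grid parameters default to the native detector; a missing volume
    intersection yields an empty (valid) path."""
    pitch = geometry.detector_pitch if pitch is None else pitch
    rows = geometry.detector_rows if rows is None else rows
    cols = geometry.detector_cols if cols is None else cols
    r, c = detector_pixel
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"detector pixel {detector_pixel} outside {rows}x{cols} grid")
    u_ax, v_ax = geometry.detector_axes(angle_deg)
    center = geometry.detector_center(angle_deg)
    u = (c - (cols - 1) / 2.0) * pitch + center_uv[0]
    v = (r - (rows - 1) / 2.0) * pitch + center_uv[1]
    p1 = center + u * u_ax + v * v_ax
    if geometry.beam == "parallel":
        p0 = p1 - 2.0 * geometry.sid * geometry.beam_direction(angle_deg)
    else:
        p0 = geometry.source_position(angle_deg)
    shape = volume.values.shape
    idx_buf = np.empty((_kernels.max_path_len(shape), 3), dtype=np.int64)
    len_buf = np.empty(_kernels.max_path_len(shape), dtype=np.float64)
    n = _kernels.siddon_path(p0[0], p0[1], p0[2], p1[0], p1[1], p1[2],
                             volume.origin[0], volume.origin[1], volume.origin[2],
                             volume.voxel_size[0], volume.voxel_size[1], volume.voxel_size[2],
                             shape[0], shape[1], shape[2], idx_buf, len_buf)
    return RayPath(idx_buf[:n].copy(), len_buf[:n].copy())


def forward_project(volume: VolumeImage, geometry: AcquisitionGeometry,
                    angle_deg: float, rows: int, cols: int, pitch: float,
                    center_uv=(0.0, 0.0)) -> np.ndarray:
    """Line-integral image (rows × cols) of the volume at one gantry angle."""
    p0, p1 = ray_endpoints(geometry, angle_deg, rows, cols, pitch, center_uv)
    out = np.empty(p0.shape[0], dtype=np.float64)
    _kernels.forward_raysums(volume.values, volume.origin[0], volume.origin[1],
                             volume.origin[2], volume.voxel_size[0],
                             volume.voxel_size[1], volume.voxel_size[2],
                             p0, p1, out)
    return out.reshape(rows, cols)


def shift_volume(volume: VolumeImage, shift: CouchShift | Sequence[float]) -> VolumeImage:
    """Rigidly translate the sampled field by ``shift`` mm (trilinear).

    The anatomy moves by +shift in world coordinates: the output at position p
    equals the input at p − shift.  Grid-aligned shifts reduce to exact rolls."""
    if not isinstance(shift, CouchShift):
        shift = CouchShift(*shift)
    t = shift.as_array()
    if np.all(t == 0):
        return volume.copy()
    vox = t / np.asarray(volume.voxel_size)
    shifted = ndimage.shift(volume.values, vox, order=1, mode="constant", cval=0.0,
                            prefilter=False)
    return replace(volume, values=shifted)
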