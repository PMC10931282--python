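"""Digital thorax phantom: voxelized attenuation maps and synthetic planning CT.

A stand-in for a physical thorax quality-assurance phantom: a water-equivalent
body cross-section, two low-attenuation lungs, a high-attenuation spine and
optional lesion spheres.  Attenuation values are linear coefficients in mm⁻¹
at megavoltage energies (water ≈ 0.0049 mm⁻¹ at 6 MV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VolumeImage

MU_WATER = 0.0049  # mm^-1, ~6 MV


@dataclass(frozen=True)
class Insert:
    """One geometric insert painted into the phantom (later inserts overwrite).

    kinds: 'ellipsoid' (size = semi-axes), 'sphere' (size[0] = radius),
    'cylinder' (z axis; size = (radius, radius, half-length)),
    'elliptic_cylinder' (z axis; size = (semi-x, semi-y, half-length)).
    """

    kind: str
    center: tuple
    size: tuple
    mu: float
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "sphere", "cylinder", "elliptic_cylinder"):
            raise ValueError(f"unknown insert kind {self.kind!r}")
        if self.mu < 0:
            raise ValueError("attenuation must be non-negative")

    def mask(self, x, y, z):
        cx, cy, cz = self.center
        if self.kind == "sphere":
            r = self.size[0]
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
        if self.kind == "ellipsoid":
            a, b, c = self.size
            return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
        if self.kind == "cylinder":
            r, _, h = self.size
            return ((x - cx) ** 2 + (y - cy) ** 2 <= r * r) & (np.abs(z - cz) <= h)
        a, b, h = self.size
        return (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0) & (np.abs(z - cz) <= h)

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        if self.kind == "sphere":
            half = np.full(3, self.size[0], dtype=float)
        elif self.kind == "ellipsoid":
            half = np.asarray(self.size, dtype=float)
        else:
            half = np.array([self.size[0], self.size[1], self.size[2]], dtype=float)
        return c - half, c + half


def default_thorax_spec(scale: float = 1.0, lesion: bool = True):
    """Thorax-like insert list; ``scale`` shrinks all dimensions uniformly.

    The object is finite along z (a thorax section), so a reconstruction grid
    long enough in z sees the whole illuminated anatomy — sparse-view ART is
    unstable when measured rays cross matter outside the solved volume."""
    s = float(scale)
    spec = [
        Insert("elliptic_cylinder", (0, 0, 0), (150 * s, 100 * s, 68 * s), 0.0049, "body"),
        Insert("ellipsoid", (-70 * s, -10 * s, 0), (44 * s, 60 * s, 60 * s), 0.0013, "lung_left"),
        Insert("ellipsoid", (70 * s, -10 * s, 0), (44 * s, 60 * s, 60 * s), 0.0013, "lung_right"),
        Insert("cylinder", (0, 60 * s, 0), (16 * s, 16 * s, 68 * s), 0.0085, "spine"),
    ]
    if lesion:
        spec.append(Insert("sphere", (40 * s, 20 * s, 18 * s), (24 * s,), 0.0060, "lesion"))
    return spec


def build_thorax_phantom(grid_shape, voxel_size, spec=None) -> VolumeImage:
    """Voxelize an insert list onto an isocenter-centered grid.

    Each insert paints its attenuation over earlier ones (piecewise-constant,
    sampled at voxel centers); an insert entirely outside the grid is rejected.
    Deterministic given the spec."""
    if spec is None:
        spec = default_thorax_spec()
    shape = tuple(int(n) for n in grid_shape)
    if any(n <= 0 for n in shape):
        raise ValueError("grid_shape must be positive")
    vs = np.asarray(voxel_size, dtype=float)
    vol = VolumeImage.centered(np.zeros(shape), tuple(vs), modality="attenuation")
    lo = np.asarray(vol.origin)
    hi = lo + np.array(shape) * vs
    x = vol.voxel_centers(0)[:, None, None]
    y = vol.voxel_centers(1)[None, :, None]
    z = vol.voxel_centers(2)[None, None, :]
    for ins in spec:
        blo, bhi = ins.bounding_box()
        if np.any(bhi < lo) or np.any(blo > hi):
            raise ValueError(f"insert {ins.name or ins.kind!r} lies outside the grid")
        vol.values[ins.mask(x, y, z)] = ins.mu
    return vol


def planning_ct_from_spec(grid_shape, voxel_size, spec=None,
                          mu_water: float = MU_WATER) -> VolumeImage:
    """Voxelize the phantom on the planning grid in HU-like units
    (1000·(μ/μ_water − 1)), the intensity scale of a kilovoltage planning CT."""
    vol = build_thorax_phantom(grid_shape, voxel_size, spec)
    hu = 1000.0 * (vol.values / mu_water - 1.0)
    return VolumeImage(hu, vol.voxel_size, vol.origin, modality="planning-CT")
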