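"""Back-projection of EPID transmission grayscale to accelerator primary fluence.

The primary fluence at a plane a perpendicular distance d from the source is
recovered from the primary EPID signal by

    ψ_p(t′, r, d) = f · (SID²/d²) · ψ_EPID(t, r) / exp(−a(r)·t′ / (1 + b(r)·t′)),

combining the grayscale→fluence conversion factor f, inverse-square scaling
from the EPID plane back to depth, and an equivalent-thickness attenuation
correction in which a(r) corrects off-axis beam softening and b(r) in-patient
hardening.  t is the water-equivalent path length source→EPID pixel and t′ the
remaining equivalent thickness between the EPID plane and the calculation
point.  a(r) and b(r) are low-order polynomials of the off-axis radius,
calibration quantities of a given linac/EPID pair; the defaults are a
water-like attenuation slope at 6 MV with no off-axis or hardening terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import ndimage

from .geometry import AcquisitionGeometry, VolumeImage, forward_project, pixel_uv
from .phantom import MU_WATER
from .preprocess import EPIDImage


@dataclass
class AttenuationModel:
    """Conversion factor f and attenuation-correction polynomials a(r), b(r).

    ``a_poly``/``b_poly`` are ascending coefficient sequences in the off-axis
    radius r (mm), evaluated at the EPID plane and rescaled by d/SID at depth."""

    f: float = 1.0
    a_poly: tuple = (0.005,)   # mm^-1, water-like at 6 MV
    b_poly: tuple = (0.0,)

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("conversion factor f must be positive")

    def a(self, r):
        return npoly.polyval(np.asarray(r, dtype=float), self.a_poly)

    def b(self, r):
        return npoly.polyval(np.asarray(r, dtype=float), self.b_poly)


@dataclass
class FluenceMap:
    """Primary fluence on a regular grid at a stated source distance d (mm)."""

    values: np.ndarray
    pixel_pitch: float
    distance: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FluenceMap requires a 2D array")
        if self.pixel_pitch <= 0 or self.distance <= 0:
            raise ValueError("pixel_pitch and distance must be positive")
        if np.any(self.values < 0):
            raise ValueError("fluence values must be non-negative")


@dataclass
class EquivalentThicknessMap:
    """Per-ray water-equivalent path lengths (mm) on a detector-plane grid.

    ``t`` runs source→EPID pixel; ``t_prime`` EPID plane→calculation point at
    the stated perpendicular source distance d."""

    t: np.ndarray
    t_prime: np.ndarray
    pixel_pitch: float
    point_distance: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.t_prime = np.asarray(self.t_prime, dtype=np.float64)
        if np.any(self.t < -1e-9) or np.any(self.t_prime < -1e-9):
            raise ValueError("equivalent thicknesses must be non-negative")


def _to_water_density(volume: VolumeImage, mu_water: float):
    """Relative-water density grid from attenuation (μ/μ_water) or HU-like
    planning-CT values (HU/1000 + 1)."""
    if volume.modality == "planning-CT":
        dens = volume.values / 1000.0 + 1.0
    else:
        dens = volume.values / mu_water
    return np.clip(dens, 0.0, None)


def compute_equivalent_thickness(ct_volume: VolumeImage,
                                 geometry: AcquisitionGeometry,
                                 angle_deg: float,
                                 rows: int | None = None,
                                 cols: int | None = None,
                                 pitch: float | None = None,
                                 point_distance: float | None = None,
                                 mu_water: float = MU_WATER
                                 ) -> EquivalentThicknessMap:
    """Water-equivalent raysums source→EPID (t) and EPID→point plane (t′).

    The calculation point of each ray lies where the ray crosses the plane
    perpendicular to the beam axis at source distance ``point_distance``
    (default: the isocenter plane at SAD).  A point beyond the EPID plane is
    rejected."""
    rows = geometry.detector_rows if rows is None else rows
    cols = geometry.detector_cols if cols is None else cols
    pitch = geometry.detector_pitch if pitch is None else pitch
    d = geometry.sad if point_distance is None else float(point_distance)
    if not (0 < d <= geometry.sid):
        raise ValueError(f"point distance {d} outside (0, SID={geometry.sid}]")
    dens = VolumeImage(_to_water_density(ct_volume, mu_water),
                       ct_volume.voxel_size, ct_volume.origin)
    t = forward_project(dens, geometry, angle_deg, rows, cols, pitch)
    if geometry.beam == "cone":
        # scale the detector grid onto the plane at distance d and integrate
        # source→point; t' is the remainder of the full path
        from .geometry import ray_endpoints
        from . import _kernels
        p0, p1 = ray_endpoints(geometry, angle_deg, rows, cols, pitch)
        frac = d / geometry.sid
        pts = p0 + (p1 - p0) * frac
        part = np.empty(p0.shape[0])
        _kernels.forward_raysums(dens.values, dens.origin[0], dens.origin[1],
                                 dens.origin[2], dens.voxel_size[0],
                                 dens.voxel_size[1], dens.voxel_size[2],
                                 np.ascontiguousarray(p0),
                                 np.ascontiguousarray(pts), part)
        t_point = part.reshape(rows, cols)
    else:
        t_point = np.zeros_like(t)
    t_prime = np.clip(t - t_point, 0.0, None)
    return EquivalentThicknessMap(t, t_prime, pitch, d)


def attenuation_correction(model: AttenuationModel, t_prime: np.ndarray,
                           r: np.ndarray) -> np.ndarray:
    """exp(−a(r)·t′ / (1 + b(r)·t′)); invalid where 1 + b(r)·t′ ≤ 0."""
    a = model.a(r)
    b = model.b(r)
    denom = 1.0 + b * t_prime
    if np.any(denom <= 0):
        raise ValueError("attenuation model invalid for this thickness: "
                         "1 + b(r)·t' <= 0 somewhere in the field")
    return np.exp(-a * t_prime / denom)


def _offaxis_radius(rows, cols, pitch, scale=1.0):
    u, v = pixel_uv(rows, cols, pitch)
    uu, vv = np.meshgrid(u, v)
    return np.hypot(uu, vv) * scale


def invert_primary_fluence(epid_primary: EPIDImage,
                           thickness: EquivalentThicknessMap,
                           model: AttenuationModel,
                           geometry: AcquisitionGeometry,
                           d: float | None = None) -> FluenceMap:
    """Primary fluence at source distance d from the primary EPID signal."""
    d = thickness.point_distance if d is None else float(d)
    if not (0 < d <= geometry.sid):
        raise ValueError(f"distance d={d} outside (0, SID={geometry.sid}]")
    rows, cols = epid_primary.values.shape
    if thickness.t_prime.shape != (rows, cols):
        raise ValueError("thickness map shape does not match the EPID image")
    r = _offaxis_radius(rows, cols, epid_primary.pixel_pitch, scale=d / geometry.sid)
    corr = attenuation_correction(model, thickness.t_prime, r)
    sid = geometry.sid
    vals = model.f * (sid * sid) / (d * d) * epid_primary.values / corr
    return FluenceMap(vals, epid_primary.pixel_pitch * d / sid, d)


def forward_primary_epid(fluence: FluenceMap, thickness: EquivalentThicknessMap,
                         model: AttenuationModel, geometry: AcquisitionGeometry
                         ) -> EPIDImage:
    """Synthesize the primary EPID signal a given primary fluence would leave —
    the exact algebraic inverse of :func:`invert_primary_fluence`."""
    d = fluence.distance
    rows, cols = fluence.values.shape
    epid_pitch = fluence.pixel_pitch * geometry.sid / d
    r = _offaxis_radius(rows, cols, epid_pitch, scale=d / geometry.sid)
    corr = attenuation_correction(model, thickness.t_prime, r)
    sid = geometry.sid
    vals = fluence.values * (d * d) / (sid * sid) / model.f * corr
    return EPIDImage(vals, epid_pitch)


def calibrate_conversion(open_field: EPIDImage, known_output: FluenceMap):
    """Least-squares scalar f minimizing ‖f·open − known‖²; returns (f, residual)."""
    x = open_field.values.ravel()
    y = known_output.values.ravel()
    if x.shape != y.shape:
        raise ValueError("open-field image and fluence map footprints differ")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("open-field image is identically zero")
    f = float(np.dot(x, y)) / denom
    residual = float(np.linalg.norm(f * x - y))
    return f, residual


def scatter_correct(epid_transmission: EPIDImage, kernel_spec=None) -> EPIDImage:
    """Remove an estimated scatter component from a transmission image.

    ``kernel_spec`` is None (identity) or ``("gaussian", amplitude, width_px)``:
    the correction subtracts amplitude × (image ⊛ Gaussian(width)), clamped at
    zero.  A full scatter kernel is a per-machine calibration; this hook only
    fixes the interface."""
    if kernel_spec is None:
        return EPIDImage(epid_transmission.values.copy(),
                         epid_transmission.pixel_pitch,
                         epid_transmission.gantry_angle)
    kind, amplitude, width = kernel_spec
    if kind != "gaussian":
        raise ValueError(f"unknown scatter kernel {kind!r}")
    if amplitude == 0:
        return EPIDImage(epid_transmission.values.copy(),
                         epid_transmission.pixel_pitch,
                         epid_transmission.gantry_angle)
    scatter = amplitude * ndimage.gaussian_filter(epid_transmission.values, width)
    corrected = epid_transmission.values - scatter
    if corrected.sum() < 0:
        raise ValueError("scatter amplitude removes more than the total signal")
    return EPIDImage(np.clip(corrected, 0.0, None),
                     epid_transmission.pixel_pitch,
                     epid_transmission.gantry_angle)
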