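"""EPID → projection conversion and the down-sampling/cropping chain.

The chain converts an open-field/transmission pair to log line integrals
P = ln(I0/I), resamples the native-pitch grid to 1 mm by bilinear
interpolation, crops the unexposed border, fixes a 300 mm square box around
the beam axis and resamples to 3 mm — ending, with the default geometry, at a
100×100 projection.  The physical footprint center is tracked through every
stage so reconstruction rays stay anchored to the detector plane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage


@dataclass
class EPIDImage:
    """2D non-negative detector-plane grayscale grid."""

    values: np.ndarray
    pixel_pitch: float
    gantry_angle: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("EPIDImage requires a 2D array")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if np.any(self.values < 0):
            raise ValueError("EPID grayscale values must be non-negative")


@dataclass
class ProjectionImage:
    """2D grid of line-integral values with detector-plane bookkeeping.

    ``center_uv`` is the (u, v) mm position of the grid's physical center
    relative to the beam axis; ``crop_offset`` the (row, col) origin of this
    grid inside its pre-crop parent."""

    values: np.ndarray
    pixel_pitch: float
    gantry_angle: float = 0.0
    center_uv: tuple = (0.0, 0.0)
    crop_offset: tuple = (0, 0)
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ProjectionImage requires a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self):
        return self.values.shape


def to_projection(open_image: EPIDImage, transmission: EPIDImage,
                  floor: float | None = None) -> ProjectionImage:
    """Elementwise log-projection P = ln(max(I0, floor)/max(I, floor)).

    ``floor`` (default 1e−6·max(I0)) guards the logarithm where pixels are
    unexposed; negative values (noise pushing I above I0) are clamped to 0."""
    if open_image.values.shape != transmission.values.shape:
        raise ValueError(
            f"shape mismatch: open {open_image.values.shape} vs "
            f"transmission {transmission.values.shape}")
    if open_image.pixel_pitch != transmission.pixel_pitch:
        raise ValueError("pixel pitch mismatch between open and transmission images")
    if open_image.gantry_angle != transmission.gantry_angle:
        raise ValueError("gantry angle mismatch between open and transmission images")
    if floor is None:
        peak = float(open_image.values.max())
        floor = 1e-6 * peak if peak > 0 else 1e-6
    if floor <= 0:
        raise ValueError("floor must be positive")
    i0 = np.maximum(open_image.values, floor)
    i = np.maximum(transmission.values, floor)
    p = np.log(i0 / i)
    np.maximum(p, 0.0, out=p)
    return ProjectionImage(p, open_image.pixel_pitch, open_image.gantry_angle,
                           valid_mask=open_image.values > floor)


def resample_bilinear(image, target_pitch: float):
    """Resample an EPIDImage/ProjectionImage to a new pitch (bilinear).

    The output grid has round(n·pitch/target_pitch) pixels per side and shares
    the input's physical center (pixel-center alignment), so the world
    footprint — and any registration anchored to it — is preserved."""
    if target_pitch <= 0:
        raise ValueError("target_pitch must be positive")
    vals = image.values
    out_shape = tuple(int(round(n * image.pixel_pitch / target_pitch)) for n in vals.shape)
    if out_shape[0] < 2 or out_shape[1] < 2:
        raise ValueError(
            f"target pitch {target_pitch} mm too coarse: output grid {out_shape}")
    coords = []
    for ax, m in enumerate(out_shape):
        n = vals.shape[ax]
        # output pixel centers expressed in input pixel-index units
        c = ((np.arange(m) - (m - 1) / 2.0) * target_pitch / image.pixel_pitch
             + (n - 1) / 2.0)
        coords.append(c)
    rr, cc = np.meshgrid(coords[0], coords[1], indexing="ij")
    out = ndimage.map_coordinates(vals, [rr, cc], order=1, mode="nearest")
    if isinstance(image, ProjectionImage):
        mask = None
        if image.valid_mask is not None:
            m = ndimage.map_coordinates(image.valid_mask.astype(np.float64),
                                        [rr, cc], order=1, mode="nearest")
            mask = m > 0.5
        return replace(image, values=out, pixel_pitch=float(target_pitch),
                       valid_mask=mask)
    return EPIDImage(out, float(target_pitch), image.gantry_angle)


def crop_invalid(projection: ProjectionImage, zero_tol: float = 0.0,
                 mask: np.ndarray | None = None) -> ProjectionImage:
    """Remove maximal border rows/columns that carry no exposed pixel.

    Validity comes from the projection's open-field mask when available
    (``valid_mask``), else from values > zero_tol; the crop offset is recorded
    for geometry bookkeeping."""
    if mask is None:
        mask = projection.valid_mask
    if mask is None:
        mask = projection.values > zero_tol
    if mask.shape != projection.values.shape:
        raise ValueError("mask shape does not match projection")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        raise ValueError("projection is fully invalid; nothing to crop to")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    n, m = projection.values.shape
    pitch = projection.pixel_pitch
    du = ((c0 + c1 - 1) / 2.0 - (m - 1) / 2.0) * pitch
    dv = ((r0 + r1 - 1) / 2.0 - (n - 1) / 2.0) * pitch
    return replace(projection,
                   values=projection.values[r0:r1, c0:c1].copy(),
                   center_uv=(projection.center_uv[0] + du,
                              projection.center_uv[1] + dv),
                   crop_offset=(r0, c0),
                   valid_mask=mask[r0:r1, c0:c1].copy())


def center_crop_pad(projection: ProjectionImage, box_mm: float) -> ProjectionImage:
    """Symmetric crop or zero-pad to a square box of ``box_mm`` per side.

    The tracked physical center moves only by the sub-pixel asymmetry of an
    odd crop/pad split; axis 0 (rows) maps to v, axis 1 (cols) to u."""
    target = int(round(box_mm / projection.pixel_pitch))
    if target < 1:
        raise ValueError("box smaller than one pixel")
    pitch = projection.pixel_pitch
    out = projection.values
    mask = projection.valid_mask
    center = list(projection.center_uv)  # (u, v)
    for ax in range(2):
        n = out.shape[ax]
        if n == target:
            continue
        if n > target:
            start = (n - target) // 2
            sl = [slice(None), slice(None)]
            sl[ax] = slice(start, start + target)
            out = out[tuple(sl)]
            if mask is not None:
                mask = mask[tuple(sl)]
            # new index j maps to old index j + start
            delta = (start + (target - 1) / 2.0 - (n - 1) / 2.0) * pitch
        else:
            before = (target - n) // 2
            pad = [(0, 0), (0, 0)]
            pad[ax] = (before, target - n - before)
            out = np.pad(out, pad)
            if mask is not None:
                mask = np.pad(mask, pad)
            # new index j maps to old index j - before
            delta = ((target - 1) / 2.0 - before - (n - 1) / 2.0) * pitch
        center[1 if ax == 0 else 0] += delta
    return replace(projection, values=np.ascontiguousarray(out),
                   center_uv=tuple(center),
                   valid_mask=None if mask is None else np.ascontiguousarray(mask))


def preprocess_chain(open_image: EPIDImage, transmission: EPIDImage,
                     mid_pitch: float = 1.0, final_pitch: float = 3.0,
                     box_mm: float = 300.0, floor: float | None = None
                     ) -> ProjectionImage:
    """Full projection preprocessing: log conversion → 1 mm bilinear resample →
    border crop → fixed 300 mm box → 3 mm resample (final 100×100 grid with
    the default geometry)."""
    p = to_projection(open_image, transmission, floor=floor)
    p = resample_bilinear(p, mid_pitch)
    p = crop_invalid(p)
    p = center_crop_pad(p, box_mm)
    p = resample_bilinear(p, final_pitch)
    return p
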