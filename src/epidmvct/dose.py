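"""Pencil-beam dose from primary fluence, and imaging+treatment accumulation.

Dose at depth d is a three-component convolution model

    D′(x, y, d) = Σ_{j=1..3} D′_j(d) · [Ψ_p ⊛ W_j](x, y),

with j = 1 the primary deposition (near-delta lateral kernel), j = 2
small-scale scatter and j = 3 large-scale scatter.  D′_j carries the depth
dependence and the component weight; each lateral kernel W_j is normalized to
unit sum so the components partition the energy.  Dose is reported in model
units (no absolute Gy calibration); depth is measured along the central beam
axis in the registration-corrected CT frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .fluence import FluenceMap
from .geometry import VolumeImage


def _gaussian_kernel(sigma_px: float, radius_px: int) -> np.ndarray:
    ax = np.arange(-radius_px, radius_px + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma_px * sigma_px))
    return k / k.sum()


@dataclass
class PencilBeamModel:
    """Depth curves and lateral kernels of the three deposition components.

    ``depth_grid`` (mm) samples each D′_j; ``kernel_sigmas`` are lateral
    spreads in mm (0 = discrete delta) and must increase from primary to
    large-scale scatter."""

    depth_grid: np.ndarray
    depth_dose: np.ndarray      # (3, n_depth), >= 0
    kernel_sigmas: tuple = (0.0, 3.0, 20.0)

    def __post_init__(self):
        self.depth_grid = np.asarray(self.depth_grid, dtype=np.float64)
        self.depth_dose = np.asarray(self.depth_dose, dtype=np.float64)
        if self.depth_dose.shape != (3, self.depth_grid.size):
            raise ValueError("depth_dose must be (3, len(depth_grid))")
        if np.any(self.depth_dose < 0):
            raise ValueError("depth-dose curves must be non-negative")
        if not (self.kernel_sigmas[0] < self.kernel_sigmas[1] < self.kernel_sigmas[2]):
            raise ValueError("kernel widths must strictly increase j = 1 → 3")

    @classmethod
    def default(cls, max_depth: float = 400.0):
        """Exponential depth curves c_j·exp(−μ_j d), weights (0.8, 0.15, 0.05),
        attenuation slopes (0.005, 0.004, 0.003) mm⁻¹ — a generic megavoltage
        parameterization; real kernels are per-machine calibrations."""
        d = np.arange(0.0, max_depth + 1.0, 1.0)
        c = np.array([0.8, 0.15, 0.05])
        mu = np.array([0.005, 0.004, 0.003])
        curves = c[:, None] * np.exp(-mu[:, None] * d[None, :])
        return cls(d, curves)

    def kernels(self, pitch_mm: float):
        out = []
        for s in self.kernel_sigmas:
            if s <= 0:
                out.append(np.ones((1, 1)))
            else:
                sigma_px = s / pitch_mm
                out.append(_gaussian_kernel(sigma_px, max(1, int(np.ceil(3 * sigma_px)))))
        return out

    def depth_factors(self, depths) -> np.ndarray:
        depths = np.asarray(depths, dtype=float)
        lo, hi = self.depth_grid[0], self.depth_grid[-1]
        if np.any(depths < lo) or np.any(depths > hi):
            raise ValueError(f"depth outside model range [{lo}, {hi}] mm")
        return np.vstack([np.interp(depths, self.depth_grid, self.depth_dose[j])
                          for j in range(3)])


@dataclass
class DoseGrid:
    """3D dose grid (x, y, depth) with provenance bookkeeping."""

    values: np.ndarray
    pixel_pitch: float
    depths: np.ndarray
    provenance: str = "treatment"   # imaging | treatment | total
    contributions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != self.depths.size:
            raise ValueError("dose grid must be (nx, ny, n_depth)")
        if np.any(self.values < 0):
            raise ValueError("dose must be non-negative")

    def central_axis(self) -> np.ndarray:
        nx, ny, _ = self.values.shape
        return self.values[nx // 2, ny // 2, :]


def pencil_beam_dose(fluence: FluenceMap, model: PencilBeamModel,
                     depth_grid, provenance: str = "treatment") -> DoseGrid:
    """Evaluate the three-component convolution at each requested depth.

    Convolutions are zero-padded ('same' size); dose is linear in fluence."""
    depths = np.asarray(depth_grid, dtype=float)
    factors = model.depth_factors(depths)        # (3, nd)
    kernels = model.kernels(fluence.pixel_pitch)
    comps = [fftconvolve(fluence.values, k, mode="same") for k in kernels]
    nd = depths.size
    out = np.zeros(fluence.values.shape + (nd,))
    for j in range(3):
        out += comps[j][:, :, None] * factors[j][None, None, :]
    np.clip(out, 0.0, None, out=out)   # fft roundoff can leave -1e-17
    return DoseGrid(out, fluence.pixel_pitch, depths, provenance)


def apply_registration_correction(planning_ct: VolumeImage, shift_mm) -> VolumeImage:
    """Translate the planning CT to the registered patient pose.

    The corrected CT at position p equals the planning CT at p − t, i.e. the
    anatomy is moved by the recovered couch shift t; integer-voxel shifts are
    exact index rolls, sub-voxel shifts trilinear."""
    t = np.asarray(shift_mm, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("shift must be finite")
    if np.all(t == 0):
        return planning_ct.copy()
    vox = t / np.asarray(planning_ct.voxel_size)
    vals = ndimage.shift(planning_ct.values, vox, order=1, mode="nearest",
                         prefilter=False)
    return VolumeImage(vals, planning_ct.voxel_size, planning_ct.origin,
                       planning_ct.modality)


def accumulate_total_dose(imaging_fields, treatment_fields) -> DoseGrid:
    """Elementwise sum of per-field dose grids with provenance bookkeeping.

    Returns a 'total' grid whose ``contributions`` record the imaging and
    treatment sums and the imaging fraction of the total central-axis dose."""
    fields = list(imaging_fields) + list(treatment_fields)
    if not fields:
        raise ValueError("no dose fields to accumulate")
    ref = fields[0]
    for f in fields[1:]:
        if (f.values.shape != ref.values.shape
                or f.pixel_pitch != ref.pixel_pitch
                or not np.array_equal(f.depths, ref.depths)):
            raise ValueError("dose grids are not aligned")
    img = np.zeros_like(ref.values)
    for f in imaging_fields:
        img += f.values
    trt = np.zeros_like(ref.values)
    for f in treatment_fields:
        trt += f.values
    total = img + trt
    cax_total = total[total.shape[0] // 2, total.shape[1] // 2, :].sum()
    cax_img = img[img.shape[0] // 2, img.shape[1] // 2, :].sum()
    contributions = {
        "imaging": float(img.sum()),
        "treatment": float(trt.sum()),
        "imaging_fraction_central_axis": float(cax_img / cax_total) if cax_total > 0 else 0.0,
    }
    return DoseGrid(total, ref.pixel_pitch, ref.depths.copy(), "total", contributions)
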