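"""Synthetic EPID open-field / transmission image pairs.

The forward model is Beer–Lambert attenuation of a collimated cone beam:
open = I0 inside the projected field aperture, transmission = open·exp(−raysum)
with the raysum the exact line integral through the (optionally couch-shifted)
phantom.  Optional Poisson noise draws each pixel with the noiseless value as
its mean.  The EPID response itself is taken as flat (no horns/glare model):
only the open/transmission ratio enters the projection conversion.
"""

from __future__ import annotations

import numpy as np

from .geometry import (AcquisitionGeometry, CouchShift, VolumeImage,
                       forward_project, pixel_uv, shift_volume)
from .preprocess import EPIDImage


def field_aperture_mask(geometry: AcquisitionGeometry, rows=None, cols=None,
                        pitch=None, center_uv=(0.0, 0.0)) -> np.ndarray:
    """Boolean detector mask of the field aperture projected to the EPID plane."""
    rows = geometry.detector_rows if rows is None else rows
    cols = geometry.detector_cols if cols is None else cols
    pitch = geometry.detector_pitch if pitch is None else pitch
    mag = geometry.magnification if geometry.beam == "cone" else 1.0
    half_u = geometry.field_size[0] / 2.0 * mag
    half_v = geometry.field_size[1] / 2.0 * mag
    u, v = pixel_uv(rows, cols, pitch, center_uv)
    uu, vv = np.meshgrid(u, v)
    return (np.abs(uu) <= half_u) & (np.abs(vv) <= half_v)


def simulate_epid_pair(geometry: AcquisitionGeometry, angle_deg: float,
                       phantom: VolumeImage, shift: CouchShift | None = None,
                       i0_level: float = 1000.0, noise: str = "off",
                       seed: int | None = None, rows=None, cols=None,
                       pitch=None):
    """Simulate one (open-field, transmission) EPID pair at a gantry angle.

    Returns two :class:`EPIDImage` on the native detector grid (or an override
    grid).  ``noise='poisson'`` draws both images pixelwise with ``seed``."""
    if i0_level <= 0:
        raise ValueError("i0_level must be positive")
    if noise not in ("off", "poisson"):
        raise ValueError("noise must be 'off' or 'poisson'")
    rows = geometry.detector_rows if rows is None else rows
    cols = geometry.detector_cols if cols is None else cols
    pitch = geometry.detector_pitch if pitch is None else pitch
    vol = phantom if shift is None else shift_volume(phantom, shift)
    raysum = forward_project(vol, geometry, angle_deg, rows, cols, pitch)
    mask = field_aperture_mask(geometry, rows, cols, pitch)
    open_img = np.where(mask, float(i0_level), 0.0)
    trans_img = open_img * np.exp(-raysum)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        open_img = rng.poisson(open_img).astype(np.float64)
        trans_img = rng.poisson(trans_img).astype(np.float64)
    return (EPIDImage(open_img, pitch, angle_deg),
            EPIDImage(trans_img, pitch, angle_deg))
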