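"""Global gamma-index comparison of 2D fluence/dose maps.

For each reference pixel above the low-signal threshold,

    γ = min over evaluated positions p of √( (Δr/dta)² + (ΔD/(dd·D_norm))² ),

with dd the dose tolerance as a fraction of the global normalization (the
reference maximum), dta the distance-to-agreement, and the minimum searched
over a disc of radius 3·dta with sub-pixel bilinear sampling.  γ ≤ 1 counts
as agreement; the passing rate is the percentage of evaluated pixels passing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fluence import FluenceMap


@dataclass
class GammaCriteria:
    dose_tol: float = 3.0        # % of normalization
    dta: float = 2.0             # mm
    low_threshold: float = 10.0  # % of normalization
    normalization: str = "global"  # "global" (ref max) or "local" (per pixel)
    search_step: float = 0.2     # mm sub-sampling of the search disc
    search_factor: float = 3.0   # search radius = factor × dta

    def __post_init__(self):
        if self.dose_tol <= 0 or self.dta <= 0 or self.low_threshold <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")


@dataclass
class GammaMap:
    gamma: np.ndarray            # NaN outside the evaluated mask
    mask: np.ndarray
    criteria: GammaCriteria

    @property
    def passing_rate(self) -> float:
        return passing_rate(self)


def global_gamma(reference: FluenceMap, evaluated: FluenceMap,
                 criteria: GammaCriteria | None = None) -> GammaMap:
    """Gamma map of ``evaluated`` against ``reference`` (same pitch required).

    Boundary pixels use only in-map samples of the evaluated distribution."""
    if criteria is None:
        criteria = GammaCriteria()
    if reference.pixel_pitch != evaluated.pixel_pitch:
        raise ValueError(
            f"pitch mismatch: reference {reference.pixel_pitch} mm vs "
            f"evaluated {evaluated.pixel_pitch} mm")
    ref = reference.values
    ev = evaluated.values
    if ref.shape != ev.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {ev.shape}")
    pitch = reference.pixel_pitch
    norm = float(ref.max())
    if norm <= 0:
        raise ValueError("reference map has no signal")
    mask = ref >= criteria.low_threshold / 100.0 * norm
    if criteria.normalization == "global":
        dose_scale = criteria.dose_tol / 100.0 * norm
        dose_den = np.full(ref.shape, dose_scale)
    else:
        dose_den = criteria.dose_tol / 100.0 * np.maximum(ref, 1e-12 * norm)

    # search disc: capped at the map extent (farther offsets are out of map
    # for every pixel); visited in order of growing radius so the scan can
    # stop exactly once the distance term alone exceeds every pixel's current
    # best gamma — no candidate farther out can improve any minimum.
    radius = min(criteria.search_factor * criteria.dta,
                 pitch * float(np.hypot(ref.shape[0] - 1, ref.shape[1] - 1)))
    step = criteria.search_step
    n = int(np.floor(radius / step))
    offs = np.arange(-n, n + 1) * step
    du_g, dv_g = np.meshgrid(offs, offs)
    r2_g = du_g ** 2 + dv_g ** 2
    keep = r2_g <= radius * radius
    order = np.argsort(r2_g[keep], kind="stable")
    du_list = du_g[keep][order]
    dv_list = dv_g[keep][order]
    r2_list = r2_g[keep][order]
    rr, cc = np.meshgrid(np.arange(ref.shape[0], dtype=float),
                         np.arange(ref.shape[1], dtype=float), indexing="ij")
    gamma_sq = np.full(ref.shape, np.inf)
    dta_sq = criteria.dta * criteria.dta
    for du, dv, r2 in zip(du_list, dv_list, r2_list):
        if r2 / dta_sq > np.max(gamma_sq[mask], initial=0.0) and np.isfinite(
                gamma_sq[mask]).all():
            break
        coords = [rr + dv / pitch, cc + du / pitch]
        inside = ((coords[0] >= 0) & (coords[0] <= ref.shape[0] - 1)
                  & (coords[1] >= 0) & (coords[1] <= ref.shape[1] - 1))
        sample = ndimage.map_coordinates(ev, coords, order=1, mode="nearest")
        dd = (sample - ref) / dose_den
        cand = r2 / dta_sq + dd * dd
        cand = np.where(inside, cand, np.inf)
        np.minimum(gamma_sq, cand, out=gamma_sq)
    gamma = np.sqrt(gamma_sq)
    gamma[~mask] = np.nan
    return GammaMap(gamma, mask, criteria)


def passing_rate(gamma_map: GammaMap) -> float:
    """Percentage of evaluated pixels with γ ≤ 1 (boundary counts as a pass)."""
    vals = gamma_map.gamma[gamma_map.mask]
    if vals.size == 0:
        raise ValueError("all pixels below threshold: empty evaluated mask")
    return 100.0 * float(np.mean(vals <= 1.0 + 1e-9))
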