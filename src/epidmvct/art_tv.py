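"""Sparse-view MVCT reconstruction: ray-by-ray ART with TV gradient descent.

The solver interleaves relaxed Kaczmarz projections onto each ray's
measurement hyperplane with a non-negativity projection and an adaptive
total-variation descent step

    x_TV = x_pos − μ · d · v / ‖v‖₂,

where d = ‖Δx‖₂ is the norm of the ART-induced change since the previous TV
step and v the gradient of the ε-smoothed TV functional.  TV is evaluated
slice-by-slice in the axial plane (the functional is two-dimensional and the slice
spacing is anisotropic).  The TV cadence is configurable: ``per_ray`` follows the
written algorithm literally, ``per_view`` (default) applies the step after
each projection's sweep, ``per_iteration`` once per full iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import AcquisitionGeometry, RayPath, VolumeImage, ray_endpoints
from .preprocess import ProjectionImage


@dataclass
class ReconstructionConfig:
    max_iterations: int = 12
    relaxation: float = 0.1
    tv_weight: float = 1.0
    epsilon: float = 1e-8
    stop_tol: float = 1e-6  # relative to ‖x‖₂
    grid_shape: tuple = (128, 128, 122)
    voxel_size: tuple = (2.0, 2.0, 3.0)
    tv_cadence: str = "per_view"

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.relaxation < 2):
            raise ValueError("relaxation must lie in (0, 2)")
        if self.tv_weight < 0:
            raise ValueError("tv_weight must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.tv_cadence not in ("per_ray", "per_view", "per_iteration"):
            raise ValueError("tv_cadence must be per_ray, per_view or per_iteration")


def nonneg_project(x: np.ndarray) -> np.ndarray:
    """Elementwise projection onto the non-negative orthant."""
    return np.maximum(x, 0.0)


def art_update_ray(x: np.ndarray, ray: RayPath, p_i: float, lam: float) -> np.ndarray:
    """One relaxed Kaczmarz update x ← x + λ(p_i − wᵀx)/‖w‖²·w on the voxels of
    one ray; zero-norm (empty) rays are no-ops.  Returns a new array."""
    if lam <= 0:
        raise ValueError("relaxation must be positive")
    out = x.copy()
    if len(ray) == 0:
        return out
    i = ray.indices
    w = ray.lengths
    w2 = float(np.dot(w, w))
    if w2 == 0.0:
        return out
    s = float(np.sum(out[i[:, 0], i[:, 1], i[:, 2]] * w))
    out[i[:, 0], i[:, 1], i[:, 2]] += lam * (p_i - s) / w2 * w
    return out


def _slice_diffs(x: np.ndarray):
    """Forward differences over the valid index set (i≥1, j≥1) of each axial
    slice; works for a 2D slice or a 3D volume batched over the last axis."""
    d0 = x[1:, 1:] - x[:-1, 1:]
    d1 = x[1:, 1:] - x[1:, :-1]
    return d0, d1


def tv_norm(x: np.ndarray, eps: float = 0.0) -> float:
    """Isotropic TV: Σ √((x[i,j]−x[i−1,j])² + (x[i,j]−x[i,j−1])² + eps)
    over valid interior indices, summed over axial slices for a volume."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim not in (2, 3):
        raise ValueError("tv_norm expects a 2D slice or a 3D volume")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("grid must be at least 2x2 in the slice plane")
    d0, d1 = _slice_diffs(x)
    return float(np.sum(np.sqrt(d0 * d0 + d1 * d1 + eps)))


def tv_gradient(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Exact gradient of the ε-smoothed TV functional, per axial slice.

    Each valid-index term √(d0²+d1²+ε) contributes to the three pixels it
    touches; boundary pixels simply lack the dropped out-of-grid terms."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim not in (2, 3):
        raise ValueError("tv_gradient expects a 2D slice or a 3D volume")
    d0, d1 = _slice_diffs(x)
    denom = np.sqrt(d0 * d0 + d1 * d1 + eps)
    g = np.zeros_like(x)
    g[1:, 1:] += (d0 + d1) / denom
    g[:-1, 1:] -= d0 / denom
    g[1:, :-1] -= d1 / denom
    return g


def _tv_step(x: np.ndarray, mu: float, d: float, eps: float) -> np.ndarray:
    """x_TV = x_pos − μ·d·v/‖v‖₂ followed by the non-negativity projection."""
    if mu == 0.0 or d == 0.0:
        return x
    v = tv_gradient(x, eps)
    nv = float(np.linalg.norm(v))
    if nv == 0.0:
        return x
    return nonneg_project(x - mu * d / nv * v)


def build_ray_set(projections, geometry: AcquisitionGeometry):
    """Stack ray endpoints and measured values for all projections, in sweep
    order: projection-major (given order), row-major within a projection."""
    p0_list, p1_list, val_list = [], [], []
    for proj in projections:
        rows, cols = proj.values.shape
        p0, p1 = ray_endpoints(geometry, proj.gantry_angle, rows, cols,
                               proj.pixel_pitch, proj.center_uv)
        p0_list.append(p0)
        p1_list.append(p1)
        val_list.append(proj.values.reshape(-1))
    return p0_list, p1_list, val_list


def support_mask(projections, geometry: AcquisitionGeometry,
                 grid_shape, voxel_size) -> np.ndarray:
    """Voxels crossed by at least one measured ray (reconstruction support)."""
    vol = VolumeImage.centered(np.zeros(grid_shape), voxel_size)
    mask = np.zeros(grid_shape, dtype=bool)
    p0s, p1s, _ = build_ray_set(projections, geometry)
    for p0, p1 in zip(p0s, p1s):
        _kernels.mark_support(mask, vol.origin[0], vol.origin[1], vol.origin[2],
                              vol.voxel_size[0], vol.voxel_size[1],
                              vol.voxel_size[2], p0, p1)
    return mask


def reconstruct(projections, geometry: AcquisitionGeometry,
                config: ReconstructionConfig | None = None,
                return_support: bool = False):
    """ART-TV reconstruction of the local MVCT from preprocessed projections.

    Returns ``(VolumeImage, trace)`` — the trace a dict of per-iteration lists
    (``iteration``, ``d``, ``tv_norm``, ``rel_change``) — plus the ray-support
    mask when requested.  Deterministic: the ray order is fixed."""
    if config is None:
        config = ReconstructionConfig()
    projections = list(projections)
    if not projections:
        raise ValueError("at least one projection is required")
    vol = VolumeImage.centered(np.zeros(config.grid_shape), config.voxel_size,
                               modality="MVCT")
    ox, oy, oz = vol.origin
    vx, vy, vz = vol.voxel_size
    p0s, p1s, vals = build_ray_set(projections, geometry)
    # geometry sanity: at least one ray must cross the volume
    probe = np.zeros(config.grid_shape, dtype=bool)
    for p0, p1 in zip(p0s, p1s):
        _kernels.mark_support(probe, ox, oy, oz, vx, vy, vz, p0, p1)
        if probe.any():
            break
    if not probe.any():
        raise ValueError("geometry mismatch: no ray intersects the reconstruction volume")

    x = vol.values
    lam = config.relaxation
    mu = config.tv_weight
    eps = config.epsilon
    trace = {"iteration": [], "d": [], "tv_norm": [], "rel_change": []}
    for t in range(1, config.max_iterations + 1):
        x_iter_prev = x.copy()
        d_stop = 0.0  # largest ART-induced change this iteration (stop rule)
        if config.tv_cadence == "per_ray":
            for p0, p1, pv in zip(p0s, p1s, vals):
                for k in range(p0.shape[0]):
                    ray = _trace_segment(p0[k], p1[k], vol)
                    x_new = art_update_ray(x, ray, pv[k], lam)
                    x_new = nonneg_project(x_new)
                    d = float(np.linalg.norm(x - x_new))
                    d_stop = max(d_stop, d)
                    x = _tv_step(x_new, mu, d, eps)
        else:
            for p0, p1, pv in zip(p0s, p1s, vals):
                xref = x.copy()
                _kernels.art_sweep(x, ox, oy, oz, vx, vy, vz, p0, p1, pv, lam)
                if config.tv_cadence == "per_view":
                    d = float(np.linalg.norm(x - xref))
                    d_stop = max(d_stop, d)
                    x = _tv_step(x, mu, d, eps)
            if config.tv_cadence == "per_iteration":
                d = float(np.linalg.norm(x - x_iter_prev))
                d_stop = d
                x = _tv_step(x, mu, d, eps)
        xn = float(np.linalg.norm(x))
        rel = float(np.linalg.norm(x - x_iter_prev)) / xn if xn > 0 else 0.0
        trace["iteration"].append(t)
        trace["d"].append(d_stop)
        trace["tv_norm"].append(tv_norm(x))
        trace["rel_change"].append(rel)
        if d_stop < config.stop_tol * max(xn, 1e-300):
            break
    out = VolumeImage(nonneg_project(x), vol.voxel_size, vol.origin, "MVCT")
    if return_support:
        mask = support_mask(projections, geometry, config.grid_shape,
                            config.voxel_size)
        return out, trace, mask
    return out, trace


def _trace_segment(p0, p1, vol: VolumeImage) -> RayPath:
    shape = vol.values.shape
    idx_buf = np.empty((_kernels.max_path_len(shape), 3), dtype=np.int64)
    len_buf = np.empty(_kernels.max_path_len(shape), dtype=np.float64)
    n = _kernels.siddon_path(p0[0], p0[1], p0[2], p1[0], p1[1], p1[2],
                             vol.origin[0], vol.origin[1], vol.origin[2],
                             vol.voxel_size[0], vol.voxel_size[1],
                             vol.voxel_size[2], shape[0], shape[1], shape[2],
                             idx_buf, len_buf)
    return RayPath(idx_buf[:n].copy(), len_buf[:n].copy())
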