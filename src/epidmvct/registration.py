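"""Mutual-information rigid registration of the local MVCT to the planning CT.

The reconstructed MVCT acts as a reference window that slides in one-voxel
steps inside a search region of the planning CT; the integer-voxel offset
maximizing the mutual information MI = H(R)+H(F)−H(R,F) of the overlapping
grayscales locates the patient, and the difference between the planned and
matched window centers, scaled by the voxel size, is the couch shift in mm.
Matched centers are reported in the half-voxel convention natural for
even-sized windows (center of an n-wide window at start + n/2 + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .geometry import VolumeImage


@dataclass
class JointHistogram:
    bins: int
    counts: np.ndarray          # (bins, bins)
    marginal_a: np.ndarray
    marginal_b: np.ndarray
    range_a: tuple
    range_b: tuple


@dataclass
class RegistrationResult:
    matched_center: tuple       # (x, y, z), half-voxel convention
    plan_center: tuple
    mi_value: float             # bits
    shift_mm: tuple             # t = (plan − matched)·voxel_size
    mi_surface: np.ndarray | None = None
    search_radius: tuple | None = None


def _digitize(values: np.ndarray, bins: int, rng=None):
    lo = float(values.min()) if rng is None else rng[0]
    hi = float(values.max()) if rng is None else rng[1]
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64), (lo, hi)
    idx = ((values - lo) / (hi - lo) * bins).astype(np.int64)
    np.clip(idx, 0, bins - 1, out=idx)
    return idx, (lo, hi)


def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = 64) -> JointHistogram:
    """Joint grayscale histogram over per-image [min, max] ranges; the
    marginals are its row/column sums."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have identical size")
    if a.size == 0:
        raise ValueError("need at least one sample")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    ia, ra = _digitize(a, bins)
    ib, rb = _digitize(b, bins)
    counts = np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins)
    return JointHistogram(bins, counts.astype(np.float64),
                          counts.sum(axis=1).astype(np.float64),
                          counts.sum(axis=0).astype(np.float64), ra, rb)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def shannon_entropy(values, bins: int = 64) -> float:
    """Entropy in bits of the normalized bin-count distribution of a sample."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("need at least one sample")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    idx, _ = _digitize(values, bins)
    counts = np.bincount(idx, minlength=bins).astype(np.float64)
    return _entropy_from_counts(counts)


def mutual_information(a, b, bins: int = 64) -> float:
    """MI(A,B) = H(A) + H(B) − H(A,B) in bits, from one joint histogram.

    Taking the marginals from the joint histogram guarantees MI ≥ 0 up to
    floating-point roundoff."""
    h = joint_histogram(a, b, bins)
    return (_entropy_from_counts(h.marginal_a)
            + _entropy_from_counts(h.marginal_b)
            - _entropy_from_counts(h.counts))


def _mi_digitized(ia: np.ndarray, ib: np.ndarray, bins: int) -> float:
    counts = np.bincount(ia * bins + ib, minlength=bins * bins).astype(np.float64)
    joint = counts.reshape(bins, bins)
    return (_entropy_from_counts(joint.sum(axis=1))
            + _entropy_from_counts(joint.sum(axis=0))
            - _entropy_from_counts(counts))


def window_center(start, size) -> float:
    """Half-voxel-convention center coordinate of a window [start, start+size)."""
    return start + size / 2.0 + 0.5


def shift_from_centers(plan_center, matched_center, voxel_size):
    """Couch shift t (mm): componentwise (plan − matched)·voxel size."""
    return tuple(float((p - m) * s) for p, m, s
                 in zip(plan_center, matched_center, voxel_size))


def sliding_search(mvct: VolumeImage, planning_ct: VolumeImage, plan_center,
                   search_radius=(15, 15, 15), bins: int = 64,
                   mask: np.ndarray | None = None,
                   return_surface: bool = False) -> RegistrationResult:
    """Exhaustive MI maximization over integer-voxel window offsets.

    ``plan_center`` is the planned window center in planning-CT voxel
    coordinates (half-voxel convention); the search visits every offset within
    ±search_radius per axis.  Ties are broken by the smallest Euclidean offset,
    then lexicographically on (z, y, x).  ``mask`` restricts the compared
    voxels (e.g. to the reconstruction's ray support)."""
    if tuple(mvct.voxel_size) != tuple(planning_ct.voxel_size):
        raise ValueError("MVCT and planning CT must share a voxel size")
    win = np.array(mvct.values.shape)
    vol = np.array(planning_ct.values.shape)
    radius = np.array([int(r) for r in search_radius])
    if np.any(radius < 0):
        raise ValueError("search_radius must be non-negative")
    start0 = np.array([int(round(c - 0.5 - n / 2.0))
                       for c, n in zip(plan_center, win)])
    lo = start0 - radius
    hi = start0 + radius + win
    if np.any(lo < 0) or np.any(hi > vol):
        raise ValueError(
            f"window {tuple(win)} with radius {tuple(radius)} does not fit in "
            f"planning CT {tuple(vol)} around center {tuple(plan_center)}")
    if mask is not None:
        if mask.shape != mvct.values.shape:
            raise ValueError("mask must match the MVCT shape")
        flat_mask = mask.ravel()
    else:
        flat_mask = None

    ref = mvct.values.ravel()
    if flat_mask is not None:
        ref = ref[flat_mask]
    ia, _ = _digitize(ref, bins)

    shape_surf = tuple(2 * radius + 1)
    surface = np.empty(shape_surf, dtype=np.float64)
    best = None
    offsets = product(range(-radius[0], radius[0] + 1),
                      range(-radius[1], radius[1] + 1),
                      range(-radius[2], radius[2] + 1))
    for off in offsets:
        s = start0 + np.array(off)
        window = planning_ct.values[s[0]:s[0] + win[0],
                                    s[1]:s[1] + win[1],
                                    s[2]:s[2] + win[2]].ravel()
        if flat_mask is not None:
            window = window[flat_mask]
        ib, _ = _digitize(window, bins)
        mi = _mi_digitized(ia, ib, bins)
        surface[off[0] + radius[0], off[1] + radius[1], off[2] + radius[2]] = mi
        key = (-mi, float(np.dot(off, off)), (off[2], off[1], off[0]))
        if best is None or key < best[0]:
            best = (key, off, mi)
    off = best[1]
    matched = tuple(window_center(start0[k] + off[k], win[k]) for k in range(3))
    plan_c = tuple(float(c) for c in plan_center)
    t = shift_from_centers(plan_c, matched, planning_ct.voxel_size)
    return RegistrationResult(matched, plan_c, best[2], t,
                              surface if return_surface else None,
                              tuple(int(r) for r in radius))
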