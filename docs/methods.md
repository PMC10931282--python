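# Methods

## Coordinate and acquisition model

World coordinates place the isocenter at the origin with x = patient left,
y = anterior→posterior, z = superior→inferior. At gantry 0° the source lies
on +y at SAD = 1000 mm and the beam travels toward −y; the flat detector sits
perpendicular to the beam at SID = 1540 mm from the source (magnification
SID/SAD = 1.54). Detector axes are u (rotated x, columns) and v (z, rows).
Ten views span [0°, 180°) at 18° steps. The native panel is 1280×1280 at
0.336 mm (43 cm), the collimated field 20×20 cm at the isocenter. Voxel
indexing is 0-based with voxel centers at `origin + (index + 0.5)·voxel_size`.

The beam is a true point-source cone beam; a parallel-beam toggle exists only
so oracle tests can build well-conditioned single-slice systems. Ray-voxel
intersection lengths come from exact Siddon traversal, so the forward
projector and the ART back-projector share identical weights — a requirement
for ray-by-ray ART to be self-consistent.

## Synthetic phantom and EPID model

The digital thorax phantom is a painter's-algorithm stack of analytic
inserts: a water-equivalent elliptic body cylinder (μ = 0.0049 mm⁻¹, the
linear attenuation of water at 6 MV), two lung ellipsoids (0.0013 mm⁻¹), a
spine cylinder (0.0085 mm⁻¹) and a lesion sphere (0.0060 mm⁻¹). The object
is finite along z (a thorax section): sparse-view ART destabilizes when
measured rays cross matter outside the solved volume, so the reconstruction
grid is sized to cover the illuminated anatomy, matching the full-length
(122-slice) grid of the full-scale protocol.

EPID pairs follow Beer–Lambert: open = I0 inside the projected field aperture
(flat profile, I0 = 1000 grayscale; only the open/transmission ratio enters
the projection conversion, so the flat profile is a neutral stand-in for the
unspecified beam horns), transmission = open · exp(−∫μ dl) through the
optionally couch-shifted phantom. Couch shifts translate the sampled
attenuation field trilinearly; integer-voxel shifts reduce to exact rolls.
Optional Poisson noise draws each pixel with the noiseless value as mean.
What this generator deliberately omits: detector glare/lag and energy
response, head scatter, beam hardening of the imaging chain, MLC leaf
sequences. Passing tests therefore demonstrate algorithmic correctness and
protocol-level behavior, not clinical image quality.

## Preprocessing chain

`P = ln(max(I0, floor)/max(I, floor))` with floor = 1e−6·max(I0) (the log is
undefined at unexposed pixels); negative values, possible under noise, are
clamped to zero since attenuation line integrals are non-negative. The chain
then: bilinear resample to 1 mm (pixel-center alignment of the physical
extents, preserving the world footprint), crop the unexposed border using the
open-field mask, fix a 300 mm square box about the beam axis, and resample to
3 mm — ending at 100×100 regardless of panel orientation quirks. The
physical center of the grid is tracked through every stage so reconstruction
rays stay anchored to the detector plane.

## ART-TV reconstruction

Per ray: Kaczmarz update with relaxation λ, non-negativity projection, then a
TV descent step `x_TV = x_pos − μ·d·v/‖v‖₂` where d = ‖Δx‖₂ is the norm of
the ART-induced change since the previous TV step and v the exact gradient of
the ε-smoothed TV (ε = 1e−8; boundary terms dropped one-sided). TV is
evaluated slice-by-slice in the axial plane — the functional is written in
2D and the 3 mm slice spacing is anisotropic. Defaults: 12 iterations,
λ = 0.1, μ = 1, x⁽⁰⁾ = 0, stop when the largest per-step d falls below
1e−6·‖x‖₂.

Design points settled here:

- The piecewise "skip when wᵢᵀx ≤ pᵢ" condition sometimes quoted for ART
  contradicts the method's own description of correcting by the residual;
  the update applies whenever ‖wᵢ‖ > 0.
- TV cadence is configurable (`per_ray`, `per_view`, `per_iteration`).
  `per_view` is the default: a literal per-ray TV step costs a full-volume
  gradient for each of ~10⁵ rays per iteration, which is intractable at any
  realistic size; per-view retains the adaptive μ·d scaling at 10 steps per
  iteration. The `per_ray` path exists and is exercised on small problems.
- A full non-negativity clamp follows each TV step (the next ray's clamp
  would apply it anyway; doing it eagerly keeps every emitted state
  non-negative).
- Large TV weights overshoot: the step size μ·d does not shrink with the
  TV landscape, and at μ = 5 the iteration limit-cycles with a higher final
  TV than μ = 1 (both far below μ = 0). This is a property of the adaptive
  scheme itself; μ = 1 is the working default.
- With λ = 0.1 the Kaczmarz tail contracts by ≈ 0.85/iteration on the
  10-view thorax problem, leaving the relative image change at ~1.1% after
  12 iterations on the 80×80×24 grid; on the fully sampled 32×32×8
  convergence problem (rays oversample voxels ~12×) it falls below 1% at
  iteration 11. Convergence statements are therefore tied to the
  fully sampled problem; the registration never needed the last fraction of
  a percent.

## MI registration

The MVCT (restricted to voxels with ray support) slides in one-voxel steps
within ±(15, 15, 2) voxels (desk: ±(8, 8, 2)) of the planned window center;
at each offset the joint 64-bin histogram over the overlap gives
MI = H(R) + H(F) − H(R,F) in bits, with marginals taken from the joint
histogram so MI ≥ 0 holds to roundoff. Intensities stay in native units
(attenuation vs HU-like) — MI is invariant to monotone rebinning, so no
cross-calibration is applied. Ties break toward the smallest Euclidean
offset, then lexicographically (z, y, x). Window centers are reported in the
half-voxel convention natural to even windows (center = start + n/2 + 0.5),
and the shift is `t = (plan − matched)·voxel_size` per axis. With 2×2×3 mm³
voxels the search quantization bounds the per-axis error by half the recovery
step: recovered shifts land on the nearest grid point, ≤ 1 mm error in x/y.
The z axis is searched symmetrically but the validation protocol exercises
x/y shifts only.

## Fluence inversion and dose

`ψ_p(t′, r, d) = f · SID²/d² · ψ_EPID(t, r) / exp(−a(r)·t′/(1 + b(r)·t′))`.
Water-equivalent thicknesses come from Siddon raysums of relative-water
density (attenuation/μ_water, or HU/1000 + 1 for planning CTs): t runs
source→EPID pixel, t′ is the remainder between the EPID plane and the
calculation point, located where each ray crosses the plane at perpendicular
source distance d (default: the isocenter plane). a(r) and b(r) are
low-order polynomials of the off-axis radius measured at the EPID plane and
rescaled by d/SID at depth; they are per-machine calibration quantities, so
the defaults are a water-like slope a₀ = 0.005 mm⁻¹ with no off-axis or
hardening terms, and the synthetic forward model uses the same model — the
validation measures the inversion, not an unavailable calibration. The
scatter-correction hook (identity, or subtract an amplitude-scaled Gaussian
blur) fixes the interface for a measured kernel without pretending to one.

Pencil-beam dose: `D′(x,y,d) = Σⱼ D′ⱼ(d)·[Ψ_p ⊛ Wⱼ]` with j = primary,
small-scale and large-scale scatter. Defaults are exponential depth curves
cⱼ·exp(−μⱼd) with weights (0.8, 0.15, 0.05) and slopes (0.005, 0.004,
0.003) mm⁻¹, lateral kernels delta / Gaussian σ = 3 mm / σ = 20 mm
(unit-normalized, widths strictly increasing) — a generic megavoltage
parameterization; tests assert structural properties (linearity, impulse
response, normalization), never these numbers. Dose is in model units: no
absolute Gy calibration and no heterogeneity correction. Registration
correction resamples the planning CT at grid points translated by the
recovered shift (trilinear; integer shifts are exact rolls) before dose
accumulation; imaging (ten 1 MU views) and treatment fields sum elementwise
with provenance, reporting the imaging fraction of central-axis dose.

## Gamma

Global gamma with 3% of the reference maximum, 2 mm distance-to-agreement and
a 10% low-dose threshold. The minimization samples the evaluated map
bilinearly at 0.2 mm steps over a disc of radius 3·dta (capped at the map
extent); offsets are visited in order of growing radius and the scan stops
exactly when the distance term alone exceeds every pixel's current best γ —
a pure speedup with no change to the minimum. γ ≤ 1 counts as a pass,
boundary included.

## Problem sizes

Two presets fix all study conditions. `fullscale`: 1280×1280 panel,
128×128×122 MVCT in a 256×256×122 planning CT. `desk` (used by the
acceptance script and end-to-end tests): the same protocol — 10 views, 18°
spacing, SAD/SID, 2×2×3 mm³ voxels, 12 iterations, λ = 0.1, μ = 1, the
five-shift list, 3%/2 mm/10% gamma — on a half-scale phantom with a 320×320
native panel (1.344 mm), an 80×80×24 MVCT inside a 128×128×32 planning CT,
and ±(8, 8, 2) search. The desk preset keeps every algorithmic parameter and
voxel pitch identical while sizing the grids so the whole five-shift
experiment runs in about a minute on a single CPU. A third preset,
`convergence` (32×32×8), is the fully sampled problem used for convergence
measurements.

## Known limitations

- Rigid translations only: no rotations, no deformable registration, no
  sub-voxel MI interpolation (the search step is one voxel by design).
- Integrated-mode acquisition: one image per static field; VMAT delivery
  cannot provide per-angle transmission images in this mode.
- The EPID/beam models are idealized (flat profile, no glare, no spectrum);
  a(r), b(r), f and the pencil-beam kernels are placeholders for per-machine
  calibrations.
- Dose is relative and water-homogeneous; no TPS comparison or DVH metrics.
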