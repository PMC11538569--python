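# Methods

## Physical model

All propagation is monochromatic, linear, lossless, and purely longitudinal,
with the time convention `e^{+iωt}` (outgoing waves `e^{−ikr}`) shared by
every module. Media are homogeneous fluids characterized by density and
longitudinal sound speed; the shear speeds of the resin and skull are
carried in the registry for completeness but do not enter the propagation
model.

**Rayleigh–Sommerfeld propagator.** `rs_propagate` evaluates the discrete
monopole sum `p(d) = (iωρ₀/2π) Σ_j s_j e^{−ik₀ r_j}/r_j`, the midpoint-rule
discretization of the first Rayleigh integral with the surface element
folded into each strength (`s = u₀ dS`). A singularity guard rejects
evaluation points closer than one tenth of the local grid spacing to any
source; this prevents 1/r blow-up without blocking genuine near-field use.
Convergence is validated against the closed-form on-axis baffled-piston
pressure `p(z) = ρ₀c₀u₀ [e^{−ik₀z} − e^{−ik₀√(z²+a²)}]`: a disc lattice at
λ/6 pitch agrees to better than 1% at the on-axis extrema for z ≥ a.
Measuring the error at the extrema matters — relative error is undefined at
the interleaved nulls — and the disc lattice weights rim-cut cells by their
fractional overlap area (8×8 sub-cell midpoints); a hard center-in-disc mask
at the same pitch carries a several-percent staircase bias.

**Skull layer.** The skull is a flat slab at normal incidence between
identical outer media; its pressure transmission is
`t = 2 / (2 cos(kd) + i(Z + 1/Z) sin(kd))` with `Z` the impedance ratio.
`|t| ≤ 1` always; a matched slab is a pure delay. For the 250 μm mouse skull
at 3 MHz, `|t| ≈ 0.66`. Because the slab is uniform and incidence is treated
as normal, the factor is spatially constant: it scales the recorded hologram
and the forward field identically and cancels out of the (phase-only) design.
The skull-thickness robustness seen in the simulations is therefore exact in
this model; in reality it holds only to the extent that the thin (≈λ/3)
layer at near-normal incidence behaves like a uniform fluid slab. Curvature,
thickness variation, and shear-mode conversion — the features a real skull
adds — are outside the model, and the measured left/right focal asymmetry
such features cause is precisely what the flat-slab simulation will not
show.

## Recording and conjugation

Each focus contributes `n_sources` virtual monopoles (default 100 per
focus). Their positions are drawn uniformly inside a ball of
`jitter_radius = 0.25 mm` about the focus center — the scale of the targeted
nucleus — with a seeded generator; `jitter_radius = 0` gives a point focus.
Each strength is `amplitude/n_sources × exp(i k₀ z_center)`, the carrier
factor removing the nominal plane-wave arrival phase. For bilaterally
mirror-placed targets the second cloud is the x-reflection of the first
(`mirror_x`, on by default): paired anatomical nuclei are mirror targets,
and a mirror-symmetric source set yields an exactly symmetric lens — with
independently drawn clouds the two focal amplitudes differ by several
percent for no physical reason. The recording plane coincides with the lens
exit face (z = 0), with the skull's inner face at a configurable standoff
(default 0.5 mm) between plane and targets. Conjugation negates the wrapped
phase and conjugates the complex pressure; zero-pressure samples take phase
0 by convention so the map stays total.

## Lens inversion

The hologram plane oversamples the pixel lattice (2 samples per 0.25 mm
pixel edge by default); each pixel's design phase is the argument of the
*mean complex pressure* over its footprint, which is robust to sub-pixel
phase gradients where center-sampling is biased.

Heights are solved by exhaustive scan of `arg T(h)` at `scan_step = 5 μm`
over `[0, h_max]`. A scan rather than root-finding because the slab phase is
non-monotone across the Fabry–Pérot resonances, and 1,600 pixels × 240 scan
values is one vectorized argmin. Ties (residuals within 10⁻⁹ rad) resolve to
the smaller height. Defaults: `h_max = 1.2 mm` — the thin-slab relative
phase rate for water/resin at 3 MHz is `f(1/c₀ − 1/c_L) ≈ 0.89 cycles/mm`,
so ≈1.13 mm spans a full 2π and 1.2 mm adds margin — and
`base_thickness l = 0.8 mm`, keeping the total build inside the 2 mm
envelope of the printed part. `T(h)` is evaluated exactly as written above
even where `l − h < 0`; the water-path factor is then a pure phase
reference, and only relative pixel phase matters to the design. `|T(h)|`
varies with height (down to `2Z/(Z²+1) ≈ 0.77` at the resin quarter-wave)
but is deliberately not inverted — the design is phase-only — and is
recorded per pixel for diagnostics. Quantization snaps heights to the 100 μm
print quantum (idempotently) and recomputes residuals; the worst-pixel
degradation is bounded by the maximum phase slope times half the quantum.

## Forward validation

A unit plane wave times the per-pixel `T(h)` defines the exit-plane field;
it is re-radiated by Huygens monopoles at `pixel_width/subsample` pitch
(default 2 per edge = λ/4 in water at 3 MHz; the solver refuses coarser
sampling because a 0.25 mm pixel is λ/2 and would alias). Propagation is
one-way: lens–skull multiple reflections are neglected. This semi-analytic
scheme stands in for a full finite-element solve at desk scale and is
validated against the closed-form piston field and the designed focal
geometry rather than against FEM itself.

Peaks are strict local maxima of |p| over the 3³ neighborhood, ranked by
amplitude, refined per axis by a three-point parabolic fit (offset clipped
to ±half a cell), and normalized to the global maximum. FWHMs are linear
interpolations of the half-max crossings along the lateral and axial grid
lines through each peak; `symmetry_error` is the relative amplitude
difference of the two strongest peaks. Line profiles interpolate |p|
trilinearly and normalize to the field maximum (each field is normalized to
its own maximum throughout). Thickness sweeps re-simulate a *fixed* design
across skull thicknesses — the lens is not re-derived — to measure
robustness of one design to skull variation.

## Study configuration and problem sizes

The built-in configuration uses the study conditions: 3 MHz; media
water (1000 kg/m³, 1500 m/s), resin (1180, 2700), skull (1912, 2300);
10 × 10 mm aperture at Δw = 0.25 mm (40 × 40 pixels); 250 μm skull at
0.5 mm standoff; two foci of 100 sources each at (±1.5, 0, 3.5) mm; pulse
scheme 3 MHz / 500 Hz PRF / 0.4 ms TBD / 1 s SD / 4 s ISI with
Isppa = 0.9 W/cm² and PNP = 0.87 MPa at the focus. The evaluation volume is
x ∈ [−2.5, 2.5] mm, y ∈ [−0.5, 0.5] mm, z ∈ [2.5, 5.5] mm at 0.125 mm pitch
(41 × 9 × 25 ≈ 9 × 10³ points from 6,400 Huygens sources) — sizes chosen so
a design-plus-simulation cycle completes in seconds on one core while the
grid pitch stays at half a lens pixel. Exposure-limit defaults are the FDA
diagnostic-ultrasound track (MI 1.9, Ispta 720 mW/cm²), overridable in
config; the report lists Ispta both with the intra-burst duty alone and with
the SD/ISI factor folded in, since temporal-averaging conventions differ.

## Numerical choices and edge cases

- Phase wrapping is to the half-open interval (−π, π]; −π wraps to π, making
  conjugation an involution on wrapped phases.
- `find_foci` collapses plateaus of equal magnitude to a single
  representative before ranking, and refuses fields with fewer maxima than
  requested rather than padding.
- The STL is a tiling of closed rectangular columns (12 triangles each, one
  per pixel, base included), the standard slicer-friendly representation;
  every body is individually watertight, the enclosed volume equals the
  analytic column sum, and re-export is byte-identical.
- All randomness flows through a single integer seed; a run is reproducible
  bit-for-bit from (config, seed).

## What the synthetic configuration does and does not show

The built-in fixture exercises the full design loop under idealized
conditions: flat uniform skull, lossless media, one-way propagation, exact
plane-wave drive. Passing tests demonstrate the internal consistency of the
design method (recording → conjugation → inversion → refocusing) and its
insensitivity to uniform-slab thickness, not performance against a real,
curved, attenuating skull or transducer non-uniformity. Attenuation,
nonlinearity, broadband pulses, elastic propagation, amplitude-and-phase
(iterative) holography, and CT-based per-ray aberration correction are out
of scope.
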