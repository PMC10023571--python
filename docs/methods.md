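# Methods

`helixsub` re-creates, at desk scale, the structure-determination route for a
flexible helical polymer of D1-symmetric protomers — the situation of a
vacuole-associated TORC1 polymer whose filaments behave like a spring with
varying pitch — together with the fluorescence-quantification statistics used
alongside such a study.  Everything runs on synthetic data with known ground
truth; this note records the models, the defaults and why, the numerical
choices, and what the synthetic results do and do not show.

## Coordinate and pose conventions

Volumes are cubic `(z, y, x)` arrays with the helix axis along `z`, voxel
size in Å, and the rotation center at index `N/2` (coinciding with the DC
sample of a centered FFT).  A pose `(rot, tilt, psi)` in degrees means the
matrix `Rz(psi) · Ry(tilt) · Rz(rot)` applied actively to the reference,
followed by projection along `z`: `rot` spins the reference about the helix
axis, `tilt` is the out-of-plane angle (helical side views sit near 90°),
`psi` is in-plane.  Composing a pose with an extra reference-frame rotation
`phi` about `z` gives `(rot + phi, tilt, psi)`, which is what makes helical
bookkeeping additive.  The helix is right-handed: positive twist advances
counterclockwise (seen from +z) while climbing `+z`.  The D1 two-fold is the
`x` axis; on the lattice this axis passes through the protomer centered at
azimuth zero, so the filament-level and protomer-level two-folds coincide.

## The synthetic scene

**Protomer.** Five isotropic 3D Gaussians (σ 5–6 Å, support radius ≈ 34 Å):
one blob on the two-fold axis plus two asymmetric pairs.  The set is exactly
D1-symmetric, chiral (mirror correlation 0.64 at identity), and has no
hidden rotational symmetry (max off-symmetry self-correlation 0.84 over a
coarse grid).  Gaussians make everything analytic: volumes are evaluated in
closed form, and a projection is again a sum of 2D Gaussians, so the
simulator never shares an interpolation path with the reconstruction
operators it is used to test.

**Lattice.** Twist ≈ 46.9–47.7° per unit, rise ≈ 25.2–28.2 Å per unit
(pitch = rise·360/twist ≈ 192–215 Å), D1 point group — the parameter ranges
reported for the polymer being emulated.  These are kept at their physical
values so geometry-level checks are unscaled; only the radial scale is a toy:
protomers sit at 45 Å from the axis (outer diameter ≈ 160 Å, a ~4× scaled-down
stand-in for the real ~620 Å polymer).

**Pitch variability.** Three modes: `constant`, `per_filament` (one draw per
filament), and the default `random_walk`, a boundary-reflected walk along the
filament whose step is up to 30% of the observed range per unit.  The default
models *intra*-filament flexibility — the spring-with-varying-pitch picture —
because a per-filament-constant pitch leaves each filament internally rigid,
in which case helical averaging inside a segment stays coherent and the
degradation that motivates signal subtraction barely appears.  The adjacent-
unit step size is not something the source data constrain directly; 30% of
the observed range gives walks that traverse the full reported interval
within one filament while remaining smooth at the unit scale.

**Dataset.** Default 24 filaments of 24 units (long filaments, so that
filament ends — which helical averaging sees but subparticle extraction does
not — contribute little; the real dataset averaged ~25 segments per
filament), imaged at 3.0 Å/px in 72-pixel boxes.  Each filament is projected
once onto a canvas strip along its in-plane direction; overlapping boxes are
then cropped at every interior unit's axis position, exactly the way helical
extraction walks a trace at one-rise steps.  Cropping from one canvas means
neighboring segments share micrograph noise — the statistical structure that
makes "keep particles from the same helix in the same half-set" necessary
for honest gold-standard FSC.  One defocus per filament (1.0–2.5 µm,
underfocus positive), 300 kV, Cs 2.7 mm, amplitude contrast 0.1; CTF is
applied to the canvas; white Gaussian noise is scaled to SNR 0.1 measured as
in-mask signal variance over noise variance.  All randomness fans out from
one top-level seed into named substreams (pitch, pose, defocus, noise), so
modules are independently reproducible and a rerun is bit-identical.

The pixel size of 3.0 Å (rather than the 4–5 Å one might first pick for a
toy) is deliberate: the rise variability spans ±1.5 Å, and at a 9 Å Nyquist
the axial blur it causes would be barely resolvable, hiding the very
phenomenon the pipeline exists to demonstrate.  The symmetry-search
experiments, which do not depend on this, use 96³ at 4.5 Å/px.

## Optics

Standard weak-phase CTF, `CTF(s) = −[√(1−A²)·sin γ + A·cos γ]` with
`γ = πλΔf s² − (π/2)Cs λ³ s⁴` and the relativistic electron wavelength;
negative at low frequency (protein dark), no astigmatism, no envelope by
default (an optional Gaussian B-factor flag exists).  Dose bookkeeping is
rate × exposure (the 2.5 e⁻/Å²/s × 8 s = 20 e⁻/Å² arithmetic).  The
subparticle defocus correction is additive: a subunit displaced by `z` Å
along the beam gets `defocus + z`, with the convention (flippable) that a
subunit farther from the detector is more underfocused.

## Projection, reconstruction, symmetrization

Projection extracts a central slice from the 2×-zero-padded, centered 3D FFT
of the reference.  Cubic-spline interpolation of the transform (the default)
agrees with a high-order real-space rotate-and-sum oracle to NRMSE < 0.1% on
blob densities; linear interpolation, a few times faster, is used only for
exhaustive template matching, where template and image pass through the same
interpolant and absolute accuracy is irrelevant.  Reconstruction is direct
Fourier inversion: each image's CTF-premultiplied transform is spread onto a
2×-oversampled 3D grid with trilinear gridding weights and the accumulated
numerator divided by `ΣCTF² + ε` with `ε` equal to 10% of the mean nonzero
weight — a Wiener-style regularization that keeps small-particle-count
reconstructions stable; the trilinear gridding envelope (sinc²) is divided
out in real space.

Helical symmetrization averages the volume over `k ∈ {−2..2}` applications
of the (twist, rise) operator with in-bounds coverage weights (so edge
regions average over fewer terms instead of fading to zero), then the D1
flip.  The flip about the `x` axis through the center is exact
(flip-and-roll); the helical steps use cubic-spline resampling.  Averaging
over a finite window is a true projector only away from the filament ends,
so idempotence holds on the central z-span.

## Twist/rise symmetry search

The symmetry score is the mean squared difference between a volume and its
(twist, rise)-transformed copy inside a cylindrical mask over a central
z-window, annulus-weighted (∝ r); zero iff exactly invariant.  For grid
searches the volume is resampled once into cylindrical coordinates
`(z, r, φ)`, where the helical operator is a pure separable shift, making a
51 × 121 grid (twist 45–50° step 0.1, rise 24–30 Å step 0.05) a few seconds'
work; the Cartesian affine-transform scorer is retained as the independent
oracle in the tests (they agree to a few percent; the argmin is the same).
The z-window excludes the bottom `max(rise)` voxels so every candidate is
scored on identical samples, and callers exclude the filament ends.  Ties at
the minimum break toward the search's starting parameters.

On a noiseless constant-pitch filament the search recovers the generator
parameters exactly (to the grid step).  On a variable-pitch filament the
1.1×-minimum basin broadens severalfold in both axes — the degeneracy
diagnostic that, on the real data, indicated a flexible polymer rather than
a poorly sampled rigid one.

## Helical refinement

Projection matching over an exhaustive grid: first iteration rot 0–360°
(step 6°) × tilt 90 ± 15° (step 6°) × psi prior ± 15° (step 6°), shifts by
windowed cross-correlation (±3 px) with parabolic sub-pixel refinement;
subsequent iterations refine each particle locally at ±2°.  CTF enters the
matching (templates are CTF-multiplied per particle group).  After each
alignment the map is reconstructed and helically + D1 symmetrized.  The
initial reference is a deliberately featureless stand-in for a previously
acquired low-resolution map: one fat Gaussian per unit on the nominal
lattice, low-pass filtered to 30 Å — it encodes the lattice geometry but
none of the protomer detail the refinement is judged on.  Alignment cost is
tracked per iteration; non-convergence returns the best result with a flag
rather than raising.

## Subtraction and subparticles

The all-but-one mask is built from the lattice geometry: a soft union of the
neighbor units' blob supports (3σ, raised-cosine edge), minus the kept unit
dilated by an interface buffer (default one mean blob σ) so density at the
unit–unit interfaces stays with the kept unit.  Subtraction removes
`a · CTF · project(reference × mask)` at the particle's pose, with `a` a
per-image least-squares intensity scale fitted inside the projected mask
support (the reference and the toy images have no shared normalization; the
fit is exactly 1 in the noiseless self-consistent case and can be disabled).
Subparticles are recentered on the kept unit's projected center by an exact
Fourier phase shift, cropped to 40 px (the same ~0.5 box ratio as the
600→300 px crop in the emulated workflow), and given the geometry-corrected
defocus.

## SPA refinement and FSC

Half-sets are split per filament (whole helices assigned greedily, largest
first, to the smaller half) — required here because overlapping segments of
one filament share canvas noise, which a random split would leak across
halves and inflate the FSC.  Both halves start from reconstructions at their
input poses under a shared 30 Å low-pass; each iteration locally realigns
every particle to its own half-map, reconstructs, imposes D1, and then both
half-maps are filtered at the resolution their mutual FSC currently supports
(0.143 crossing) before the next round — the halves share only the cutoff,
never amplitudes.  FSC uses one-voxel shells of normalized cross-correlation
of centered Fourier coefficients; resolution is the first downward 0.143
crossing, linearly interpolated, with a Nyquist flag when the curve never
drops.

## How the two routes are compared to ground truth

Both routes are scored in the 40-px subparticle box against the same local
ground truth: the true protomer plus its neighbor tails rendered at the
lattice returned by the symmetry search, recentered on the central unit, and
masked with the kept-unit support mask.  The helical map is translated (by
exact phase shift, the unit center sits on the x axis) and cropped; the SPA
map is already in that frame.  Including the neighbor tails in the truth is
what makes the comparison meaningful: both routes deliberately retain
interface density (the subtraction mask protects it), so a protomer-only
truth would punish both for being faithful to the data.

## Problem sizes and what the tests show

Default end-to-end runs use 24 filaments × 16 interior segments = 384
segments at 72³/40³ boxes, completing in two to three minutes per pipeline
on one CPU; symmetry-search experiments use 10-unit filaments at 96³.  These sizes
were chosen so the qualitative phenomena — exact parameter recovery on rigid
filaments, basin broadening and the subtraction rescue on flexible ones —
are statistically clear while a full study (both pipeline variants plus all
property suites) stays in the minutes range.

What passing tests show: the operators are mutually consistent and accurate
against independent analytic oracles; the symmetry-search degeneracy
(sharp minimum on rigid filaments, broad basin on flexible ones) and the
flexibility-induced degradation of the helical route emerge from the stated
generative model.  What they do not show: anything about real micrographs —
the generator has no ice gradients, no structural heterogeneity beyond
pitch, no beam-induced motion, no per-frame dose effects, isotropic white
noise, and a protomer that is a five-Gaussian cartoon.  Absolute
resolutions are toy-scale quantities and are not comparable to real
reconstructions.

An important toy-scale caveat on the subtraction route: in an SSNR-driven
map-versus-truth FSC, helical symmetrization can only add signal — every
averaged neighbor copy contributes nonnegatively — and with pitch
displacements of ±1.5 Å per unit (further shrunk on the twist side by the
radial scale-down) the per-neighbor attenuation never outweighs that
multiplicity below the toy Nyquist.  The regime in which rigid-lattice
averaging collapses outright requires boxes spanning ~30 rises and larger
per-unit displacements than the desk-scale geometry can hold, and the
re-refinement of subparticles that polished the real maps needs far more
aggregate signal than a few hundred SNR-0.1 particles carry (measured here:
wide per-subparticle searches against FSC-filtered half-maps are
noise-driven, which is why the SPA stage defaults to a tight local search).
At this scale the flexible-versus-rigid contrast is therefore expressed as
the helical route's own degradation and the broadening of the symmetry
basin, not as the subparticle route overtaking it.

## Fluorescence and plate statistics

Puncta segmentation thresholds with Otsu by default (an absolute threshold
is available), labels with 26-connectivity, discards objects under
`min_voxels`, and measures volumes in physical units; "size" is the
equivalent diameter of the sphere of equal volume (the 500 nm gate does not
itself define a measure, so this choice is explicit and configurable; gate
ties go to "large").  Pearson correlation is over masked voxels; Manders
M1/M2 are the standard intensity-fraction overlaps and asymmetric by
construction.  Vacuolar enrichment is mean(membrane) − mean(cytosol).  The
kinetic half-time is model-free: first crossing of (min+max)/2, linearly
interpolated, direction auto-detected.  The growth coefficient is the OLS
slope of spot intensity over the four ten-fold dilutions; EC50 comes from a
four-parameter logistic fit with a flagged monotone-interpolation fallback.

The two-channel generator places solid spheres (default diameters 300–900 nm,
straddling the gate) at a controlled overlap fraction, blurs with a 130 nm
Gaussian PSF — flat-top objects would have no internal intensity structure
and make within-object correlation degenerate — and adds Gaussian noise on a
constant background.  Default voxels are (500, 100, 100) nm (z, y, x), the
confocal z-step of the emulated acquisitions; note that sub-500 nm objects
are heavily quantized along z at that spacing, exactly as in the real
images.

## Known limitations

Alignment is grid-based with hard priors, not marginalizing; there is no 3D
classification, no per-particle B-factor or scale refinement, no map
sharpening, and no local-resolution estimation.  The symmetry search scores
real-space MSE only — absolute score values are not comparable to any named
package's internal functional, only the surface's shape is.  Box-spanning
filament references wrap at the box edge under the Fourier-slice projector
(periodic convention); segments of real micrographs simply truncate.  The
EC50 fit assumes a monotone four-parameter logistic.
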