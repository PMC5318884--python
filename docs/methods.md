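# Methods

## Optical model

The excitation point-spread function is computed with a scalar
Debye/Fourier model: the focal field at defocus z is the inverse Fourier
transform of the circular pupil (uniform apodization by default; a
Gaussian-overfill option exists) multiplied by `exp(i φ)` for the aberration
phase φ and by the angular-spectrum propagator
`exp(i 2π z √((n/λ)² − f²))`. Scalar treatment is the standard choice at
NA 0.8; vectorial corrections matter above ~NA 1. The two-photon effective
PSF is the *squared* excitation intensity, normalized to unit sum — in
point-scanning two-photon microscopy all emitted photons are collected onto
a large detector, so no detection PSF enters. Unit-sum normalization
encodes that aberrations redistribute excitation without destroying it,
which is precisely the mechanism behind the sample-dependence bias: an
aberrated focus can overlap a bright out-of-plane structure better than a
clean one.

Defaults: λ = 0.92 μm, NA 0.8, water immersion (n = 1.33), grid
128×128×64 voxels at dx = dy = 0.4 μm, dz = 0.8 μm. The configuration
rejects lateral steps above the field Nyquist limit λ/(2NA) = 0.575 μm;
at 0.4 μm the complex field is band-limited and squaring it is exact
sample-wise. Measured on this model, one radian of (unit-RMS) defocus
displaces the focus axially by ≈ 1.6 μm — the calibration used to express a
defocus coefficient as an equivalent depth shift.

## Zernike basis

OSA/ANSI single indexing with unit-RMS ("Noll-normalized") polynomials, so
a coefficient *is* the RMS pupil phase it contributes in radians, and
disjoint coefficient vectors add in quadrature. A Noll↔OSA conversion
helper is provided because the two conventions are easy to confuse (e.g.
astigmatism/coma swap indices 5–8 between them). The default optimized set
is N = 8 modes: both astigmatisms (3, 5), defocus (4), both trefoils
(6, 9), both comas (7, 8) and primary spherical (12); tip/tilt are never
probed. Orthonormality on the discretized pupil is verified with
boundary-pixel coverage weighting (plain masking of a 512² grid leaves
~1.4×10⁻³ quadrature error at the rim; coverage weighting reduces it to
~2×10⁻⁴).

## Imaging model

A frame at stage depth z0 is `Σ_z psf(z − z0) ⊛ sample(z)` with per-plane
*circular* (FFT) convolution. Circularity makes the factorization of the
image mean exact: the mean of the frame equals the sample's mean axial
profile weighted by the PSF's per-plane energy, independent of transverse
structure — the property that makes M1 useless for locking, and a cheap
oracle for tests. Phantom generators keep bright structure away from the
lateral edges so wrap-around has nothing to wrap. Stage depths snap to the
axial voxel grid (nearest plane).

Detection noise is Poisson shot noise on `photon_scale × ideal` plus
Gaussian read noise, clipped at zero — photon-counting two-photon detection
with a PMT. The virtual microscope can replay a frozen noise realization
for exactly reproducible closed-loop runs. Photobleaching is modeled as a
per-frame exponential decay in acquisition order and compensated by a
log-linear fit of frame means vs order; the fit assumes the underlying
frame means are stationary (or symmetric) across the sequence, so a
monotonic structural trend in a z-stack would alias into the decay
estimate.

## Phantoms

*Beads*: solid spheres, antialiased by 4× subvoxel partial-volume
weighting (total mass accurate to <0.1% for a 10 μm bead).

*Neuron slab*: two 10 μm somata at z = −8 and +8 μm (laterally at
x = ∓9 μm) plus dendrites — persistent 3D random walks rasterized as
1.5 μm tubes, density peaking at mid-depth, per-voxel brightness equal to
the somata. The defaults (40 dendrites, seed 0) were calibrated so the
phantom reproduces the qualitative structure the method is designed for:
the per-plane mean concentration at z = 0 stays ≥ 50% of its soma-plane
value (so M1 cannot separate the somata), M2 acquires a spurious mid-depth
local maximum from the in-focus dendrites, and M3's two dominant maxima
stay within 2 μm of ±8 μm — verified across generator seeds 0–4. The slab
reproduces stated structure, not any particular tissue volume; its soma
interiors are uniform by default (a hollow, nucleus-excluded option exists
for cytosolic labels).

What the phantoms do *not* emulate: scattering, depth-dependent spherical
aberration from index mismatch, activity-dependent brightness, motion.
Passing tests therefore demonstrate the optimizer's correctness against the
stated imaging model, not robustness to every in vivo nuisance.

## Metrics

M1 = mean intensity; M2 = population variance; M3 = variance of the
difference-of-Gaussians band-passed image (FFT-applied, periodic — matching
the circular imaging model; each cutoff is the FWHM of its Gaussian
kernel). M3 with an all-pass band reduces exactly to M2, and M3 is
invariant to constant offsets.

Band defaults: low_cut = 15 μm, high_cut = 1.5 μm. The low cut removes the
M1-like smooth background — this is what lets M3 localize somata where M2
is confounded. The high cut is deliberately close to the diffraction scale
rather than the dendrite scale: narrowing the band from above was measured
to cost aberration sensitivity faster than it gains soma selectivity
(with a 4 μm high cut, M2 out-drops M3 by ~0.08 under 1 rad of coma,
noiseless). With the wide band, locking still succeeds (the somata dominate
the band-passed variance) *and* M3 is the most aberration-sensitive metric
under realistic photon-counting noise, because the band rejects most of
the white shot-noise floor that dilutes M2's normalized drop. In the
strictly noiseless limit the M3 ≥ M2 ordering is not guaranteed — the
sensitivity comparison is run at a few counts per bright pixel
(photon_scale 5, read 0.5), the regime fast in vivo imaging lives in, with
the metric averaged over 3 frames per probe.

## Optimizer

Axial lock: 51 planes at 0.8 μm (= the axial voxel step) spanning 40 μm,
M3 per plane (bleach-corrected when enabled), argmax with ties broken
toward the requested center; a flat profile (max/min < 1.05) raises "no
lockable structure". The lock runs once; defocus probing supplies the fine
focus afterwards.

Per mode, 4 probes at offsets {−1.5, −0.5, +0.5, +1.5} rad around the
current coefficient plus one reference per cycle (the 4N+1 budget; 3 cycles
× (4×8 + 1) = 99 images for the defaults). The maximizing coefficient uses
the "interpolated" rule: a parabola through the best sample and its two
neighbors (reference included), vertex clamped to the probed interval,
falling back to the best sample when the local fit is convex or
degenerate. A global parabola through all five points was rejected: it is
strongly biased whenever the peak sits off-center in the ±1.5 rad range,
while the local fit recovers single-mode injections to <0.01 rad. An
"argmax" rule (best sampled point) is available. Wavefront updates are
batched per cycle: all modes are probed against the same current wavefront,
then updated together.

Because the lock fixes the stage depth first, the defocus coefficient and
the locked depth are exactly degenerate: after correction, any residual
defocus is deliberate refocusing within the lock's 0.8 μm quantization (and
the soma-localization tolerance of ~2 μm), not uncorrected aberration.
Closed-loop performance is therefore quantified as the residual RMS over
the non-displacement modes (measured 0.03–0.07 rad for RMS-1.0 rad
injections across seeds), together with the equivalent focal shift of the
defocus term and the ratio of the achieved metric to the metric under
perfect correction (≥ 0.99, occasionally > 1 when the optimizer
out-focuses the quantized lock).

## Axial profile quantification

Soma profiles are disk means (12 μm diameter) per z plane, fitted with
`f(z) = a + b/(1 + ((z−c)/(d/2))²)²` — the square of the Lorentzian axial
intensity profile of a Gaussian beam. The parametrization makes
`f(c ± d/2) − a = b/4` exact, so `d` is the FWQM of the
background-subtracted profile by construction; quarter-maximum is measured
relative to the fitted background, which is the convention that makes `d`
exact. Signal = `b`; resolution = `d`; paired improvements are
`100(S_a/S_b − 1)` and `100(1 − d_a/d_b)` with medians across objects.
Start values come from the raw profile (min, max−min, argmax, interpolated
FWQM); fits are bounded least squares. On noiseless simulated bead
profiles the fitted `d` agrees with a model-free interpolated FWQM within
8%; the model is an approximation for a PSF convolved with a sphere, not an
identity.

## Problem sizes and determinism

All shipped experiments run at the desk-scale grid (128×128×64 voxels,
51.2×51.2 μm FOV), chosen so the full validation suite completes in a few
minutes on one CPU; the optics configuration scales to larger FOVs. Every
experiment is deterministic under its master seed; CSV outputs carry a
configuration hash.

## Known limitations

- The bleaching fit can absorb structural intensity trends (see above).
- The sensitivity ordering M3 ≥ M2 is a statement about realistic noisy
  acquisition, not a noiseless identity.
- The slab's M2 mid-depth confound is seed-dependent in strength (clearly
  present for the default seed); M3 locking is robust across seeds.
- No scattering or index-mismatch modeling; the acquisition contract is
  the integration point for real hardware, which this package does not
  drive.
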