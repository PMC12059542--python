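# Methods

This note records the models, numerical choices and limitations behind
`histocal`.  It documents what the code does and why; every number it
mentions is either a package default (inspectable in the source) or a
quantity the test suite / acceptance script computes at run time.

## Coordinate and image model

All volumes are axis-aligned scalar grids with voxel-center addressing:
`world = origin + index · spacing`, indices 0-based, axes ordered (x, y, z),
and axis 2 ("Z") the layer normal, which is also the transducer's beam axis.
NIfTI and NRRD files are normalised on read to this convention; direction
matrices that are not permutations/flips of the identity are rejected
rather than silently resampled, because the analysis is deliberately
axis-aligned to the phantom layers.  Out-of-bounds interpolation returns a
configurable background value (default 0) so that ROI cuboids may poke past
a cropped volume edge and degrade gracefully.

The reference grid is 0.47 mm/voxel — the clinical CBCT reconstruction
pitch — over a 60 × 60 × 35 mm field (≈128 × 128 × 74 voxels).  This keeps
the voxel-denominated algorithm constants (5-voxel filter kernel, 1-voxel
σ, ±2/±4-voxel seed perturbations) on the scale they assume while keeping a
simulated scan pair under a second to generate.

## Synthetic phantom

`PhantomSpec` describes a 50 × 50 × 25 mm agar block of 11 alternating
layers (6 plain, 5 barium-doped), embedded in a water background of
intensity 0.  Default intensities are 60 (plain agar) and 400 (barium) in
arbitrary CBCT-like units; the barium–plain contrast of 340 is the scale
against which noise defaults are set.  Layer thicknesses are drawn per
phantom — plain U[3, 4] mm, barium U[1, 1.5] mm, jittered by 0.15 mm — and
rescaled proportionally if a draw exceeds the 25 mm depth, emulating the
hand-poured manufacturing variability that motivates the two-branch Z rule.

A treatment is an ellipsoid of radii (2, 2, 4) mm.  The post scan inside
the zone is a convex blend toward the locally homogenised value:

    post(x) = (1 − w(x)) · pre(x) + w(x) · (homog + η(x)),

where `homog` is the mean of the pre volume over a 4 × 4 mm column and
10 mm Z window at the treatment's XY position (the fully mixed material),
η is zero-mean Gaussian mixing heterogeneity with σ = 0.15 · contrast = 51,
and w(x) = m(t) · s(x) with s a smoothstep equal to 1 inside 80 % of the
radii and falling to 0 at the boundary.

The duration dependence is a saturating exponential,
m(t) = 1 − exp(−t/τ) with τ = 11.5 s, chosen so the 20 s / 5 s contrast
ratio is ≈ 2.34, matching the observed ratio of mean treatment-zone
intensities at those durations; visibility rises steeply to ~20 s and
plateaus beyond, which is why 20 s is the default treatment duration.

Two barium-specific mechanisms reproduce the phantom's known Z behavior:

* **Edge blur**: when a treatment intersects a barium layer its Z radius is
  dilated by 1.25 (barium powder seeds cavitation and blurs the cloud's top
  and bottom).  With ~4.4 mm layer periods an 8 mm cloud almost always
  triggers this, making the Z extent of the difference signal — and hence
  the Z branch of the localizer — the noisy part of the problem, as on the
  bench.
* **Seeding boost**: mixing completeness grows linearly from 1 at a barium
  layer center to 1.15 midway between layers.  A focus placed directly on a
  layer cavitates prematurely at the layer, partially shielding the focal
  zone; a focus between layers cavitates in clean agar fed by seed bubbles
  from both neighbours.  This reproduces the observed direction of the
  between-layers > on-layer visibility asymmetry; setting the boost to 0
  disables it.

Scan degradation: Gaussian reconstruction blur (σ 0.4 mm), additive
Gaussian noise (σ 10, i.e. ~3 % of contrast), and a rigid motion of the
post scan drawn uniformly from ±1 mm / ±0.5° per axis unless fixed —
"minor physical shifts" of the phantom in the water bath.  Pre and post
noise streams are independent; all randomness flows from explicit seeds
through `numpy.random.SeedSequence`, so every pair is bit-reproducible.

What the simulator does **not** model: acoustic propagation, cavitation
physics, projection-domain artifacts (beam hardening, scatter, rings),
non-rigid phantom deformation, and CBCT intensity nonlinearity.  Passing
tests therefore demonstrate the analysis chain's correctness and its
robustness to the modelled effects (layer-phase ambiguity, noise, small
rigid motion), not performance on scanner data.

## Registration

MSE metric, regular-step gradient descent, trilinear interpolation, 3-level
shrink pyramid (4×, 2×, 1×), backed by SimpleITK's registration framework.
The metric is evaluated on a fixed-seed 2 % random voxel sample; the
learning rate is 0.2 with step halving down to 5 × 10⁻⁴.  A larger initial
step can hop into a false minimum of the layered phantom's periodic Z
structure (an 11° in-plane rotation once the layers alias), which is why
the step policy is conservative — the motions to be recovered are ≤ ~2 mm.
Measured recovery error on simulated pairs is ~0.01 mm noiseless and well
under 0.25 mm at default noise.  The transform is parameterised as XYZ
Euler angles about the fixed volume's center; the registered *pre* volume is
resampled onto the *post* grid, and reported centroids are mapped back to
the pre (plan) frame through the fitted transform.

## Localization

The cost of a candidate ROI center is the mean of trilinear samples on a
lattice at voxel pitch spanning the 4 × 4 × 30 mm cuboid, anchored to the
cuboid center so the cost is continuous in the center.  The tall cuboid
weights all Z equally, which keeps the in-plane optimum insensitive to the
exact Z and to beam-path extension of the zone toward the transducer.

Because the lattice is commensurate with the voxel grid, the cost is
piecewise linear in the ROI center with knots at voxel-center phase: its
argmax is knot-quantized, giving the in-plane estimate an inherent
±half-voxel (0.235 mm) resolution — the scale of the bench X/Y spreads.
An exactly symmetric signal produces a perfectly flat one-pitch plateau on
which a simplex stops arbitrarily; a deterministic refinement therefore
centers the converged position within its tied-optimal set (midpoint of
the tied run within half a pitch of the converged point, scanned at
pitch/20 along each axis).

Nelder–Mead settings: initial simplex edge 1 voxel, position tolerance
0.01 mm, relative cost tolerance 10⁻⁶, at most 200 evaluations per start.
Seven starts — the seed, ±2 voxels in X, ±2 in Y, ±4 in Z — with the winner
chosen by highest converged cost and ties broken toward the unperturbed
seed, so repeated runs are identical.

The Z profile averages the central third (~1.33 × 1.33 mm) of the ROI
footprint at each of the 64 Z samples.  The detected extent counts the
half-pitch support at each end of the supra-threshold run
(extent = z_top − z_bot + pitch): sample-center differences alone would
systematically understate a boxcar's width by one pitch and make the 8 mm
branch decision oscillate between adjacent sample counts.  In the
weighted-centroid branch the first moment is taken over the raw full
profile without background subtraction — the fallback exists precisely
because the supra-threshold span is unreliable there, so all evidence is
used.  The nonzero |difference| background means this branch shrinks the
estimate slightly toward the profile window's center; the multi-cloud
estimator exists to average such errors away.

## Calibration

The pattern is four clouds at p_k = p₀ + k · (0, 10, 1) mm.  The 1 mm Z
stagger makes the four clouds sample different layer phases, which is what
lets their average cancel the layer-phase error of any single cloud.
Joint localization proceeds in three stages: (1) independent per-cloud
localization seeds the shared offset; (2) Nelder–Mead over a single shared
in-plane offset of the rigidly co-moving ROIs maximises the pooled mean
cost; (3) the four Z profiles are aligned by the known stagger, averaged,
and the unchanged single-cloud Z rule is applied to the average — the
minimal joint extension of the single-cloud algorithm, since the reference
procedure specifies joint optimisation but not how Z is jointly resolved.
The 1 mm stagger is not a multiple of the 0.47 mm pitch, so the four
aligned profiles sample Z at four distinct sub-pitch phases; the average is
taken on a pitch/4 grid, which preserves that dither and gives the joint Z
estimate sub-voxel resolution — the "unique treatment positions" the
staggered pattern was designed to create.

Stage 1 is seeded at the planned targets by default.  The experiment
drivers instead snap each seed to the brightest difference voxel within
±5 mm of its target (`snap_seed_radius_mm=5`), emulating the manually
placed "observed center" seed of the bench workflow; without this, a
transducer offset approaching half the 10 mm pattern spacing can latch a
single-cloud search onto its neighbour.  The ±5 mm radius is half the
pattern spacing, the largest unambiguous window.

Offsets are reported as measured − planned, per axis, in the plan frame.

## Experiments and problem sizes

The four drivers reproduce the study designs: duration/visibility (6
durations × on/between positions), translation accuracy (1–6 mm moves per
axis; the reference cloud sits on a barium layer, and the translated cloud
is additionally displaced 14 mm orthogonally in-plane so even a 1 mm
planned move yields disjoint zones — the measured translation is the signed
centroid-difference component along the planned axis, so the orthogonal
separation does not enter), single-vs-multi MAD (replicate 4-cloud
sessions, fixed injected offset), and offset recovery (several injected
"transducer" offsets).  Treatment positions are drawn with a uniform
sub-voxel in-plane phase per replicate: a physical focal point never
aligns with the reconstruction grid, and a fixed grid-aligned (or exactly
mid-cell) placement would sit at a singular point of the half-voxel cost
quantization.  Defaults match the study sizes (n = 10 per
translation cell, 4 calibration sessions); the unit-test suite runs scaled
versions (n = 1–2) and the acceptance tests run the full sizes, which is a
few minutes of compute on one CPU.  Every report row carries the seeds and
a config hash sufficient to regenerate it; identical config + seed yields
byte-identical CSV output.

## Known limitations

* The weighted-centroid Z branch is biased toward the profile window
  center by the noise-floor background; single-cloud Z estimates inherit
  ~1 mm layer-phase scatter (the bench observation that motivates the
  multi-cloud design).
* Registration capture range is a few mm / degrees; it is a local method
  and assumes the scans are already coarsely aligned, as scanner pairs are.
* Only axis-aligned volumes are supported; DICOM series and 4D inputs are
  out of scope.
* The translation experiment assumes robot and image axes coincide; bench
  measurements include a cart-alignment error the simulator does not model,
  so synthetic residuals are an idealised lower bound.
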