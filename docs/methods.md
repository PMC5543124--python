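# Methods

`conductionscan` implements the computational chain used to resolve the
cardiac conduction system from contrast-enhanced micro-CT: attenuation-band
segmentation, structure-tensor extraction of cardiomyocyte orientation with
helix-angle mapping, morphometry of the segmented structures, and monodomain
simulation of electrical activation seeded at the sinus node.  Because no
public micro-CT dataset of this kind is available, every stage is exercised
on synthetic voxel phantoms whose ground truth (labels, fiber field, frame,
landmarks) is generated alongside the image.  This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Tissue contrast model and segmentation

Iodine staining gives soft-tissue classes distinct X-ray attenuation.  The
package adopts the ordering fat > working myocardium > paranodal tissue >
nodal tissue > connective tissue, with the paranodal mean *between*
myocardium and node — the ordering tied to the seeded segmentation of
paranodal projections ("pixel values higher than the node, lower than the
working myocardium").  Classification is a pure per-voxel banding into
half-open intensity intervals; there is deliberately no spatial
regularization, so the banding is exactly analysable against Gaussian noise
(per-class accuracy is bounded by the normal tail of half the band gap).

Band boundaries can come from three places:

* `bands_from_means` — midpoints between known class means, the
  maximum-likelihood rule for equal-variance Gaussian noise.  This is the
  reproducible surrogate for an operator setting thresholds interactively,
  and the route used for phantom studies (the phantom's configured means
  play the role of a calibration).
* `estimate_bands(..., "kmeans_1d")` — exact 1D k-means on histogram bins by
  dynamic programming, with `log1p(count)` bin weights.  The log compression
  matters: conduction structures occupy orders of magnitude fewer voxels
  than background, and any count-weighted SSE objective prefers splitting
  bulky classes over separating small, well-separated ones.  Even so, a
  class that forms a mere shoulder on a dominant neighbour's flank (the
  paranodal class in the noisy default phantom: ~240 voxels sitting 4.3
  sigma up the myocardium tail) is not identifiable by any unsupervised 1D
  method; this limitation is structural, not an implementation defect.
* `estimate_bands(..., "percentile")` — equal-mass splits, only meaningful
  when class volumes are comparable.

Structures are then extracted the way an operator would wield a magic wand,
made deterministic: the node body is the connected component (26-neighbour
by default) of the nodal band containing the seed voxel; paranodal
projections and islands are connected components of the intermediate band
lying within one voxel of the grown node body, with a minimum size of 10
voxels so isolated noise-flipped voxels on the node surface do not register
as extra components; the conduction axis and bundles grow only inside
user-supplied corridor masks, the reproducible stand-in for
histology-guided manual segmentation.  Label precedence is node > paranodal
> axis > Purkinje > myocardium.

## Orientation from the structure tensor

Myocyte chains appear as elongated texture; gradients are perpendicular to
the chain, so the along-fiber axis is the eigenvector of the *smallest*
eigenvalue of the gradient structure tensor
`J = G_{sigma_t} * (grad_{sigma_g} I)(grad_{sigma_g} I)^T`.
Defaults: `sigma_g` = 1.5 voxel pitches, `sigma_t` = 3 pitches.  The
derivative scale is deliberately above one pitch: a one-pitch Gaussian
derivative under-smooths texture near the Nyquist frequency and biases
orientations toward the grid axes by roughly `3.5 deg x sin(2 alpha)`
(measured on constant-helix shells); 1.5 pitches halves that bias at
negligible resolution cost.  Coherence is the Westin linear measure
`(l2 - l3) / (l1 + l2 + l3)`, zero (and the voxel invalid) where the trace
vanishes or `l2 = l3` leaves the minor axis undefined — degenerate voxels
are flagged rather than assigned an arbitrary vector.  Directions are
axial quantities; they are stored with nonnegative z component and all
derived maps are invariant to fiber sign flips.

The helix angle at a wall voxel is the signed angle in (-90, +90] between
the fiber's projection onto the wall-tangent plane and the local
circumferential direction `c = normalize(long_axis x n)`, positive toward
the long axis; an absolute-value variant mirrors colour maps of absolute
helical angle.  The wall normal `n` comes from the gradient of the
normalized transmural depth, computed from Euclidean distance transforms of
the wall mask; background components are classified into cavity vs exterior
by their perpendicular distance from the long axis (computed inside the
wall's bounding box, so walls truncated at a basal plane do not leak their
cavity into the exterior), and the normal is canonicalized to point away
from the frame centre.

## Synthetic phantoms

**Two-chamber heart phantom** (default 64 x 64 x 88 voxels at 300 um; the
same physical geometry can be generated at any pitch): a truncated-ellipsoid
ventricular shell (2.4 mm wall) with a linear transmural helix ramp (+60
deg endocardial to -60 deg epicardial, the standard idealization of the
transmural helical pattern), an atrial shell (1.8 mm wall) with
circumferential fibers, a 0.8 x 0.8 x 2 mm sinus-node ellipsoid at the
atrial mid-wall with three paranodal tubes leaving it, an insulating
connective base crossed only by a 0.6 mm-radius conduction-axis tube (the
sole atria-to-ventricle pathway), a recursive binary Purkinje tree on the
ventricular endocardium (branch angle 28 deg, length decay 0.8, one
free-running chord), and epicardial fat pads.  Voxel intensity is the
tissue-class mean plus independent Gaussian noise (sd 3.5 against a minimum
class gap of 15, i.e. a >= 4 sigma separation); the label geometry is
independent of the noise, and the volume is bit-reproducible given the seed.

What this phantom does *not* emulate: CT physics (beam hardening, scatter,
partial-volume blur), anatomical realism of a human heart, intensity
inhomogeneity, or textured intensity inside tissue classes.  Segmentation
results on it therefore demonstrate correctness of the banding/growing
logic under calibrated Gaussian noise, not robustness to scanner artefacts.

**Fiber test volumes**: `parallel_cylinders` sweeps a smoothed random 2D
cross-section along an arbitrary axis (texture elongated along the axis,
orientation constant); `sinusoidal_grating` is a product of transverse
cosines used for coherence-vs-noise studies.

**Helical shell phantom** (default 168 x 168 x 64 at 28 um, cylindrical
wall 48 voxels thick): fibers follow a linear transmural helix ramp; the
intensity texture is *exactly* constant along the local fiber.  Each
one-voxel radial shell carries an independent random 1D profile of the
helical invariant `xi = z cos(alpha) - r theta sin(alpha)` with the shell's
frozen radius and angle, so the in-shell gradient is perpendicular to the
fiber by construction; two angular charts with complementary seams are
blended to remove the theta-wrap discontinuity, and the texture continues
~10 voxels past the wall (clamped angle) and past the wall's z ends so the
wall boundary itself contributes no oriented gradient.  The 48-voxel wall
makes the ramp 2.5 deg/voxel, comparable in per-voxel terms to a human
ventricular wall at tens-of-micrometre pitch.  Additive noise default: 0.2
of the unit texture contrast.  An ellipsoidal-shell variant uses a
line-integral-convolution texture instead (weaker orientation contrast,
adequate for qualitative maps).

## Morphometry

Length and width are extents along the principal component axes of the
voxel-centre cloud plus one voxel pitch (the voxel footprint); a single
voxel measures one pitch in every direction.  Minimum distances are between
boundary-voxel centres (kd-tree, exact), zero for intersecting masks; the
bias relative to true sub-voxel surfaces is at most one voxel diagonal.
The ellipsoid fixture with semi-axes 7.4 x 2.15 x 2.15 mm (sinus-node-scale)
reproduces 14.8 mm length and 4.3 mm width to within a pitch.  Whether
distances should be surface-based or centroid-based was open; surface-based
was chosen as the stricter reading of "extends to within".

## Electrophysiology

**Monodomain model**, explicit operator splitting: reaction by the ionic
model (Rush-Larsen exponential updates for Hodgkin-Huxley gates, forward
Euler otherwise), diffusion `div(D grad V)` by conservative finite
differences.  Fluxes live on cell faces with harmonic-mean normal
conductivities and arithmetic-mean mixed terms; a face touching a
non-conducting voxel carries zero flux, so no-flux boundaries hold by
construction and the operator conserves the total potential to round-off.
The operator is assembled once as packed index-pair lists over conducting
voxels (cost scales with tissue volume, not bounding box).  Explicit
stability is enforced as `dt <= 0.8 h^2 / (2 max trace D)`; a larger
requested step is refused.  Units: mV, ms, mm, mm^2/ms.

**Conductivity**: `D = d_T I + (d_L - d_T) f f^T` per voxel from the fiber
field; isotropic fallback `mean(d) I` where the fiber is undefined; zero on
fat, connective tissue and background.  Default tissue values (configuration,
not measurements) are calibrated for the Mitchell-Schaeffer tissue model on
a 0.25-0.3 mm grid: working myocardium (0.3, 0.075) mm^2/ms giving ~0.6
mm/ms longitudinal conduction with a 2:1 velocity anisotropy, node (0.05)
slow, conduction axis (0.012) at ~0.1 mm/ms so its traversal supplies the
atrioventricular delay, Purkinje (1.2, 0.3) at ~2x the myocardial speed.
The Purkinje multiplier is 2x rather than 3x: velocity scales with the
square root of diffusivity, so a 3x speed needs 9x diffusivity, whose
stability limit would triple the step count on the coarse phantom grid
while the phantom's 1-2 voxel Purkinje tubes cannot resolve such a wave
anyway.

**Ionic models**: ten Tusscher 2004 (epicardial parameter set, 2004 rather
than 2006 and epicardial rather than endo/M because the variant used in the
source work is unstated) for ventricular tissue; Courtemanche 1998 for
atrial tissue; and a Mitchell-Schaeffer two-variable model rescaled to mV
(-85 to +20) for tissue-scale phantom runs, whose resting state is an exact
fixed point.  Documented stable steps: 0.02 ms for the biophysical models,
0.1 ms for Mitchell-Schaeffer.  Single-cell integration JIT-compiles the
same kinetics functions with numba (identical equations to the vectorized
tissue path; equivalence is tested), falling back to plain numpy.  Both
biophysical models start from their published initial conditions, which are
rounded; they settle within seconds to their true equilibria (ten Tusscher
to -86.46 mV, Courtemanche to -81.19 mV), so resting-drift figures are
quoted after a 10 s equilibration (then 0.004 and 0.00005 mV/s).  The
fixed-step integrator agrees with an adaptive LSODA integration of the same
equations to well under 1 mV at rest.

**Virtual heart**: the stimulus is applied at the centre of the node body
(the node is driven, not self-oscillating — no sinoatrial pacemaker model
is included).  The ordering report asserts: node first; every atrial voxel
before any ventricular voxel; Purkinje-adjacent endocardium (transmural
depth < 0.3, within 2 voxels of the tree) before mid-wall (0.4-0.6) by
median activation time; and, with the axis label removed, permanently
silent ventricles.  Assertion failures are reported in the output, never
swallowed.  The default tissue model for these runs is Mitchell-Schaeffer:
the phantom grid (0.3 mm) is far coarser than the space scales that make
biophysical AP morphology meaningful, and the ordering claims depend only
on wave arrival times.  Ten Tusscher / Courtemanche can be assigned
per-region through the configuration.

**Activation maps** record the first upward crossing of -40 mV (default,
configurable), linearly interpolated within the time step; never-activated
voxels keep +inf.

## Pipeline

`run_pipeline` executes phantom -> segment -> orient -> morphometry ->
simulate from a validated configuration (unknown keys rejected by name),
writes every artifact with its SHA-256 checksum into `manifest.json`, and
is checksum-reproducible for identical config + seed.  The global seed fans
out to stages by fixed offsets.  The default pipeline phantom is the
half-resolution grid so a full run takes seconds.  Note the orientation
stage runs on the heart phantom's intensity volume, which is flat within
classes by design, so its coherence is low there — the stage demonstrates
plumbing; quantitative orientation recovery belongs to the textured
fixtures.  `report` renders mid-slice label, helix-angle and isochrone
panels with the morphometry and ordering tables.

## Problem sizes used in the shipped studies

Orientation recovery: 64^3 voxels at 28 um, seven inclinations, 30%
relative noise.  Helix recovery: the default shell (168 x 168 x 64).
Segmentation/morphometry/virtual heart: the default phantom (64 x 64 x 88
at 300 um).  Wave physics: a 50 mm cable at 0.25 mm (reference at 0.05 mm)
and a 97 x 97 x 3 slab.  These sizes resolve every quantity tested while
keeping a full verification run in minutes on one CPU.

## Known limitations

* Band classification has no spatial prior; heavy noise (gap < 3 sigma)
  degrades it exactly as the Gaussian bound predicts.
* The helix-angle frame assumes a roughly shell-like wall around a single
  long axis; papillary-muscle-like or highly convoluted geometries need an
  explicit radial field.
* The explicit monodomain solver is bound by the diffusion CFL limit;
  resolving a genuinely 3x-faster Purkinje wave needs a finer grid, not a
  larger diffusivity.
* Purkinje-myocardial coupling is continuous (shared voxel faces); there is
  no discrete junction resistance, and no dedicated Purkinje cell model.
* The phantoms contain no CT physics; claims proven on them concern the
  analysis chain, not scanner robustness.
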