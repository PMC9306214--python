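# Methods

`nucleiws` segments individual cell nuclei in 3D fluorescence microscopy
z-stacks with a marker-controlled watershed whose two failure modes --
fused nuclei and oversegmentation -- are attacked separately: fusion by
semantic masks that carve background stripes into nucleus-nucleus contacts
(*edge emphasis*), oversegmentation by suppressing shallow distance-
transform maxima with an H-minima transform whose single depth parameter
`h` is chosen automatically from the shape of the resulting objects.

## Geometry and spaces

Confocal stacks are strongly anisotropic: the slice step `s_z` is typically
3-10x the in-plane pixel `s_xy`.  All segmentation runs in a *near
isotropic expanded space* obtained by (1) bilinear resizing of every slice
to 256x256 (with a sigma=1 px Gaussian low-pass first when downsampling),
(2) zeroing signal-free slices, and (3) inserting linearly interpolated
slices with an odd integer factor, usually 3.  Odd factors keep every
original slice in the expanded stack at `k % factor == 0`, so results map
back to the *input space* exactly, by keeping every factor-th slice
(plus 2D nearest-neighbour resizing when the original in-plane size
differed from 256).  Expansion uses edge clamping past the last slice and
yields `factor x Z` slices; the alternative `factor x (Z-1) + 1` convention
was rejected because it breaks the plain `k * factor` collapse arithmetic.

A slice is *background* iff its sigma=3 px smoothed maximum is strictly
below 10% of the smoothed stack maximum **and** it is reachable from the
first or last slice through other background slices -- the detection grows
inward from both stack ends, so a dim interior slice between bright ones is
never zeroed.  An all-zero stack is entirely background.  Filters use
reflective boundary handling so the image border cannot fabricate dark
rims.

## Masks, seeds and training targets

Three binary nuclei-mask types feed the watershed:

* `M3D` -- plain foreground;
* `M3DE` -- foreground with each nucleus's 3D *outer boundary* (the
  26-adjacent voxels outside it) forced to background; where two nuclei
  touch, each erases the other's contact layer, producing a two-voxel
  separating stripe;
* `M2DE` -- the same edge emphasis applied slice-wise with 2D 8-adjacency
  (blind to purely axial contacts by construction).

*Seeds* `S` are per-nucleus erosions with a spherical element of radius 3
voxels; if erosion empties a nucleus or splits it (26-connectivity), radius
1 is used, then in-plane-only 2D erosion with a radius-1 disc, and as a
last resort the whole nucleus -- every ground-truth nucleus contributes
exactly one seed component.

Ground truths drawn on the input grid are lifted to the expanded grid by
per-label shape-based interpolation: consecutive-slice 2D signed distance
fields are blended linearly, and a label present on only one side tapers
out toward the far slice.  Plain shape interpolation can open gaps between
nuclei that touch across slices, so inside *between-nuclei regions*
(morphological closing of the foreground union minus the union; spherical
element of radius = expansion factor -- the smallest element that spans the
inserted slices) unfilled voxels are taken from nearest-neighbour
expansion instead.  Original slices are preserved exactly.

## The U-Nets

Masks and seeds are predicted by 2D or 3D U-Nets with five encoder blocks
(the fifth acting as the bottleneck) and four decoder blocks.  Filter
counts grow linearly -- 28k per encoder block k in 2D, 16k in 3D, with
28(5-k)/16(5-k) in the decoders -- which puts both variants at almost the
same capacity and makes the 2D-versus-3D comparison fair.  The filter
rule, 3x3(x3) kernels, 2x2(x1) pooling and the 3.3e6 / 3.2e6 parameter
totals are fixed design targets; the per-block layer count is the free
internal resolved so the instantiated networks land on those totals: six
conv+ReLU layers per block at levels 1-4 and in every decoder,
a two-conv bottleneck, transposed-convolution upsampling with a 3x3(x3)
kernel, and a per-voxel fully-connected output head (a 1x1(x1) convolution
with sigmoid).  This yields exactly 3,285,241 (2D) and 3,216,769 (3D)
trainable parameters.

The networks are implemented on a compact CPU engine written with numpy:
convolutions are one GEMM per kernel offset (avoiding im2col memory
blow-up), backprop is manual, optimisation is Adam.  Arrays are
channels-last; z is never pooled, so the 3D variant accepts any depth and
any in-plane size divisible by 16.

Training follows a fixed schedule: 200 epochs, batch 4 (3D) / 16 (2D),
binary cross-entropy, learning rate 1e-3 decayed to 2e-4 after epoch 75
and 1e-4 after epoch 110 (both factors relative to the initial rate);
on-the-fly axial rotations (uniform 0-360 deg, bilinear for intensities,
nearest for targets) hit 67% of batch samples and mirroring 50%, both as
per-sample Bernoulli draws; the checkpoint kept is the epoch with the
lowest validation loss.  Patches are min-max normalised to [0, 1]
individually (constant patches map to 0).  3D training windows are 24
slices with stride 12, zero-filled over the stack boundary; inference tiles
are non-overlapping except the final tile, which is shifted back to fit,
and overlapping probabilities are averaged.  Mask probabilities threshold
at 0.5 (ties foreground); seed probabilities are first multiplied by the
mask probability and then thresholded at 0.3, so predicted seeds can never
leave the predicted mask and small seeds survive the multiplication.

A boundary-weighted cross-entropy comparator (class weights 3/1 plus
`w0 exp(-(d1+d2)^2 / 2 sigma^2)`, w0=10, sigma=5, with d1/d2 the distances
to the two nearest nuclei) is available for the connected-component
instance baseline.

## Watershed methods

The flood relief is the negated Euclidean distance transform of the mask,
computed with spacings normalised to {1, 1, s_z/s_xy} and the
voxel-center-to-voxel-center convention (an isolated foreground voxel has
DT 1).  Three methods build markers:

* **A** `O = WS_m(M, CC(S))` -- connected components of the seeds;
* **B** `O = WS_h(M, h)` -- H-minima markers from the mask's own DT;
* **C** `O = WS_m(M, WS_h(S, h))` -- watershed twice: the H-minima
  watershed first labels the seeds, and that labelling seeds the flood of
  the mask.

All methods end by removing objects whose volume is <= 5% of the mean
object volume (strict "5% or less"), with labels re-compacted.

H-minima markers are the regional maxima of the reconstruction-by-dilation
of `DT - h` under `DT` (equivalently the H-minima transform of `-DT`),
restricted to the foreground.  The transform is evaluated geodesically
within each foreground component -- the background is held below every
foreground value during reconstruction -- so a component whose whole relief
is shallower than `h` keeps a single all-component marker rather than
dissolving into the background plateau.  Without this, marker counts are
not monotone in `h`: a fully flattened image turns every component into a
maximum again.  With it, the count is non-increasing in `h` and every mask
component stays represented.

The flood itself is a priority queue over the relief restricted to the
mask: voxels are processed in ascending (relief value, insertion age)
order, markers are pushed in raster order, each voxel is labelled by the
neighbour that first queued it, and there are no watershed lines.  Ties
are therefore fully specified and outputs are bit-reproducible; the
implementation (numba) is checked in the test suite against an independent
pure-python priority flood with the same documented policy, exactly, and
the DT and H-maxima stages against exhaustive-search and iterative-
reconstruction oracles.

## Choosing h

Methods B and C run over the fixed grid
{1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 4.0, 5.0} (the minimum corresponds
to one voxel on the normalised grid).  Each proposal is scored by the mean
object roundness

    phi_R = mean_i (36 pi V_i^2)^(1/3) / A_i,

the surface area of the equal-volume sphere over the object's surface
area; 1 for a perfect sphere, (pi/6)^(1/3) ~ 0.806 for a cube.  Surface
area comes from a marching-cubes mesh on the spacing-normalised grid --
voxel-face counting was rejected because it overestimates area by ~1.5x
and destroys the R ~ 1 calibration for spheres.  The proposal with the
highest phi_R wins; ties go to the smallest h (least suppression); an
empty proposal scores -inf.  The rationale: undersegmented clumps appear
as elongated, low-roundness objects, so roundness is a ground-truth-free
proxy for segmentation quality when nuclei are near-spherical.  When a
ground truth is available the same sweep can be scored with
(AJI + PQ + JI)/3 instead -- an oracle upper bound for quantifying what
the roundness heuristic gives away.

## Evaluation

Segmentations are collapsed to input space before scoring.  Matching for
panoptic quality uses strict IoU > 0.5 (pairs are then provably unique);
DQ = TP/(TP + (FP+FN)/2), SQ = mean matched IoU, PQ = DQ x SQ.  JI averages
each ground-truth nucleus's best IoU over all predictions (false positives
unpenalised); AJI consumes each prediction at most once, visiting
ground-truth nuclei in ascending label order (the known order dependence is
pinned by that fixed ordering), and adds unmatched prediction volumes to
the denominator.  NNDP = 2|S - G| / (S + G) x 100%.  Degenerate cases are
total and logged: both-empty scores PQ 1 and AJI 1; JI over an empty
ground truth is an error.

## Synthetic spheroids

The generator places randomly oriented ellipsoids (radius 7.5-10.5 px,
elongation up to 1.3x) on an isotropic grid at the in-plane resolution of a
128x128 field of view, blurs with a Gaussian PSF stand-in (sigma 1 px),
then subsamples z by the anisotropy ratio (3x by default) and adds Poisson
plus Gaussian (sd 3) sensor noise.  A `clumping` knob in [0, 1] mixes
uniform placement with attachment next to existing nuclei; interpenetration
is capped at 20% of the smaller radius scaled by clumping, and contested
voxels go to the earlier-placed nucleus, so the ground truth stays
well-defined.  Nucleus size was chosen to reproduce the proportions of
confocal HepG2 spheroids after resampling (nuclei tens of pixels across),
which also places seed-relief depths above the h grid's upper end.  The
default benchmark is 20 spheroids with 15-40 nuclei each (drawn
deterministically per volume seed 0-19) at clumping 0.5.

What the generator does not emulate: realistic PSF side lobes, intensity
texture within nuclei (optional speckle is off by default for
determinism), photobleaching, chromatic or stage drift, and non-ellipsoidal
nucleus shapes.  Tests passing on these phantoms therefore validate the
geometric machinery, not microscope-specific robustness.

## Problem sizes used in the checked examples

Oracle-equivalence suites run on random volumes up to 16^3 (exact
agreement; metrics to 1e-12).  The end-to-end benchmark uses the 20
default spheroids above with ground-truth-derived masks and seeds
(bypassing the CNNs) -- method C with roundness selection against the Otsu
+ method B traditional route.  The training smoke test overfits one
12x32x32 expanded phantom for 50 epochs with the full 3.2M-parameter 3D
architecture; the network is fully convolutional, so the small field of
view exercises the same weights as the 256x256x24 shape.

## Known limitations

* The roundness heuristic assumes near-spherical nuclei; strongly
  elongated or lobed nuclei depress phi_R for correct segmentations.
* AJI inherits the original formulation's visit-order dependence.
* The contour interpolation's closing radius (set to the expansion factor)
  is a heuristic; very thin gaps between nuclei on the same slice pair can
  still be bridged or missed near that scale.
* h is global; per-region h estimation is out of scope.
* The CPU engine trains small models in minutes but is not suited to
  full-scale 256x256x24 training runs; those need hours per model.
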