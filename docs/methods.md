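# Methods

`delicate` enhances time-lapse 3D fluorescence movies of labelled nuclei so
that downstream lineage tracers make fewer errors. This note documents the
model and every design decision a maintainer would want to audit: the
pipeline, the two segmentation backends, the synthetic embryo that serves as
the test bed, the evaluation machinery, and the numerical choices throughout.

## The enhancement pipeline

One time point of a movie is a stack of 2D focal planes with strongly
anisotropic voxels (fine in x/y, coarse in z). The pipeline runs four steps:

1. **Reconstruction.** The planes are assembled into an isotropic volume at a
   target spacing (0.18 µm by default; the tests and benchmark use 0.36 µm to
   match their coarser synthetic data). z is interpolated linearly between
   the two bracketing planes; x/y are resampled to the same spacing —
   area-average when coarsening, bilinear when refining. Linear (not spline)
   interpolation is used because it is monotone: it cannot overshoot and
   create spurious extrema that later thresholding would pick up. A
   `keep_xy` escape hatch leaves the native x/y grid untouched.
2. **Contrast refinement** (a segmentation aid only): intensities are mapped
   so that the 1st percentile → 0 and the 99.8th → 1, then clipped. A
   constant volume maps to zeros. These percentiles are the de-facto
   convention for this normalization style.
3. **Instance segmentation** into star-convex polyhedra (below), rasterized
   into "pseudo-nuclei": one uniformly shaped region per detected nucleus.
4. **Merge and reslice.** The merge operator Φ is exact and conservative:
   every voxel inside a pseudo-nucleus is set to the maximum raw intensity of
   the current time point's volume; every other voxel keeps its raw value
   bit-for-bit. Real signal therefore survives wherever segmentation fails.
   The merged volume is cut back to the original plane geometry and written
   with the input's dtype and naming convention, so the output is a drop-in
   replacement for the raw movie.

Two refinements to the merge are our own design choices:

* where two *different* instances touch, the one-voxel seam keeps its raw
  value, preserving the segmentor's instance separation in the painted
  image (otherwise adjacent nuclei would fuse into one uniform blob);
* instances may optionally be expanded by `expand_voxels` (default 0,
  instances never invade each other) to swallow the blur halo around a
  segmented core. The default is off because expansion trades image-level
  fidelity (the painted region overshoots the true nucleus) for
  detector-level convenience.

The fill intensity is the max over the current time point's reconstructed
volume — not per-slice and not global over the movie — so enhancement
strength adapts to bleaching.

## Star-convex geometry

A nucleus instance is a centre plus radial distances to the boundary along
64 fixed rays (a spherical Fibonacci lattice: deterministic, near-uniform).
Distances are in isotropic voxels; all star-convex operations require prior
reconstruction to isotropy, which avoids per-ray anisotropy bookkeeping.

* *Encoding*: for a voxel and a ray, march in quarter-voxel steps
  (nearest-voxel sampling) while the label stays the same; the boundary
  lies half a step past the last inside sample. Sub-voxel stepping keeps
  the per-ray distance error near 1/8 voxel.
* *Rasterization*: voxel v belongs to an instance iff |v − centre| is at
  most the instance radius in that direction, interpolated over the five
  nearest rays with angle-power weights. Interpolation smooths the
  voxelization wiggle of per-ray boundary estimates; with it, encoding a
  rendered sphere at its centre and rasterizing reproduces the sphere with
  Jaccard ≥ 0.95 down to radius 4 voxels, which nearest-ray lookup alone
  cannot reach. Contested voxels go to the higher-scoring instance; ties
  break by centre lexicographic order.
* *Overlap*: IoU of the two rasterized instances on a local grid.
* *NMS*: greedy by descending score; a candidate is accepted iff its IoU
  with every accepted instance is below the threshold (default 0.3).

## Segmentation backends

Both backends emit the same result contract (instances + rasterized label
volume), so the enhancer never branches on which produced a segmentation.

### Classical detector (deterministic, no training)

The default backend and the pipeline's workhorse at desk scale:

1. **Seeds.** Default: peaks of the Euclidean distance transform of
   thresholded masks at six levels between the mask fraction and 0.75.
   Multi-level EDT seeding is texture-blind (it sees only masks) and splits
   touching equal nuclei whose intensity profile has no usable minimum —
   the two failure modes that pure difference-of-Gaussians seeding (also
   available, `seed_method="dog"`) suffers from on uneven real-looking
   nuclei.
2. **Watershed** on the inverted smoothed intensity from those seeds,
   masked by a low intensity fraction.
3. **Half-max refinement.** Each region is trimmed at half its smoothed
   near-peak brightness, which tracks the blurred sphere's half-maximum
   boundary — approximately the true radius — instead of the blur halo.
4. **Fragment merging.** Two fragments whose centroids are closer than
   ~0.7× the sum of their equivalent-sphere radii are one nucleus
   (daughters are born about two radii apart, so real pairs are never
   merged); a 1.2 µm floor handles tiny fragments.
5. **Speck rejection.** Instances smaller than a sphere of 0.8× the minimum
   configured radius — by refined-region volume or by star-convex extent —
   are sub-nuclear debris (polar bodies, autofluorescent junk), not nuclei.

Each surviving region becomes a star-convex instance by encoding distances
at its centroid (snapped onto the region if the centroid falls outside).

### Star-convex network

A small 3D U-Net with residual blocks predicts a per-voxel objectness
probability and 64 ray distances. It is implemented directly on numpy:
same-padded convolutions via im2col + BLAS matmul, hand-derived backprop
(verified against central finite differences in the test suite), max
pooling, nearest-neighbour upsampling, and Adam with AMSGrad. Everything is
float32 and deterministic for a fixed seed.

Training minimizes `L = L_obj + η·L_dist` with `L_obj` the binary
cross-entropy of the objectness map and `L_dist` the mean absolute distance
error over foreground voxels — the established choices for this
architecture family; η defaults to 0.2. The reference schedule is 128³
crops, 400 epochs, batch 8, learning rate 5e-3, weight decay 1e-5,
augmentation by random flips and noise addition. The **desk preset**
(32³ crops, 2 pooling levels, 4 base channels, 30 epochs, 16 crops per
epoch) trains in ~3.5 minutes on one CPU with identical semantics. The
returned weights are the epoch snapshot with the smallest validation loss,
never the last epoch. Head biases are initialized to the priors
(background-dominated objectness; distances near a typical radius), which
removes most of the burn-in an untuned head would spend travelling to the
right output scale.

Inference: tiled forward passes (reflect-padded to the pooling multiple),
candidates = local maxima of the objectness map (5³ neighbourhood, capped
at the 256 strongest to bound NMS cost) above a threshold, greedy NMS,
then a centre-distance dedupe: two centres closer than the sum of the
instances' mean radii cannot be two real nuclei. The dedupe compensates for
radius underestimation by the desk-sized network; a fully trained network
would not need it, but it is harmless then. The probability threshold can
be auto-calibrated by scanning 0.10–0.90 in steps of 0.05 and keeping the
value with the best instance-level accuracy TP/(TP+FP+FN) on validation
volumes (ties go to the lower threshold).

## The synthetic embryo

The simulator is first-class code: it produces the ground truth (lineage
table + label volumes) and degraded movies that pose, at desk scale, the
same problems real embryo movies pose. Defaults define the **standard
benchmark** (canonical seed 0): a 36×128×128 grid at 0.72/0.36/0.36 µm,
10 time points, 8 founders growing to ≥32 cells, nucleus radii 1.8–2.8 µm.

Each degradation maps to a documented phenomenon of real movies:

| knob | default | emulates |
| --- | --- | --- |
| `dim_fraction`, `dim_factor` | 0.25, 0.3 | sublineage-specific low marker expression (false-negative calls) |
| `intensity_jitter_sd` | 0.3 | continuous cell-to-cell expression variability, inherited with noise at division |
| `bleach_rate` | 0.05/tp | photobleaching over the movie |
| `attenuation_rate` | 0.05/µm | depth-dependent light scattering (dim bottom layers) |
| `texture_sd`, `texture_scale_um` | 0.5, 0.8 | chromatin mottle inside nuclei (over-segmentation fodder) |
| `n_debris`, `debris_intensity` | 6, 2.5 | bright, compact polar-body-like specks near the surface that fixed-threshold detectors call as nuclei |
| `blur_sigma` | 0.3 µm | optical blur (Gaussian, isotropic) |
| `shot_noise_scale`, `read_noise_sd` | 0.01, 150 | photon and camera noise |

These defaults were calibrated by verifying that each mechanism produces
its intended failure mode in a fixed slice-based detector applied to the
raw movies — dim and deep cells drop out, near-threshold cells fragment
into extra calls, debris contributes a steady false-positive floor — i.e.
that the benchmark genuinely poses the problem the enhancement removes.
Divisions displace daughters by ±0.8·r along a random axis with
volume-conserving radii (r/2^{1/3}); overlapping rendered spheres resolve
to the nearest centre. One RNG stream per operation is derived from the
seed by fixed labels, so results are independent of call order.

What the simulator does **not** model: realistic lineage timing or naming
(no Sulston tree), cell membranes, non-Gaussian PSFs, sample drift, and
z-anisotropic optics beyond the coarse plane spacing. Passing tests
demonstrate that the pipeline removes the modelled degradations; they do
not certify performance on any particular real microscope.

## Evaluation

* **MSE** is the pixel mean of squared differences against a reference
  image. The reference renders ground-truth nuclei at the per-time-point
  raw volume maximum and background 0 — the ideal image the merge aims
  for, and the scale at which raw and enhanced are comparable.
* **SNR** is total intensity inside ground-truth nucleus regions over total
  intensity outside (flagged infinite when the outside is empty).
* **Detection metrics**: one-to-one greedy matching by ascending distance
  within a per-nucleus tolerance (the ground-truth radius by default,
  2 µm fallback). Greedy matching is deterministic and, verified in the
  suite, within 1% of the optimal assignment on random instances.
  Precision, recall, and accuracy = TP/(TP+FP+FN); there are no true
  negatives in nucleus detection.
* **SliceLinkTracer** is the fixed-configuration reference detector used
  for raw-vs-enhanced comparisons: per-plane 2D smoothed peaks above an
  *absolute* threshold, greedily linked across planes, with conditional
  suppression of peaks much dimmer than a close neighbour (a halo or cap
  artifact, never a comparable-brightness real pair). It deliberately
  reproduces how slice-based production tracers fail on raw movies, and is
  applied with identical settings to both movies.
* **Tracking**: greedy nearest-neighbour frame-to-frame linking; a track
  whose continuation leaves a second unclaimed detection within the
  division radius converts to a division; an unlinked track may claim two
  (division) or one (rescue). This extends the plain one-to-one rule,
  which by itself could never call a division whose nearer daughter was
  already claimed as a continuation.
* **Error taxonomy**: every traced-vs-truth discrepancy is assigned exactly
  one class — I over-segmentation division, II movement division (two
  non-sisters made a pair), III noise-born nucleus, IV missing division,
  V false death. Precedence III > I > II for spurious divisions. Class V
  requires that the matched ground-truth cell actually becomes undetected
  for ≥2 frames after the track ends; without this condition, the class-II
  scenario (whose displaced cell's old track necessarily ends) would be
  double-counted. "Adjacent" means within twice the matching tolerance.
  Counts are binned by ground-truth cell count at the error's time
  (0–160, 160–360, 360–550; boundary counts go to the later bin). The
  procedure is an operationalization of what is normally a curator's
  judgment; counts are comparable only within one version of it.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale: the
benchmark is 10 time points of a 36×128×128 grid, network training uses
eight 64³ volumes with the desk preset, and the tracer/backends operate at
0.36 µm isotropic spacing. Images are stored as unsigned 16-bit with a base
nucleus level of 10000 (headroom for noise before clipping); closed-form
intensity checks therefore hold to quantization (one grey level), not to
machine precision. Degenerate inputs are defined rather than rejected:
constant volumes normalize to zero, empty candidate sets rasterize to empty
labels, zero denominators in precision/recall/accuracy yield 0, and an
empty SNR denominator reports infinity.

Known limitations: the desk-sized network underestimates radial distances
(compensated at inference by the centre dedupe); the classical backend's
fragment merging can, in principle, swallow a genuinely adjacent pair
closer than ~1.4× a radius sum; and the error-class decision procedure,
like any operationalization of curator judgment, draws sharp lines through
genuinely ambiguous cases. Directional benchmark results (enhanced better
than raw) are robust across seeds; individual per-time-point metrics are
not guaranteed for every random draw.
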