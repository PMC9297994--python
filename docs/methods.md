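# Methods

`sinter4d` quantifies viscous-flow sintering inside direct-ink-written
(DIW) glass or ceramic scaffolds from a time series of 3D micro-CT
reconstructions ("4D" data). This note describes the analysis chain, the
synthetic phantom that stands in for scan data, the numerical choices, and
the limits of what the bundled validation demonstrates.

## The analysis chain

A DIW scaffold is a woodpile: layers of parallel cylindrical struts,
alternating orientation between layers, printed with a z layer spacing
smaller than the strut diameter so consecutive layers interpenetrate
(strut overlap = diameter − spacing). During sintering the glass particles
inside each strut densify and the whole scaffold shrinks, so any
volume of interest (VOI) drifts through the image over time. The pipeline
processes each scan in time order:

1. **Preprocessing** (`preprocess`). Raw reconstructions are linearly
   rescaled to 8 bits (per volume, min–max, round half up), rotated about z
   so strut axes align with the image axes (fixed angle, or estimated by
   maximizing the variance of axis-projected intensity sums over an angle
   grid), cropped, and downsampled by 0.25 per axis with block local means.
   Block means (not nearest neighbor) suppress noise before macroscale
   detection; the voxel size is divided by the factor.
2. **VOI detection** (`voi_tracking`). An RBF-kernel SVM over cheap
   per-slice features (normalized 32-bin histogram, Otsu foreground
   fraction, mean, std, histogram entropy) flags the coarse z-slices that
   show clean strut cross-sections. Flag sequences are cleaned by a run
   filter (fill gaps ≤ 2 slices, drop runs < 3). A morphological
   Chan-Vese level set segments the cross-sections in each flagged slice;
   stacking the masks and labeling 26-connected components (small
   components removed) yields one component per strut segment, whose
   unweighted centroid — converted back to full resolution by dividing by
   the resampling factor — is the VOI center.
3. **Tracking** (`voi_tracking`). Centers of consecutive time points are
   linked by the exact minimum-total-Euclidean-distance assignment under a
   displacement cap (default 20 full-resolution voxels per step), solved as
   a linear assignment on a padded cost matrix. The result maximizes the
   number of links within the cap, then minimizes total distance; on small
   instances it provably equals exhaustive enumeration, which the tests
   assert. Links are chained into persistent tracks ("hyperstacks": one
   tracked VOI's sub-volumes over the series). The analysed subset is the
   `n_select` (default 3) tracks whose first centers lie closest to the
   scaffold centroid — a deterministic stand-in for a manual choice.
4. **Glass-phase segmentation** (`segmentation`). Inside each selected
   VOI's densification child volume (denoised by non-local means; compact
   patch radius 1 / search radius 3 in the pipeline), the glassy phase is
   segmented by a 200-tree random forest over a 77-attribute multi-scale
   feature bank while densification is below 90%, and by global Otsu
   thresholding after the running density estimate has been ≥ 90% for two
   consecutive time points (hysteresis; the switch is permanent). The
   feature bank (per 2D slice, scales σ ∈ {1,2,4,8}): raw intensity (1),
   Gaussian blur (4), difference of Gaussians over all scale pairs (6),
   Sobel magnitude of the blurred image (4), Hessian eigenvalues +
   determinant (12), oriented first-derivative-of-Gaussian filters at 10
   orientations × 5 scales {1,1.5,2,3,4} (50). Forest: features per split
   = √77, unlimited depth, out-of-bag scoring, fixed seed.
5. **Strut outline** (`segmentation.segment_strut_levelset`). Per slice of
   the thin diameter child volume (used raw — the estimator smooths
   internally): light Gaussian pre-smoothing (σ = 1), Chan-Vese evolution
   to convergence with the curvature-smoothing term off, removal of
   speckle regions < 25 px, union of the remaining regions, hole filling,
   and the convex hull. Curvature smoothing is off because curvature flow
   systematically erodes convex boundaries (a measurable diameter bias);
   the hull supplies the shape regularity instead, encoding the prior that
   a printed strut cross-section is convex, and restores the envelope
   across particle-scale surface dimples. Keeping all significant regions
   (rather than the largest) makes the estimate robust when noise splits
   the porous cross-section into lobes.
6. **Quantification** (`quantify`). Intrastrut porosity =
   pore/(pore+glass)×100 and relative density = 100 − porosity (they sum
   to 100 exactly). Strut diameter per slice = 2·√(area/π) assuming a
   circular cross-section; the per-VOI mean over slices, averaged over
   VOIs, is rounded to the nearest integer pixel before multiplying by the
   voxel size (0.81 µm by default) — rounding applies to the reported
   averages, not per-slice values. Pore diagonal distance (PDD) = rounded
   in-plane distance between diagonal-neighbor strut centers × voxel size −
   strut diameter; the analysed pairs are the shortest diagonal-neighbor
   pairs (offset in both in-plane axes, same z-run), tie-broken toward the
   scaffold centroid. Isotropic volume shrinkage = 1 − (1 − s)³ for linear
   shrinkage s; measured volume shrinkage = 1 − V_after/V_before from
   bounding boxes. Rows are labeled with the classical sintering stages:
   intermediate begins at the first sustained rise (two consecutive
   scan-to-scan increases ≥ 1 pp), final at the first crossing of 90%
   density. These landmarks are conventions from classical sintering
   theory and are reported as derived annotations, not claims.

## The synthetic phantom

`phantom` generates ground-truthed stand-ins for scan data, at the
default scale of a 512 × 512 × 400-voxel corner of a scaffold (tracked
struts along z, 4 struts/layer × 8 layers, pitch 112 vx, layer spacing 40
vx, strut diameter 48 vx → overlap 8 vx, 48 trackable strut segments).

* **Green body.** Each strut is packed with spheres (log-normal radii,
  clipped to [2.5, 9] vx, median 4.5) accepted when no earlier sphere is
  closer than 0.5·(r₁+r₂) — bounded overlap keeps the texture granular but
  connected. Candidates are sampled well past the cylinder wall and the
  raster clipped to it, so the fill is radially uniform; packing stops per
  strut when the *measured* voxel fill reaches the target (55%). A 1.5 px
  continuous skin at the wall mimics the smooth nozzle-formed surface of
  an extruded paste; without it the green strut has no well-defined outer
  envelope to measure.
* **Sintering.** Per time point t, geometry contracts affinely toward the
  scaffold centroid (per-axis linear shrinkage schedule, default 15% in
  y/x and 8% in z by the end — anisotropic on purpose), and the particle
  indicator is smoothed with a growing Gaussian (σ: 0.6 → 5 vx) and
  re-thresholded at the quantile that puts the programmed glass fraction
  (logistic 55 → 95% over 20 points) on the strut-core support. This is a
  geometric, not physical, densification: it reproduces the observable
  stage progression (neck growth, pore isolation, pore elimination) with
  exact density control, and the pipeline under test is agnostic to the
  driving mechanism. The core support is the strut interior (radius ≤
  r/√2, away from layer crossings where two packings meet), i.e. the
  region a densification child volume samples.
* **Imaging.** Two-level intensity (glass 180, background 60), Gaussian
  PSF blur (σ = 1), additive Gaussian noise (σ = 15), 8-bit clipping. At
  these defaults the glass and pore intensity histograms overlap, which is
  precisely the regime where thresholding degrades and the trainable
  segmenter earns its keep.

Everything is deterministic under the mandatory seed (per-time-point noise
streams are derived from (seed, t), so lazy and materialized rendering
agree).

### What the phantom does and does not emulate

It reproduces: granular strut texture with interconnected → isolated →
vanishing pores, overlapping class histograms, anisotropic shrinkage-driven
VOI drift, woodpile geometry with strut overlap. It does not reproduce:
angular particle shapes, reconstruction artifacts (rings, beam hardening,
streaks), intensity drift between scans, deformable (non-affine) motion,
or real sintering kinetics. Passing the phantom suite therefore validates
the pipeline's detection/tracking/segmentation/quantification logic under
realistic noise and drift — not its robustness to tomographic artifacts.

### Finite-particle heterogeneity and how recovery is scored

With ~450-voxel particles, the true glass fraction inside a scaled
densification child (32 × 24 × 24 vx) fluctuates several percentage points
around the strut-wide programme — real spatial heterogeneity, not error.
Density recovery is therefore scored against the true glass fraction
inside the same child volumes the pipeline measured
(`truth_voi_density_pct`); the truth report separately certifies that the
core-wide density follows the programme and is monotone. Diameter and PDD
truths are analytic (scaled cylinder diameter and lattice diagonal), so
they are compared directly.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| voxel size | 0.81 | µm/vx | detector scale of the target instrument |
| resample factor | 0.25 | — | coarse detection scale; shape = floor(n·f) |
| n_select | 3 | VOIs | analysed subset size |
| displacement cap | 20 | vx/step | max credible shrinkage drift per scan |
| segmenter switch | 90 (2-point hysteresis) | % density | histogram becomes bimodal; Otsu suffices |
| forest | 200 trees, √77 features/split | — | trainable-segmentation convention |
| NLM (children) | patch r 1, search r 3, h = 0.8·σ̂ | vx | compact neighborhood; σ̂ wavelet-estimated |
| level-set | 200 iter max, checkerboard init, smoothing 1 | — | morphological Chan-Vese |
| blank-slice gate | class-mean contrast < 40 | 8-bit levels | Otsu split of pure noise stays below this |
| min component size | 500 (full scale) | coarse vx | rejects sub-strut debris; scales with geometry |
| stage cutoffs | rise ≥ 1 pp/scan ×2; final ≥ 90% | — | classical-theory landmarks |

VOI extents default to the full-scale values (parent 330 × 306 × 70,
densification child 150 × 140 × 70, diameter child 330 × 306 × 10, all
(z,y,x) = (70,330,306) etc. in axis order); phantom runs scale them with
the phantom's strut diameter (parent (48,64,64), densification child
(32,24,24), diameter child (10,64,64)).

## Numerical choices and degenerate inputs

* 8-bit conversion and histogram equalization are monotone maps; constant
  volumes map to zero with a warning. Equalization is available but off by
  default in the segmentation path: on strongly bimodal synthetic contrast
  it only distorts the threshold (it is meant for low-contrast scans).
* Otsu foreground is `v > t`, `t` from 256-bin between-class-variance
  maximization; the tests pin it to an exhaustive 256-threshold search.
  `segment_glass_otsu` additionally guards the single-phase case: Otsu
  always produces a split, so when the class means of a fully densified
  (pore-free) VOI differ by less than 40 levels the volume is labeled
  all-glass or all-pore by its mean, instead of carving the noise in half.
* Slice-classification runs are edge-trimmed (2 slices at full scale,
  scaled with the gap length): the classifier is least reliable right at
  the transition out of a strut-crossing region, and a single contaminated
  edge slice can fuse neighboring strut segments during 3D labeling.
* The phantom's true strut diameter is reported from the voxel-aligned
  raster (equivalent-circle diameter of the rasterized cross-section at
  the segment slices), which is what a voxel-counting measurement can
  recover; the analytic lattice diameter differs from it by sub-voxel
  rasterization effects.
* Ties in tracking costs are broken by the assignment solver; matchings
  are compared to the brute-force oracle on continuous random instances
  where ties have probability zero.
* `extract_voi` boxes are centered, half-open, zero-padded at borders with
  a `clipped` flag; centers outside the volume raise.
* Empty diameter-child slices are excluded from the slice mean with a
  warning; an all-empty child warns and yields diameter 0.
* Level-set non-convergence within 200 iterations returns the best iterate
  with a warning (convergence is detected by an unchanged mask between
  evolution chunks).

## Problem sizes used by the bundled validation

The test suite exercises small phantoms (≈160 × 128 × 96 voxels, 5 time
points) for module-level checks, and one default full-scale series
(512 × 512 × 400, 20 time points, 48 segments) for the end-to-end
recovery suite; `scripts/acceptance.py` re-runs the same full-scale
analysis from scratch. The full-size acquisition geometry (2560³ raw
grids) is supported by the same code paths but not exercised by tests.

## Known limitations

* Strut diameter relies on a convexity prior; struts with genuinely
  concave cross-sections would be over-measured.
* The diameter child window is assumed to contain a single strut; a
  neighbor inside the window could inflate the convex hull.
* Tracking is rigid (center linking); sub-voxel registration and
  deformable motion are out of scope.
* The slice classifier is trained per dataset (here, from phantom truth);
  no pretrained model ships with the package.
* Physics-based shrinkage prediction (Frenkel / Mackenzie–Shuttleworth
  kinetics) is out of scope; stages are annotated, not modeled.
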