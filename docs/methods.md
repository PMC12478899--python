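# Methods

`sensillum3d` measures how the cuticular sensilla inside the *Drosophila*
antennal sacculus change shape with ambient humidity, starting from serial
block-face SEM (SBF-SEM) section stacks and ending in per-chamber statistics.
Because the SBF-SEM volumes the method was developed on are not publicly
deposited, the package ships a synthetic phantom generator that reproduces the
statistical structure every downstream stage assumes; all tests and the
reproduction script run against phantoms with known ground truth.

## The measurement chain

1. **Harmonization** (`harmonize`). An interrupted acquisition resumed after
   repositioning yields two sub-stacks with different XY pixel sizes
   (10.3760 nm vs 14.6484 nm in the high-humidity dataset) and an unknown XY
   offset. The second set is resampled by the pixel-size ratio
   (`skimage.transform.rescale`, anti-aliased), cropped/padded to the first
   set's canvas (top-left anchor, zero fill), and the offset is estimated once
   from the boundary pair — last section of set 1 against the first rescaled
   section of set 2 — by phase cross-correlation with 10× upsampled subpixel
   refinement. The same correction is applied to every set-2 section through a
   Fourier-domain phase ramp, and the merged stack is min–max normalized to
   0–255 globally (per stack, not per section, so inter-section contrast is
   preserved).

   *Numerical choice*: the correlation uses the unwhitened cross-power
   spectrum (`normalization=None`). The fully whitened ("phase") variant
   weights all frequencies equally, which on smooth, band-limited section
   images lets resampling artifacts dominate the peak; we measured up to 1 px
   of error on phantoms, against ≤ 0.1 px unwhitened. The Fourier shift wraps
   periodically; wrapped margins are logged, not masked.

2. **Segmentation** (`segment`). Sections are resized to a square model
   resolution, scaled to [0, 1], and split 90:5:5 into train/test/validation
   by largest-remainder apportionment (337 labelled images split exactly
   303/17/17). Each training image contributes four augmented variants —
   vertical flip, horizontal flip, 45° and 130° rotations about the center —
   and augmented copies always follow their parent into the same split, so no
   augmented twin of a validation image leaks into training (a flag restores
   split-after-augmentation). The segmentation network is an encoder–decoder
   with skip connections implemented directly in numpy (im2col convolutions
   with hand-derived backward passes, verified against finite differences in
   the test suite), trained with Adam on binary cross-entropy. The epoch with
   the best validation IoU is checkpointed; the learning rate halves when the
   validation loss plateaus for 3 epochs. Accuracy is reported but IoU governs
   model selection, since the structure of interest is small relative to the
   background. A deterministic threshold fallback (`mask = image > level`)
   makes every downstream stage testable without training.

3. **Reconstruction** (`reconstruct`). Each mask section yields its complete
   contour nesting tree: `skimage.measure.find_contours` on the zero-padded
   mask (padding closes border-touching regions), with containment depths
   computed through shapely point-in-polygon tests. Both outer and hole
   boundaries contribute points, as the sensilla are wall structures inside
   the sacculus lumen (a flag drops holes). A contour vertex `(row, col)` at
   section `z` maps to physical µm as `x = col·s·pixel_x`,
   `y = row·s·pixel_y`, `z = z_index·slice_z`, where `s` is the ratio of
   section width to mask width — mask-resolution rescaling is a coordinate
   factor, never a second image resampling. Coordinates are 0-based with the
   origin at the top-left pixel corner. Sensilla are cut out of the sacculus
   cloud by axis-aligned crop boxes read from JSON, replacing interactive
   cropping with a declarative, reproducible input.

4. **Alignment** (`align`). Width profiles are only comparable if every
   sensillum points along +Z. Elongated sensilla (chambers 1 and 3) are
   oriented by PCA: the covariance eigenvector with the largest eigenvalue is
   the length axis and is rotated onto +Z by the minimal rotation. Because
   eigenvectors carry no sign, the base is identified by comparing the mean
   radial extent of the bottom- and top-quartile z slabs; the wider end goes
   to low z. PCA is only trusted when λ₁/λ₂ ≥ 1.5; below that (the squat
   chamber-2 morphology, where height ≈ width) the cloud is registered to a
   synthetic cone target instead: both clouds are voxel-downsampled, surface
   normals estimated by local PCA (oriented away from the centroid),
   per-point histograms of the three Darboux-frame angles computed over
   k = 12 neighbours (3 × 11 bins), and RANSAC samples 3-point correspondence
   subsets in feature space, scoring each rigid hypothesis by
   nearest-neighbour inliers against the target and re-estimating from all
   inliers of the winner. All transforms are strictly rigid and are appended
   to the cloud's provenance, so the aligned cloud is exactly reproducible
   from the raw crop.

   *Numerical choices*: the downsampling voxel defaults to 4% of the moving
   cloud's bounding-box diagonal. Reconstructed clouds are stacks of
   per-section contour rings; a finer voxel preserves that ring anisotropy,
   normal estimates degrade, and squat-cone registration fails (measured axis
   errors up to 120° at 2%, ≤ 7° at 4%). The RANSAC inlier distance is 1.5×
   the voxel; registration is seeded and the seed is recorded. Cone-target
   dimensions default to the median bounding-box dimensions of the chamber's
   crops. Below fitness 0.2 the cloud is returned untransformed and flagged.

5. **Width profiling** (`morpho`). The aligned cloud is triangulated (3D
   Delaunay; the boundary faces — those belonging to exactly one tetrahedron —
   form the surface) and sliced at `n_slices` (default 100) uniform heights
   spanning the z range. Width at a height is the maximum pairwise XY distance
   among the mesh–plane intersection vertices; true mesh–plane intersection is
   used rather than point slabs because it is robust to uneven point density.
   The two boundary levels pass exactly through the mesh's extreme vertices,
   where a plane cuts only a degenerate sliver, so their widths are linearly
   extrapolated from the two nearest interior slices (exact for a linear
   taper, constant for a prism). Interior empty cross-sections (mesh gaps) are
   filled by interpolation and flagged. Profiles are smoothed with a
   triangular-weighted moving average (weights 1,2,…,k,…,2,1; window 5 by
   default; truncated and renormalized at the edges; a flag switches to
   uniform weights).

   The per-sensillum summary statistic is the **width at half the total
   height**, here called FWHM following this field's usage. Note this is
   *not* the conventional full-width-at-half-maximum of a peaked curve: it is
   the profile width evaluated at `z_min + (z_max − z_min)/2`, linearly
   interpolated between the bracketing samples.

6. **Statistics** (`stats`). Per chamber, width is modelled as a linear mixed
   model, `width ~ group + height + height:group`, with a random intercept per
   sensillum, fitted by REML (statsmodels `MixedLM`). The per-group taper
   slopes are the reference `height` coefficient and its sum with the
   interaction; 95% CIs and prediction bands come from the fixed-effects
   covariance (random-effect uncertainty excluded — the CI describes the mean
   profile, not a new sensillum). Chambers are fitted independently. The
   random effect is an intercept only, since it models baseline width
   differences between sensilla; a flag enables random slopes. Half-height
   width distributions are compared with a two-sided Mann–Whitney U test,
   exact when both groups have ≤ 8 tie-free observations, otherwise the
   normal approximation with tie correction.

## The phantom generator

`synthgen` emulates three things the analysis needs:

* **Cone-surface point clouds** with base width w₀, height H and taper slope
  m ≤ 0, so the analytic width w(z) = max(w₀ + m·z, 0) is available as an
  oracle at every height. Points are sampled uniformly *by lateral area* (the
  height density is proportional to the local radius), mimicking
  cuticle-surface contours where slice point density is roughly constant;
  isotropic Gaussian jitter models segmentation noise.
* **Voxelized stacks**: a voxel is foreground iff its center lies inside some
  cone — an unambiguous rule a brute-force oracle can recheck voxel by voxel.
  Images are foreground/background levels plus additive Gaussian noise,
  clipped to [0, 255]; labels are the exact noise-free occupancy. The
  split-resolution pair emulates the interrupted high-humidity acquisition:
  sections after the break are resampled to a coarser pixel size and
  translated by a known subpixel offset, recorded for recovery tests.
* **Profile tables** drawn from the exact mixed model the statistics stage
  fits: width = intercept(group) + slope(group)·height + b(sensillum) + ε.

Default cone dimensions follow the reported morphology: chamber-1 base widths
3.36 µm (high RH) and 2.59 µm (low RH) with taper slopes −0.472/−0.403,
chamber 2 −0.959/−1.120, chamber 3 −0.541/−0.652 (µm width per µm height,
used directly as d(width)/d(height)). Sensilla heights are not reported, so
the default closes each cone to a point: H = w₀/|m|, giving ≈ 7.1/6.4 µm
(chamber 1), 3.4/2.4 µm (chamber 2, squat as described) and 5.9/3.9 µm
(chamber 3). With full cones the half-height width is exactly w₀/2, so the
default cohorts reproduce the reported half-height differences (≈ 0.39 µm in
chamber 1, 0.33 µm in chambers 2–3) without further tuning. Per-sensillum
base-width variability defaults to SD 0.13 µm, the reported chamber-1 spread.
All generators are pure functions of (spec, seed).

**What the phantoms do not model**: EM texture, membranes and organelles,
beam and charging artifacts, section-to-section drift, non-conical sensillum
shapes, or curvature of the sensillum axis. Passing tests therefore
demonstrate that the *computational chain* is correct and well-calibrated on
geometry satisfying its assumptions — not that segmentation of real cuticle
at IoU 0.85 is achievable, which depends on training data quality.

## Problem sizes and calibration checks

The test suite and the reproduction script (`scripts/acceptance.py`) use
desk-scale problem sizes chosen to exercise every code path: phantom stacks
of ~50 sections at 64–96² pixels (200 nm XY / 150 nm Z voxels), cohorts of
12–24 sensilla per condition, 100-replicate simulations for coverage and
power, 200 for null calibration. The end-to-end demo
(2 conditions × 3 chambers × 4 sensilla) runs in well under a minute.

Calibration facts the suite asserts: the mixed-model slope CIs match the
closed-form balanced-design standard error (and lme4 with Kenward–Roger
degrees of freedom agrees to three decimals); each slope's 95% CI covers the
generating value in ≈ 95 of 100 replicates (the joint two-slope event runs at
the expected ≈ 0.95² and is reported alongside); Mann–Whitney p-values are
uniform under the null (KS test, α = 0.01, with the mild conservatism of a
discrete U distribution at n = 10/10); and a 0.4 µm half-height shift at
SD 0.1 µm, n = 10/10, is detected essentially always.

## Known limitations

* The numpy network trains desk-scale models (tens of thousands of
  parameters) in minutes on one CPU; it is not a general-purpose deep
  learning stack and has no GPU path.
* PCA orientation assumes one dominant elongation axis; strongly curved
  sensilla would violate the linear-axis assumption of the whole width
  profile, not just the alignment.
* Registration assumes approximate shape agreement between moving cloud and
  target; a cone target cannot correct for a sensillum whose taper is far
  from conical.
* The voxelized apex of a pointed cone vanishes where the width drops below
  one pixel diagonal, so reconstructed heights are slightly short and the
  measured half-height width correspondingly slightly wide; differences
  between conditions are much less affected than absolute values.
* Mann–Whitney exact p-values are discrete at small n; the reported
  significance stars inherit that granularity (smallest attainable two-sided
  p at n = 4/4 is 0.029).
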