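# Methods

## Problem and pipeline overview

In the two-cell *C. elegans* embryo the anterior AB blastomere is larger
and divides before the posterior P1 blastomere. Several replication
factors (SLD-2, SLD-3) accumulate asymmetrically in the two nuclei, and
the biological readouts of interest are (i) the P1/AB ratio of
background-corrected nuclear fluorescence, (ii) traces of nuclear and
cytoplasmic signal over time, and (iii) cell-cycle lengths measured from
pronuclei fusion to nuclear-envelope breakdown (NEB) of each cell.

The pipeline works per frame of a 5D (T, Z, C, Y, X) movie with one
fluorescence and one DIC channel:

1. **Focus selection.** Each channel's best-focused z-slice is the one
   maximizing the variance of the 3×3 Laplacian response. The metric is
   parameter-free, invariant to brightness offsets, and decreases
   monotonically under Gaussian defocus on textured images. DIC drives
   the segmentation slice; fluorescence drives the measurement slice.
2. **Embryo mapping (DIC).** DIC shows fine intracellular texture inside
   the embryo over a smooth background, so the embryo is the region of
   high local intensity variance: a (2r+1)² windowed population standard
   deviation (r = 2 px, reflect padding), Gaussian-smoothed (σ = 4 px),
   thresholded by Otsu's criterion on the 8-bit-quantized map, holes
   filled, largest 4-connected component kept. A run fails loudly
   (`SegmentationFailure`) when the foreground/background texture
   contrast is < 2× or the largest component is < 5% of the frame —
   pure-noise frames have no embryo.
3. **Cell split.** The embryo outline is divided into two cells by a
   distance-transform watershed seeded at the two strongest internal
   maxima of the smoothed distance map (minimum peak separation adapts
   to mask size: max(10, 0.25·√area) px). Watershed applies only when
   the outline has concave features; convex outlines are divided by the
   line through the centroid along the minor axis of the moment-fitted
   ellipse. The larger region is named AB, the smaller P1; an exact area
   tie falls to the leftmost region (anterior-left mounting convention,
   configurable).
4. **Nucleus detection (fluorescence).** Nuclei are segmented from the
   maximum-intensity z-projection with a difference-of-Gaussians
   band-pass (σ = 2, 8 px for ~6–12 px nuclei) followed by Kapur's
   maximum-entropy threshold, computed per cell on the 8-bit-quantized
   DoG histogram of that cell's interior (the interior excludes a
   boundary band one large-σ wide where the cell edge produces its own
   DoG response). Components pass a size gate of 25–400% of the expected
   nucleus area and a contrast gate (component mean ≥ 4 robust-σ above
   the in-cell median); each cell keeps its largest survivor. A cell
   with no survivor has no nucleus — that is the NEB signal, not an
   error.
5. **Quantification.** Background is the median intensity outside the
   3-px-dilated embryo mask (median for robustness to stray debris).
   Nuclear signal is the background-corrected mean over the eroded core
   (3 px) of the detected nucleus mask; the erosion discards the
   partial-volume halo of cytoplasm-level boundary pixels that would
   otherwise dilute the mean. Cytoplasmic signal is the corrected mean
   over the cell minus the full detected nucleus; after NEB it covers
   the whole cell, since the protein is then entirely cytoplasmic.
   Integrated intensities are emitted alongside means.
6. **Timing.** NEB is the first frame of the first run of nucleus
   absence lasting ≥ 2 consecutive frames (the persistence suppresses
   single-frame segmentation dropouts); a contrast-threshold criterion
   is available for traces that are continuous rather than boolean.
   Cycle lengths are (NEB − fusion) × frame interval, with the fusion
   frame supplied as an annotation — operators score pronuclei fusion
   visually, and one-cell-stage segmentation is out of scope. The AB→P1
   NEB delay may be negative; no ordering is assumed.
7. **Statistics.** Group comparisons use the Mann–Whitney–Wilcoxon test
   with midranks; for n₁+n₂ ≤ 12 the p-value is exact, by enumeration of
   all C(n₁+n₂, n₁) group assignments (an exact permutation test with or
   without ties); larger samples use the normal approximation with
   tie-corrected variance and continuity correction. Two-sided exact
   p-values use the doubling convention min(1, 2·min(tails)). Paired
   designs use Student's paired t; interval summaries are t-based 95%
   CIs. Exact and approximate rank-sum p-values agree within 0.02 at
   n₁ = n₂ = 6.

## Key normalized quantities

- **P1/AB ratio** — per embryo, mean P1 nuclear signal over the frames
  before AB NEB in which both nuclei are present, divided by the same
  mean for AB; cohorts report the mean of per-embryo ratios with a 95%
  CI. A whole-cell variant is available by config flag since mean
  nuclear vs whole-cell pooling is a reporting choice.
- **AB-cytoplasm reference** — each embryo's values divided by its own
  AB cytoplasmic signal, then the cohort rescaled so a designated
  reference group's mean AB nuclear value is 1.
- **Named-cell reference** — per-cell values divided by the embryo's
  named reference cell (e.g. ABa at the four-cell stage; four-cell
  label maps are supplied externally, not segmented here).

All normalized outputs are invariant to affine changes of the camera
scale: offsets cancel in background correction, gains cancel in the
ratios.

## Synthetic embryo movies

The generator renders the statistical structure the pipeline assumes —
it is the test bed standing in for undeposited microscopy data, not an
optics simulation. A movie is two abutting ellipses (AB strictly larger
than P1, overlap pixels assigned to the nearer centre, so the contact
boundary is flattened), disk nuclei at the cell centres, and
piecewise-constant fluorescence levels background < cytoplasm <
nucleus. Each z-slice is the focal scene blurred with σ =
|z − focal_z|·σ_defocus plus iid Gaussian noise; the DIC channel is a
smoothed-noise texture inside the embryo over a flat background. NEB is
rendered by replacing a nucleus with cytoplasm level from its NEB frame
onward. Ground truth (masks, true means, NEB frames, true ratio) is
recorded as rendered.

Default study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| frame interval | 8 s | the interval used for cell-cycle timing movies |
| image | 150×230 px, 5 z, 30 frames | ~50 µm embryo at 0.2 µm/px, 60× objective scale |
| AB / P1 semi-axes | 55×62 / 45×48 px | AB visibly larger, areas ~10,700 / ~6,800 px² |
| nucleus radii | 11 / 9 px | interphase nuclei, AB slightly larger |
| intensities | 100 / 300 / 900 AU | background / cytoplasm / AB nucleus, well inside uint16 |
| asymmetry ratio | 0.6 | wild-type-like P1/AB for an asymmetric factor |
| noise σ | 20 AU | SNR typical of live confocal GFP at short exposure |
| defocus | 2 px per z-step | visible blur one step off focus |
| DIC texture | grain 1 px, σ 200 AU | gives ≥5× in/out local-std contrast, the premise DIC mapping needs |
| NEB frames | AB 22, P1 26 | AB first; 32 s delay at 8 s/frame |

The P1 nuclear level is derived as background + ratio·(AB nuclear −
background), so the true ratio is defined on background-corrected
means — the same scale the pipeline reports — and is exact by
construction. With noise off, the focal slice reproduces every true
mean exactly.

One RNG stream per movie (NumPy PCG64 from the seed) in a documented
order — DIC texture field first, then per frame/z/channel noise
fields — makes regeneration bit-stable. Named presets: `asym04`,
`asym06`, `symmetric`, `fallback_convex` (convex hull outline,
near-equal cells, exercises the minor-axis fallback), `noisefree`.

What the generator does **not** emulate: photobleaching, cell movement
and shape change over time, optics-accurate PSFs, Poisson photon
statistics (additive Gaussian noise was chosen so expected means have
closed form), mitotic chromatin, four-cell scenes. Passing recovery
tests therefore demonstrates correctness of the measurement chain under
the stated model, not robustness to every property of real movies.

## Numerical choices and calibrations

- **Quantized thresholds.** Otsu and Kapur operate on 256-bin histograms
  of min-max-rescaled images; entropy thresholds are bin-sensitive, and
  fixing the binning makes results reproducible across dynamic ranges.
  Ties resolve to the lowest threshold; "foreground" is strictly above.
- **Solidity test for "concave features".** Solidity (area / convex-hull
  area) is measured after a morphological closing (radius 5) so the
  test responds to shape, not boundary roughness; the watershed applies
  below 0.92. Calibration: thresholded outlines lose ~0.04–0.06
  solidity to boundary wobble, putting truly convex outlines at
  ~0.93–0.97 and necked/peanut outlines at ≤ 0.89. A watershed result
  is also rejected (fallback engaged) when it yields fewer than two
  regions or a region under 20% of the mask.
- **Mask cleanup.** Fill-holes then keep-largest-component; no opening
  by default — an opening can sever the thin thresholded contact neck
  and cut the embryo in two (a radius parameter re-enables it).
- **Per-cell Kapur threshold.** A single global entropy threshold locks
  onto the brighter nucleus and misses the dimmer one once P1/AB ≤ ~0.5;
  thresholding each cell's own DoG histogram keeps detection monotone in
  contrast down to ratio 0.4 and below.
- **Nuclear-core erosion (3 px).** Removes the threshold boundary halo;
  without it the measured AB nuclear mean is biased ~10% low and the
  measured ratio ~0.1 high. If erosion would empty a small mask, the
  full mask is used.
- **Degenerate inputs.** Constant images: focus score 0, local-std map
  0, thresholds raise `DegenerateHistogram`. Full-frame embryo masks:
  `BackgroundUnavailable`. All-identical paired differences:
  `DegenerateInput`. A frame-level segmentation failure skips the frame
  with a logged warning and leaves a gap in the traces — never silent
  interpolation.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate on synthetic data
at the default conditions with these sizes: 200 random histograms for
the threshold oracles; 50 images (32×32) for the local-std oracle; 50
single-frame embryos for segmentation recovery (cell IoU ≥ 0.8,
nucleus IoU ≥ 0.7); cohorts of 20 three-frame embryos at true ratios
0.4 / 0.6 / 1.0 for ratio recovery (±0.05); 20 full 30-frame movies for
NEB timing (±1 frame); 100 replicates of 10-embryo cohorts for
discrimination power (rank-sum p < 0.01 asymmetric vs symmetric) and
false-positive rate (p < 0.05, symmetric vs symmetric). Short movies
are used where a single frame already carries the quantity under test.

## Known limitations

- Cells are static in the synthetic scenes; tracking robustness to cell
  deformation is untested.
- The fusion frame is an annotation, not detected.
- The NEB criterion is an automated stand-in for visual scoring; on real
  movies the contrast-based variant with a tuned `contrast_min` may be
  preferable to the presence-based one.
- Four-cell normalization operates on externally supplied labels only.
- The watershed split line approximates the cell contact; on real,
  strongly curved contacts a few-pixel bias between the split line and
  the true membrane is expected and uncorrected.
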