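# Methods

## The measurement

`bbquant` quantifies how a fluorescent stain is enriched in the cytoplasm
around the oocyte centrosome in 3-D confocal stacks of juvenile zebrafish
ovaries. The biological context: Balbiani-body (Bb) precursor components
(*dazl* mRNA, Bucky ball protein, DiOC6-stained organelles) first aggregate
around the centrosome — at the cytoplasm apposing the telomere cluster of
the zygotene bouquet, and later inside the nuclear cleft of
pachytene/early-diplotene oocytes. The centrosome, marked by a compact
γ-tubulin punctum, is therefore used as the spatial reference for the
enrichment measurement.

Given a multi-channel stack (experimental stain, γ-tubulin, DAPI), a
hand-drawn per-slice ROI and intensity thresholds, the pipeline is:

1. **Segmentation.** A voxel is *nuclear* iff it is inside the ROI, DAPI ≥
   `t_dapi`, and γ-tubulin < `t_tub_low` (diffuse cytoplasmic γ-tubulin
   background is absent from the nucleus). *Cytoplasm* is the ROI minus the
   nucleus, so the two masks always partition the ROI. Thresholding is pure
   (no morphological cleanup by default; optional hole-filling exists behind
   a flag). Thresholds are global per stack; an Otsu-based `auto_threshold`
   is offered only as a convenience for choosing starting values.
2. **Centrosome detection.** A centrosome is a 3-D connected component
   (26-connectivity by default, configurable to 6/18) of ≥ 8 voxels with
   γ-tubulin ≥ `t_tub_min` inside the ROI. Its center is the centroid of the
   regional maxima of the Euclidean distance transform of the component,
   computed with the anisotropic physical voxel spacing — the deepest
   interior of the blob. Plateaus contribute all of their voxels, which
   makes ties deterministic. Components touching the ROI border are kept but
   flagged.
3. **Region partition.** Every cytoplasmic voxel is classified by its
   minimum physical distance *d* to the centrosome center(s):
   *centrosome-adjacent* if d ≤ r_inner, *centrosome-nonadjacent* if
   d > r_outer, and an unassigned buffer *shell* in between. Radii default
   to 4.8 / 6.0 µm in cleft mode and 1.2 / 2.4 µm in nest mode. The shell is
   deliberately excluded from both measured regions: the two radii leave a
   buffer that prevents near-centrosome signal from contaminating the far
   region.
4. **Enrichment.** Mean raw intensity of the experimental channel is taken
   over the nuclear, adjacent, and nonadjacent regions. The nuclear mean is
   subtracted from both cytoplasmic means (per-stack background
   normalization) and the fold enrichment is

   fold = (mean_adj − mean_nuc) / (mean_non − mean_nuc).

   The fold is a ratio of region means (not a mean of per-voxel ratios) and
   is undefined — flagged, never an exception — when the denominator is ≤ 0.
   Group-level "average fold" is the mean of per-unit folds over units with a
   defined fold; undefined units are dropped with a QC flag. The fold is
   invariant under affine intensity transforms applied uniformly to the
   stack, which is the point of the normalization.

Two modes wrap this core:

- **Cleft mode** (one pachytene/early-diplotene oocyte, 17–25 µm, per ROI):
  exactly one centrosome seeds the spheres; if several components qualify
  the largest is used and the unit is flagged `multiple_centrosomes`.
- **Nest mode** (a whole zygotene nest of ~12 µm cells per ROI): cells are
  not separated; every detected centrosome seeds spheres and the bulk
  cytoplasm of the nest is measured as one unit.

## Colocalization

`pearson` is the product-moment correlation of two channels over masked
voxels. `scramble_p` is a Costes-style block-permutation test: each
z-slice's masked region is tiled into square blocks of side
`round(psf_pixels)` (minimum 1), blocks fully inside the mask are permuted
uniformly at random per slice, and the reported p is the fraction of
iterations whose scrambled correlation falls strictly *below* the observed
one — so p = 1.0 means the observed correlation beat every randomization.
This convention matches reporting "p = 1" for a clearly significant
colocalization; the inverse phrasing ("probability of receiving the same
R") is sometimes seen and is simply 1 − p under this definition. The block
size comes from `psf_pixels = (0.8 · λ_ex / NA) / pixel size`; scrambling is
2-D per slice because the emulated procedure operates on image planes.
`manders` implements the thresholded Manders coefficients: m1 is the
above-threshold channel-1 signal on voxels where channel 2 is also above
its threshold, divided by all above-threshold channel-1 signal (m2
symmetrically). No bisection auto-threshold is implemented; thresholds are
explicit inputs.

## The synthetic ovary generator

Because raw microscopy for this kind of experiment is rarely redistributable,
the test bed is a generator whose stacks have exact ground truth.

Geometry and defaults (all µm; voxel size (dz, dy, dx) = (0.53, 0.25, 0.25),
12-bit):

| parameter | default | meaning |
|---|---|---|
| cell_diameter_um | 20 (cleft) / 12 (nest) | stage-appropriate cell size |
| nucleus_fraction | 0.45 | nucleus radius / cell radius |
| cleft_depth_um | 3.0 | depth of the spherical-cap nuclear indentation |
| punctum_radius_um | 0.6 | γ-tubulin punctum (≥ 8 voxels on this grid) |
| enrichment_factor | 2.0 (1.0 in controls) | core-vs-far intensity contrast |
| enrichment_radius_um | 4.8 (cleft) / 1.2 (nest) | flat core of the field |
| enrichment_sigma_um | 0.6 (cleft) / 0.4 (nest) | Gaussian shoulder scale |
| base_intensity / offset | 300 / 40 counts | cytoplasmic stain and shared background |
| punctum / tub background / tub nuclear | 3000 / 90 / 10 counts | γ-tubulin levels |
| dapi nucleus / cytoplasm | 2200 / 30 counts | DAPI levels |
| noise | Poisson on, Gaussian sd 6 | shot + read noise, then 12-bit clip |

The experimental channel in the cytoplasm is
`offset + base · (1 + (factor − 1) · G(d))` with
`G(d) = exp(−max(0, d − r_core)² / 2σ²)`: a flat core whose radius matches
the analysis inner sphere, with a Gaussian shoulder. This shape was chosen
over a pure Gaussian falloff so that the generative factor *is* the
core-versus-far-field contrast — i.e. the measured fold has an exact truth
to recover — while the soft shoulder still populates and exercises the
buffer shell. The nucleus carries only the offset, which makes the nuclear
mean an exact background estimate by construction.

The cleft oocyte is a sphere whose nucleus has a spherical-cap indentation
along a random 3-D axis; the punctum sits in the middle of the pocket
(`cleft_depth = 0` gives a spherical nucleus with a perinuclear punctum).
Nests pack n cells (two staggered rows, 0.98 diameters apart with small
jitter, overlap-rejected) in one slice-wise convex-hull ROI; the
interstitial hull space is rendered as bulk cytoplasm, emulating tightly
adjacent cells whose boundaries are invisible at these stages — consistent
with measuring the nest in bulk. Each cell gets one perinuclear centrosome
(random direction, re-drawn until the punctum fits inside the domain and
outside every nucleus). `uniform_control` / `dispersed_control` force the
factor to 1. Optional follicle-cell nuclei (DAPI-only, at the hull
periphery) stress-test segmentation and are off by default.

All randomness comes from one `numpy` Generator per stack, drawn in a fixed
order (geometry, then noise per channel: experimental, γ-tubulin, DAPI), so
generation is bit-reproducible for a fixed spec and seed.

What the generator does **not** emulate: optical blur (no PSF convolution),
spectral bleed-through, depth-dependent attenuation, irregular cell and
nucleus shapes, or chromatin texture. Passing recovery tests therefore
demonstrates the correctness of the measurement logic on images whose noise
and geometry are idealized, not robustness to every real-microscopy
artifact; thresholds on real data remain the user's responsibility, as they
were in the original interactive procedure.

## Numerical choices and edge cases

- Distances use voxel centers and physical spacing; nothing is resampled,
  so voxel-count rules (≥ 8 voxels) keep their meaning on anisotropic grids.
- Region boundaries: adjacent is d ≤ r_inner (closed), nonadjacent is
  d > r_outer (open); rasterized ROI membership is strict polygon interior
  of the voxel center.
- Undefined quantities (fold with non-positive denominator, empty regions,
  zero detected centrosomes) are QC flags on the per-unit result —
  `no_centrosome`, `multiple_centrosomes`, `undefined_fold`,
  `border_touching`, `empty_region`, `negative_normalized_intensity` — and
  never abort a run.
- The group t test is the equal-variance Student form by default (Welch
  behind a flag), two-tailed, with star coding at p < 0.05 / 0.01 / 0.0001.
- Result CSVs write floats at full `repr` precision and contain no
  timestamps, so a rerun with identical config and inputs is byte-identical.

## Verification scale

The test suite verifies every voxel primitive (rasterization, nuclear mask,
connected components, EDT-maxima centers, sphere partition, Pearson,
Manders) against independent brute-force oracles on small volumes, exactly.
Parameter recovery uses 50 synthetic oocytes per enrichment factor in
{1.0, 1.6, 2.0, 5.0} and 50 eight-cell nests at 1.6 (median within ±15% of
truth; noiseless recovery within ±5%); the uniform null uses 20 nests; the
scramble-uniformity check uses 200 seeded runs of 100 iterations each.
These sizes were chosen to estimate medians and a KS statistic stably;
`scripts/acceptance.py` recomputes the same quantities from scratch in
about a minute.
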