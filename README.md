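# bbquant

Quantification of Balbiani-body precursor enrichment around the oocyte
centrosome in 3-D confocal stacks.

In early zebrafish oogenesis, Balbiani-body (Bb) precursor components —
*dazl* mRNA, Bucky ball protein, DiOC6-stained organelles — aggregate in the
cytoplasm around the centrosome: first at the cytoplasm apposing the telomere
cluster of the zygotene bouquet, later inside the nuclear cleft of
pachytene/early-diplotene oocytes. `bbquant` implements the image
quantification for this biology as a tested, reusable pipeline for anyone
measuring regional enrichment of a stain around a punctate reference marker
in anisotropic 3-D stacks.

## The measurement

Given a multi-channel stack (experimental stain, γ-tubulin, DAPI), a
per-slice hand-drawn ROI and intensity thresholds:

- **nucleus**: voxels in the ROI with DAPI ≥ t_dapi and γ-tubulin < t_tub_low;
  **cytoplasm** = ROI \ nucleus.
- **centrosome**: a 3-D connected component of ≥ 8 voxels with γ-tubulin ≥
  t_tub_min; its center is the centroid of the regional maxima of the
  anisotropic Euclidean distance transform.
- **partition**: cytoplasm within r_in of a center is *centrosome-adjacent*,
  beyond r_out *centrosome-nonadjacent* (r_in/r_out = 4.8/6.0 µm for single
  oocytes, 1.2/2.4 µm for nests measured in bulk); the shell in between
  belongs to neither.
- **fold enrichment**:
  `fold = (mean_adjacent − mean_nuclear) / (mean_nonadjacent − mean_nuclear)`,
  the nuclear mean serving as per-stack background.

The package also provides Costes-style block-scramble colocalization
statistics (Pearson r, scramble p at PSF-sized blocks, thresholded Manders
coefficients) and a synthetic ovary generator that renders oocytes and nests
with known ground truth, so every stage is verifiable without proprietary
microscopy data.

## Worked example

```python
import bbquant as bq

# render a cleft-stage oocyte with a known 2.0x enrichment around the centrosome
spec = bq.SyntheticSpec(mode="oocyte_cleft", enrichment_factor=2.0)
stack, rois, truth = bq.generate_oocyte(spec, seed=1)

result = bq.analyze_cleft(stack, rois.units[0], bq.default_config("cleft"))
print(f"centrosomes: {result.n_centrosomes}")
print(f"mean intensities  nuclear={result.mean_nuclear:.1f}  "
      f"adjacent={result.mean_adjacent:.1f}  nonadjacent={result.mean_nonadjacent:.1f}")
print(f"fold enrichment: {result.fold:.2f}  (generative truth: {truth.enrichment_factor})")
```

prints

```
centrosomes: 1
mean intensities  nuclear=40.1  adjacent=640.1  nonadjacent=341.5
fold enrichment: 1.99  (generative truth: 2.0)
```

One γ-tubulin punctum was detected; the stain averages 640 counts in the
cytoplasm within 4.8 µm of it versus 342 counts beyond 6 µm, and after
subtracting the 40-count nuclear background the near/far ratio recovers the
generative 2-fold enrichment to within voxel-discretization error.

The same is available from the shell:

```sh
bbquant simulate --mode oocyte_cleft --seed 1 --out demo/
bbquant analyze config.json        # JSON config naming the stack, ROIs, thresholds
bbquant coloc ch1.tif ch2.tif --wavelength 488 --na 1.2 --pixel-size 130
bbquant compare groupA.csv groupB.csv --column fold
bbquant recompute-s1 per_unit.xlsx mapping.json
```

`analyze` writes a per-unit `results.csv` (fixed column order, QC flags such
as `no_centrosome` or `undefined_fold`), a `summary.json` with the group mean
fold ± SEM, and a `manifest.json` (config hash, package version, seed); reruns
are byte-identical.

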