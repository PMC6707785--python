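# imclesion

Quantitative single-cell analysis of imaging mass cytometry (IMC) data from
staged demyelinating (multiple sclerosis) brain lesions.

IMC ablates tissue with a 1 µm laser spot and reads metal-isotope-tagged
antibodies by mass spectrometry, yielding one ion-count image per marker.
This package implements the full quantification workflow needed to turn such
acquisitions into per-lesion-stage immune-cell statistics:

- **Reconstruction & cleanup** — lay out laser shots line scan by line scan
  into pixel grids; remove single-pixel speckle artifacts with a gray-level
  morphological opening (radius-1 kernel).
- **Limit-of-detection normalization** — scale each channel by
  `I_zs = I / (μ + 3σ)`, where μ and σ are the mean and population standard
  deviation of in-ROI pixel intensities, making positivity thresholds
  comparable across channels.
- **Single-cell segmentation** — Gaussian blur + threshold + watershed on the
  DNA-intercalator channel, cytoplasm simulation by label expansion, and
  marker-guided refinement: cells positive for a configured marker set (e.g.
  membrane CD3) are re-fit to the connected marker-positive region.
- **Hierarchical gating** — positive/negative threshold gating through three
  exclusive lineage branches (B → T → myeloid) with a two-level CD45 gate
  (CD45^low/+ microglia vs CD45^high macrophages/lymphocytes), CD4×CD8 and
  IgM×CD38 quadrants, Igκ⁺Igλ⁺ artifact removal, and functional modifiers
  (Ki67, NFAT1, CD38⁺HLA⁺). Thresholds can be fitted from annotated seed
  cells (log-scale midpoint of the seed gap).
- **Morphometry** — cell densities (cells/mm² per class per ROI) and
  distances to collagen⁺ perivascular regions (retained only when strictly
  exceeding 10 µm equivalent diameter and 800 µm² area), with `n/a` for
  classes absent from an ROI.
- **Validation & embedding** — Spearman rank correlation (exact permutation
  p for small n) for cross-modality comparisons, and a deterministic
  diffusion embedding of log-transformed, z-scored T-cell features.

Because the original patient acquisitions are not publicly deposited, the
package ships a first-class synthetic scene generator
(`imclesion.synthetic`) that renders ground-truthed multichannel scenes —
nucleated cells of 20+ phenotypes, vessels, lesion-stage-dependent
composition, Poisson shot noise, speckles — so every stage is testable
end to end.

## Worked example

`examples/02_segment_and_gate.py` simulates a 0.25 mm² active-lesion-center
scene (300 cells, default noise), runs the full pipeline and compares
recovered densities with ground truth:

```
segmentation: recall 1.000, precision 1.000
gating accuracy vs ground truth: 1.000
                              class  truth  found  density/mm2
            demyelinating microglia     60     60       240.0
           demyelinating macrophage     40     40       160.0
                activated microglia     30     30       120.0
                          microglia     25     25       100.0
                         macrophage     25     25       100.0
                         CD8 T cell     25     25       100.0
               activated macrophage     20     20        80.0
                         CD4 T cell     20     20        80.0
                unclassified T cell     10     10        40.0
   chronically activated CD8 T cell      8      8        32.0
                       naive B cell      8      8        32.0
                              other      8      8        32.0
           proliferating CD8 T cell      6      6        24.0
               activated CD4 T cell      6      6        24.0
                  IgM memory B cell      5      5        20.0
             switched memory B cell      4      4        16.0
```

Each density is the class count divided by the ROI's analysis-mask area in
mm²; recall/precision score nucleus detection against true cell centers, and
gating accuracy is the fraction of matched cells assigned their true
phenotype. The other examples cover preprocessing statistics, vessel
morphometry, seed-based gate fitting, and the cross-stage Spearman
validation plus T-cell embedding.

Scenes can also be generated from the shell:

```sh
imclesion simulate --seed 17 --out scene_dir/
```

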