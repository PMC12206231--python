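# slidescape

Cell-based spatial and morphological explainability analysis for
whole-slide-image (WSI) progression models.

## The problem

Deep multiple-instance-learning models can predict whether a cutaneous
squamous cell carcinoma (cSCC) patient will progress (local recurrence
or metastasis) from a routine H&E diagnostic slide — but they do not
say *why*. A quantitative explainability protocol answers that by
combining three ingredients:

1. **Attribution.** Integrated Gradients (IG) assigns each 256×256 px
   patch (at ×20, 0.5 µm/px) a score for how much it pushed the model
   toward the patient's true class. Analysis is restricted to the tumor
   region plus an ~800 µm stripe of surrounding tissue; each slide
   contributes its top 10% IG-scored patches, capped at 200.
2. **Cell-based featurization.** From a nuclei-segmentation output
   (typed centroids for granulocyte / lymphocyte / plasma / stroma /
   tumor / epithelial cells, with per-nucleus area, eccentricity,
   solidity and extent), every patch is summarized into a fixed-order
   **524-entry feature vector**: composition, morphology summaries,
   cross-type distances, and two spatial point-pattern statistics —
   - the **average nearest neighbor ratio**
     `ANNR = D̄_O / D̄_E` with `D̄_E = 0.5 / √(n/A)`
     (< 1 clustered, > 1 regular), and
   - **join-count spatial autocorrelation**
     `(J_BB − J_BW) / J_T` over the Voronoi/Delaunay neighbor graph of
     the nuclei, with the focal cell type labeled black.
3. **Group comparison.** Selected patches of progressors (positive
   group) vs non-progressors (negative group) are compared per feature
   with the brute-force common-language effect size
   `CLES = P(X > Y)` and two-sided Mann–Whitney U tests; an XGBoost
   classifier on the same features checks that they carry the
   predictive signal (80–20 patient-grouped split, 3-fold CV, AUROC
   with bootstrap CI, Youden-index dichotomization).

Because no nuclei-level dataset is publicly deposited for this
analysis, the package ships a first-class **synthetic cohort
generator** (Thomas-cluster tumor cells inside smooth tumor masks,
Poisson background types, configurable intermixing and morphology
distributions, and a step-plus-noise attribution surrogate focused on
the tumor interior for non-progressors vs the border stripe for
progressors). Every stage of the pipeline is exercised and tested
end-to-end on these synthetic slides; see `docs/methods.md` for what
that does and does not demonstrate about real tissue.

## Worked example

```python
import slidescape as ss

geom = ss.SlideGeometry("demo", width_px=2048, height_px=2048)
nuclei, tumor, tissue = ss.generate_slide(
    ss.default_phenotype("progress"), geom, seed=3)
patches = ss.tissue_filter(ss.tile_slide(geom), tissue, geom)
table = ss.featurize_slide(nuclei, patches, tumor_mask=tumor)
row = table[table.frac_tumor > 0.4].iloc[0]
print(f"patch ({row['row']},{row['col']}): n={row['count_total']:.0f}, "
      f"tumor frac={row['frac_tumor']:.2f}, "
      f"ANNR(tumor)={row['annr_tumor']:.3f}, "
      f"join autocorr(tumor)={row['join_autocorr_tumor']:.3f}")
```

prints

```
patch (3,2): n=126, tumor frac=0.42, ANNR(tumor)=0.859, join autocorr(tumor)=-0.096
```

a tumor-rich patch of a progressor slide: its tumor cells sit closer
together than a random pattern (ANNR 0.86 < 1, the Thomas clustering),
and tumor nuclei border non-tumor nuclei slightly more often than each
other (autocorrelation −0.10, the configured intermixing).

The full pipeline runs from the command line:

```bash
slidescape --out-dir run --seed 11 run     # simulate → … → report
```

which writes the 524-column patch feature table (`features.csv`), the
selected explanatory patches (`selections.csv`), the per-feature
CLES/Mann–Whitney report (`comparison.csv`), classifier metrics
(`metrics.json`) and heatmap/violin-plot renderings (`report/`).
On the default 20-patient synthetic cohort the comparison recovers the
configured contrasts — e.g. tumor-cell ANNR and nuclear area larger in
non-progressors, eccentricity larger in progressors — at p < 0.01.

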