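# ductmorph

Quantitative duct morphometry for H&E histopathology.

Pancreatic ductal adenocarcinoma (PDAC) is diagnosed and graded by
inspecting ducts: a healthy duct has a smooth, near-convex lumen ringed by
cuboidal epithelium, while carcinomatous ducts grow papillary fronds,
irregular boundaries, and columnar epithelium with loss of nuclear
polarity.  `ductmorph` turns those visual impressions into numbers for a
single-duct RGB crop:

1. **Segmentation** — the lumen is binarised (median filter, robust
   illumination flattening, Kapur maximum-entropy threshold), seeded from
   the peaks of a direction cumulative map `H(A) = Σ_d √(run_d)`, and grown
   by seeded region growing; nuclei come from k-means colour clustering
   plus a watershed split, and the nuclei nearest to the lumen boundary
   form the epithelial set `N_E` (the rest are stromal).
2. **Features** — twelve classical morphometrics (Area, Perimeter, …,
   Solidity) for lumen and both nucleus classes, plus six duct-atypia
   features.  With `B_I` the *ideal* lumen boundary (convex hull of the
   traced boundary `B_O`, rescaled by `s = √(Area(R_O)/Area(R_C))` so it
   encloses the same area) and `A(t)` the signed orthogonal distance from
   `B_I` to `B_O` along `B_I`'s arc length `L(t)`:

   * `RMSAA = √((1/m) Σ_t A(t)²)` — overall boundary deviation (µm);
   * `TSAV = Σ_i arccos(a_i·b_i / |a_i||b_i|)` — total turning angle at
     the perceptually important points of the `(L, A)` signature (rad);
   * `AtypiaRatio`, `#AtypiaRegions` — area fraction and supra-300 µm²
     count of the components of `(R_I ∪ R_O) − (R_I ∩ R_O)`;
   * `CytoplasmLength` mean and SD — orthogonal nucleus-to-lumen
     distances of the epithelial nuclei (µm), the SD with divisor `m`.
3. **Evaluation** — 13 feature-set compositions (lumen / epithelial /
   stromal / duct / tissue, classical vs proposed), repeated stratified
   60:40 SVM evaluation with RBF kernel and 10-fold cross-validated grid
   search over C ∈ {10⁻¹…10⁴}, γ ∈ {2⁻⁵…2⁰}, confusion metrics, ROC/AUC,
   and one-way ANOVA with Fisher-LSD feature screening.

Because annotated slides are rarely available, the package ships a
**phantom generator**: parametric synthetic duct images (bright lumen,
ring of columnar nuclei, scattered stromal nuclei, papillary fronds of
known count and area, controlled nucleus-to-lumen offsets) with exact
ground truth, so every stage is testable against known answers.
See `docs/methods.md` for the measurement conventions and design choices.

## Worked example

```python
import ductmorph as dm

cfg = dm.PhantomConfig(n_lobes=3, rng_seed=7)       # 3 papillary fronds
image, truth = dm.generate_duct_phantom(cfg)        # 768x768 RGB + truth
row = dm.run_pipeline(image)                        # segment + measure
print(row["status"], row["#AtypiaRegions"])
print(round(row["RMSAA"], 2), round(row["AtypiaRatio"], 3),
      round(row["CytoplasmLength"], 2))
```

prints

```
ok 3
17.05 0.253 9.03
```

The pipeline found the lumen, counted exactly the 3 generated papillary
fronds among the supra-threshold atypia regions, measured an RMS boundary
deviation of ≈ 17 µm with a quarter of the lumen area displaced relative
to the ideal boundary, and recovered the generated 8 µm nucleus-to-lumen
offset to within ~1 µm (the median filter nudges the segmented boundary
slightly inward; measuring on the ground-truth objects instead gives
8.03 µm).  A convex phantom (`n_lobes=0`) yields `#AtypiaRegions = 0` and
RMSAA ≈ 0.1 µm.

The same measurements run from the shell:

```bash
ductmorph phantom --out phantoms/ --n 4 --seed 7
ductmorph features phantoms/*.png --out features.csv
ductmorph classify features.csv --case g1-vs-g2 --sets PLF,PDF --out eval.csv
```

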