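# Methods

`ductmorph` quantifies the architecture of a single pancreatic duct in an
H&E-stained tissue crop: how far the lumen outline departs from the smooth,
convex cavity of a healthy duct, and how regularly the epithelial nuclei are
arranged around it.  This note records the model, the measurement
conventions, the tunable parameters, and the design choices made where the
procedure was genuinely open.

## The duct model

A duct is a lumen (bright open cavity) ringed by epithelial cells whose
nuclei sit a roughly constant distance from the cavity wall.  In
well/moderately differentiated ductal adenocarcinoma the cavity grows
papillary fronds and irregular indentations, and the epithelium becomes
columnar with loss of nuclear polarity, so (i) the boundary deviates from
its convex idealisation and (ii) the nucleus-to-lumen distances become both
longer and more variable.  Six duct features capture this:

* **Ideal boundary** `B_I`: the convex hull `B_C` of the traced lumen
  boundary `B_O`, shrunk about the hull centroid by
  `s = sqrt(Area(R_O) / Area(R_C))` so that `Area(R_I) = Area(R_O)`.  `B_I`
  is resampled to uniform arc-length spacing of at most 1 px so that
  signature indices track geometric arc length.
* **Atypia-amplitude signature** `A(t)`: at each point `p_t` of `B_I`, a
  line is cast along the outward normal; the nearest intersection `q` with
  the `B_O` polygon gives `|A(t)|` with sign +/− for `q` outside/inside the
  region enclosed by `B_I`.  `L(t)` is the cumulative arc length of `B_I`
  with `L(0) = 0`.  When the normal line misses `B_O` inside the search
  window (default: the `B_O` bounding-box diagonal), the nearest boundary
  point is used with a point-in-region sign test.
* **RMSAA** = `sqrt(mean A(t)^2)`, reported in µm.
* **TSAV**: the signature is reduced to its perceptually important points
  (PIPs) by recursive bisection — within the current PIP pair, the point of
  maximum perpendicular distance (VD) from the chord in the `(L, A)` plane
  becomes a PIP whenever VD exceeds a threshold `T` — and TSAV is the sum
  of turning angles (radians) at the interior PIPs.  A post-pass removes
  near-collinear PIPs, iteratively dropping the interior PIP with the
  smallest turning angle while it is below `theta_min`.
* **AtypiaRatio / #AtypiaRegions**: the symmetric difference of `R_O` and
  `R_I` is separated by `B_I` into outside and inside parts; 8-connected
  raster components of each side are the atypia regions.  AtypiaRatio is
  the summed area of all regions over `Area(R_O)`; the count includes only
  regions larger than an area threshold (default 300 µm², matching the
  clinical convention for the slide resolution used).
* **CytoplasmLength (mean, SD)**: distance from each epithelial nucleus
  centroid to the nearest point of the `B_O` polyline (the minimising
  segment is orthogonal to the boundary at its foot).  The SD uses the
  population divisor `m = |N_E|`.

Conventions worth noting: the scaling factor uses the *square root* of the
area ratio, since a linear scale by `s` multiplies area by `s²` — this is
the only reading under which the ideal boundary actually preserves the
lumen area (verified to ≤ 1% on random star polygons).  PIP detection is
anchored at the signature's maximum-amplitude point, not the arbitrary
start of the boundary trace, so TSAV is invariant (to < 1%) under rigid
motion of the input image.  Ties in the VD recursion go to the smallest
index; grid ties elsewhere follow the same smallest-first rule.

## Segmentation

* **Lumen binarisation**: median filter (disk radius 2 px) → illumination
  flattening → Kapur maximum-entropy threshold on the 256-bin histogram.
  Two departures from the plain recipe proved necessary.  First,
  illumination is flattened with a robust low-order polynomial fit (default
  degree 1) that iteratively excludes high-residual pixels; a rolling-ball
  estimate is unusable here because the duct lumen can fill half the crop,
  and any ball smaller than the lumen swallows it into the background.
  Second, Kapur's threshold is applied hierarchically: on sharply
  multimodal histograms a single entropy split isolates the small dark
  chromatin phase, so while the bright class still holds the majority of
  pixels the threshold is recomputed within it (at most 3 rounds).
  Finally, components (and holes) smaller than 64 px and smaller than 1% of
  the largest bright component are removed — threshold-tail speckle in the
  stroma, orders of magnitude below any lumen.
* **Seed detection**: the direction cumulative map sums `sqrt(run)` of the
  4-directional white runs at each white pixel (self excluded, so isolated
  pixels score 0).  The map is zeroed below the Otsu threshold of its
  nonzero values and local maxima (plateau centroids) become seeds.
* **Seeded region growing**: region statistics are estimated from 11×11
  neighbourhoods of the seeds; every pixel within `tolerance` (default 25
  grey levels) of the region mean and 4-connected to a seed joins.  Because
  the criterion is fixed after the statistics pass, the result is
  independent of seed order, and seeds in one region merge trivially.  The
  largest merged region, hole-filled, is the lumen; a warning fires if it
  touches most of the image border (background leak).
* **Nuclei**: median filter → k-means on RGB (k = 3: chromatin, stroma,
  lumen; fitted on ≤ 50k subsampled pixels with a fixed seed) → darkest
  cluster, provided it is ≥ 25 grey levels darker than the tissue median →
  hole filling → distance-transform watershed with peak markers (minimum
  separation default 7 px) → discard components < 10 px².
* **Epithelial split**: for every point of `B_O` the nearest nucleus
  centroid is selected (ties to the smallest index); the union is `N_E`,
  the rest `N_NE`.  No distance cap is applied.

The classical features (Area, Perimeter, Width, Height, Major/MinorAxis,
Circularity, Feret diameter, AspectRatio, Skewness, Roundness, Solidity)
follow the usual measurement-tool definitions; the perimeter is the traced
polygon length after a 5-point circular moving average of the contour,
because a raw marching-squares chain overestimates a disk's perimeter by
~6% and would push Circularity of a perfect circle to 0.89.  Skewness is
the third standardised moment of the luminance inside the region — the
intensity-based convention — and 0 when no intensity raster is supplied.

## Synthetic phantoms

The phantom generator renders the study conditions: a near-white lumen
(RGB 245,245,245) on eosin-pink stroma (230,180,200) with hematoxylin-dark
nuclei (60,40,120) and additive Gaussian noise (σ = 3 by default).

* The smooth lumen is a disk; `boundary_noise_amp` adds band-limited
  (harmonics 2–8) radial noise with the given RMS amplitude in px.
* Papillary phantoms carry `n_lobes` inward fronds — papillae project into
  the cavity — rendered as radially elongated ellipses (2:1) of a
  prescribed area (default 2000 µm²) breaching the rim by 12 px, plus a
  deterministic cosine scalloping of the rim between fronds (wavelength
  ≈ 29 px, depth ≈ 0.27 of the lumen radius).  The scalloping is not
  decoration: the area-preserving ideal boundary forces the outside and
  inside symmetric-difference totals to be equal, so a boundary with only
  k large fronds would dump the balancing area into a connected band and
  break the region count.  The scallops absorb that balance as many
  fragments that each stay below the 300 µm² counting threshold, which
  makes the expected supra-threshold count exactly `n_lobes` — an analytic
  ground truth, verified exactly over k = 1…5 across random placements.
* Epithelial nuclei are anchored on locally convex rim points (scallop
  tops for papillary rims) and displaced along the outward normal by the
  configured cytoplasm offset, so the placed nucleus-to-boundary distance
  equals the offset by construction; `cytoplasm_offset_sd` jitters it to
  model loss of polarity.  Stromal nuclei are scattered with a clearance
  of ≥ 60 px from the boundary so that the nearest-nucleus rule can never
  select them.
* The per-grade reference conditions (`grade_configs`) use the reported
  per-class means of the source cohort where available: cytoplasm offsets
  6.2 / 12.9 / 15.9 µm with SD 2.1 / 5.8 / 8.5 µm, ~0 / 2.5 / 4.8 atypia
  regions (Poisson-jittered, clipped to 1–6), and lumen sizes ordered
  normal < grade 1 < grade 2 (scaled to fit single-duct crops at 0.492
  µm/px).  Cohort generation derives one sub-seed per image from the
  master seed and adds within-class lognormal jitter (radius ±8%, noise
  amplitude ±25%, offset ±12%) so neighbouring grades overlap as
  biological classes do.

What the phantoms deliberately do not model: H&E staining texture and
colour variability, cribriform (multi-lumen) architecture, overlapping
nuclear clusters, mucin, tissue folds and out-of-focus blur.  Passing
phantom tests therefore demonstrates correctness of the measurement
machinery under controlled geometry, not segmentation robustness on real
slides.

## Classifier evaluation protocol

Feature sets are composed per the published table (13 sets, dimensions
12/12/4/16/12/2/14/24/6/30/36/18/42).  For a binary case the evaluation
runs 10 repetitions of a stratified 60:40 train/test split (true
with-replacement resampling is available as a config option); on each
training split the features are z-scored and an RBF soft-margin SVM is
tuned by 10-fold cross-validated grid search over
C ∈ {10⁻¹, 10⁻⁰·⁵, …, 10⁴} and γ ∈ {2⁻⁵, 2⁻⁴·⁵, …, 2⁰} (ties: smallest C,
then smallest γ), refit, and scored on the held-out split.  Confusion
counts, SN/SP/PPV/NPV/ACC (as percentages) and trapezoidal AUC are
averaged over repetitions; ROC curves are vertically averaged on a common
FPR grid.  Standardisation is applied because the γ grid presumes
comparable feature scales.  The normal-vs-carcinoma case balances the
positive class by a seeded stratified half-sample of the two grades.

Feature screening uses one-way ANOVA per feature (F test at α = 0.01)
with Fisher's LSD post hoc:
`LSD = t_{1−α/2, df_W} · sqrt(MS_W · (1/n_a + 1/n_b))`, a pair differing
when the absolute mean difference exceeds LSD.  Zero within-group variance
with equal means yields F = 0, not NaN.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| resolution | 0.492 | µm/px | slide scanner resolution of the reference cohort |
| median_radius | 2 | px | removes pixel noise without erasing 29 px scallops |
| bg_degree | 1 | – | plane fit suffices for linear illumination drift |
| kmeans_k | 3 | – | chromatin / stroma / lumen phases of H&E |
| min_nucleus_area | 10 | px² | debris floor |
| nucleus_min_separation | 7 | px | ~0.7 of the default nuclear minor axis |
| pip_threshold T | 1.0 | px | sub-pixel signature wiggle is not a critical point |
| theta_min | 5 | deg | near-collinear PIP pruning |
| atypia_threshold | 300 | µm² | clinical counting threshold |
| SRG tolerance | 25 | grey | half the stroma–lumen contrast of stained tissue |

## Problem sizes

The standard experiment uses 80 images per class (240 total) measured on
ground-truth objects, the exact-recovery suite uses 10 random placements
for each frond count k = 1…5 at full working resolution (768² px), and the
convex-limit suite uses 20 images; the PIP detector is cross-checked
against an independent recursive implementation on 1000 random 50-point
signatures.  Full from-pixels segmentation is exercised on a smaller set
of phantoms, since its per-image cost (~1–2 s) is dominated by k-means and
the median filter.

## Known limitations

* The SRG criterion uses fixed region statistics estimated from the seed
  neighbourhoods rather than an incrementally updated mean; on phantoms
  and high-contrast crops the two coincide, and the fixed form is
  deterministic and seed-order independent.
* TSAV inherits the PIP recursion's sensitivity to sampling: on extremely
  spiky boundaries (the scalloped phantoms) a rigid motion can change it
  by ~2% through single PIPs appearing or disappearing near threshold.
* The epithelial split has no distance cap: in an image with a distant
  nucleus cluster and a sparse ring, a far nucleus can be selected if it
  is the nearest to some boundary point.
* Real-slide accuracy figures are not reproducible here (no slides); the
  phantom cohort is cleaner than tissue, so its accuracies exceed the
  published ones while preserving the qualitative ordering (detection
  easier than grading).
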