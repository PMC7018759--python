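# Methods

## Problem and data model

Intravascular OCT (IVOCT) acquires one axial reflectivity profile — an
A-line — per emitter angle θ; a frame is the polar (r, θ) stack of one
catheter rotation, and a pullback is the ordered frame stack along the vessel
axis z. `octaline` classifies every A-line as **fibrolipidic** (fibrous
tissue at the lumen border followed by lipid), **fibrocalcific** (fibrous
tissue followed by calcification), or **other**, and reports the clinical
attributes interventionalists care about: the arc angle and longitudinal
length of each plaque. All computation stays in the polar domain; Cartesian
views are rendered for display only, to avoid interpolation artifacts.

Working on A-lines rather than pixels sidesteps the indeterminate rear
border of lipid pools (light is absorbed so quickly in lipid that the back
boundary is unobservable) and matches the innate data unit of the scanner.

Pixel annotations are collapsed to A-line labels with a counting rule: an
A-line containing ≥ 3 lipid or calcium pixels takes the majority class of
those two; everything else is *other*. Ties with both classes at or above
threshold go to fibrocalcific — the rule must be deterministic and calcium
drives interventional decisions. Guidewire-shadow A-lines carry a distinct
`GUIDEWIRE` state, excluded from training and from every confusion count,
so that "no tissue information" is never conflated with "other tissue".

## Pipeline

1. **Pre-processing.** The guidewire shadow is found on the accumulated
   intensity map (sum over r per A-line): an Otsu threshold proposes shadow
   width, and a dynamic program over frames tracks the interval center with
   an L1 drift penalty (0.02 per A-line on the normalized map) — the shadow
   moves slowly in θ. A contrast gate (shadow mean < 0.4 × tissue mean)
   prevents false detections on shadow-free pullbacks. The lumen boundary is
   the closed contour maximizing cumulative radial edge strength
   (derivative-of-Gaussian along r, σ = 2 px) under a ≤ 3 px per-step jump
   constraint; closure is enforced by solving the DP from several candidate
   start rows (exact search over all rows is available and is what the
   optimality tests use). Guidewire A-lines get a neutral score, are bridged
   by circular linear interpolation, and flagged invalid. Each A-line is then
   shifted so its boundary sits at r = 0, the first 200 px (~1 mm, the
   useful penetration depth) become the region of interest, five further
   samples are kept as the CNN's right-padding source, and a 7 × 7 σ = 1
   Gaussian suppresses speckle.

2. **Convolutional features.** A small 1-D CNN — three convolution blocks
   (32/64/96 filters, kernels 11/9/7, stride 2, batch-norm + ReLU), max
   pooling (2) after the first two, then fully connected 100/100/3 with
   dropout 0.5 — is trained to classify A-lines with a class-weighted
   softmax cross-entropy (weights = median class frequency / class
   frequency), Adam (base lr 1e-3, β₁ = 0.9, step decay ×0.2 every 5
   epochs), batch size 30, up to 50 epochs with early stopping after 5
   epochs without validation improvement. Inputs are padded to 210 samples:
   5 zeros on the lumen side, 200 ROI samples, and the 5 post-ROI tissue
   samples on the right. After training the softmax layer is discarded and
   the 100 penultimate activations become the feature vector. The network is
   implemented directly in numpy (im2col convolutions with hand-written
   backward passes); at these input sizes it trains in seconds to minutes on
   one CPU core. The receptive field implied by the architecture is 149
   samples under the standard recursion; the model manifest records this
   computed value.

3. **Lumen morphology features.** Pixel shifting erases lumen shape, which
   is exactly where large calcifications show (flat or irregular walls), so
   shape is restored through contour-only features: frame area (shoelace)
   and moment-ellipse eccentricity with ±1..3-frame deltas and ratios;
   per-A-line signed distance to the equal-area concentric circle centered
   at the lumen centroid; total-least-squares line fits over sliding
   circular windows of ⅛ of the boundary (SSR, R², chord-projection
   magnitude) per A-line and as frame min/max/mean with deltas; and the
   smoothed dR/dθ lumen slope (0 = perpendicular beam incidence). The
   historical inventory this feature set descends from counted 371 scalars;
   here the families are parameterized (lags, window divisor, aggregate
   window) and the default configuration realizes 94 named features, with
   the manifest recording the count. Edge-of-pullback deltas clamp to the
   nearest frame and set a validity-flag feature.

4. **Hybrid random forest.** CNN features (first) and morphology features
   are concatenated per A-line and classified by a random forest: 250 trees,
   16 candidate variables per split. The tree count can be re-derived from
   the out-of-bag error curve over 100..1000 in steps of 50 (warm-started),
   choosing the smallest size within 0.002 absolute of the curve minimum —
   the curve plateaus near 250. Trees are scale-invariant so features are
   not normalized, and the forest trains on raw class counts; imbalance is
   handled only in the CNN loss. Vote fractions serve as class
   probabilities.

5. **CRF smoothing.** Independent A-line decisions speckle the en-face
   (θ, z) map, so a fully connected CRF with Potts compatibility and a
   single Gaussian smoothness kernel ω₁·exp(−|pᵢ−pⱼ|²/2θ_α²) is applied by
   mean-field inference (10 iterations). En-face cells carry no meaningful
   intensity, so the appearance kernel is fixed at ω₂ = 0. θ is circular
   (A-line 0 adjacent to A-line n−1), z linear; both axes share θ_α by
   default, with an anisotropy option because A-line pitch and the 0.2 mm
   frame pitch are physically different. Unary potentials are −log(p + ε)
   with ε = 1e-6. Updates follow a red-black (checkerboard) schedule: each
   half-update sees the freshest estimates of the other half, which settles
   the iteration where a fully parallel update can oscillate between
   near-tied labelings. ω₁ and θ_α are chosen by grid search maximizing
   mean per-class F1 on validation folds (ω₁ = 0 is always in the grid, so
   smoothing can never be chosen when it hurts validation).

## Evaluation

Metrics are one-vs-rest over non-guidewire A-lines: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F1 2TP/(2TP+FP+FN). Sensitivity and F1
are reported as *missing* (not zero) when a class has no positive reference
A-lines. Cross validation is at VOI granularity — frames of one lesion are
too correlated to split — with five subsets rotating through
train(3)/validation(1)/test(1) roles and an optional held-out set. Per-fold
metrics pool A-lines within the fold. Arc angle is 360°·k/n_theta per
maximal circular run of k same-class A-lines; length is (contiguous frame
count) × (frame interval = pullback speed / frame rate, 0.2 mm at
36 mm/s / 180 fps); agreement between predicted and reference attributes is
summarized by Bland–Altman bias ± 1.96 SD, and paired method comparisons use
the two-sided Wilcoxon signed-rank test (exact null for n ≤ 25). Folds with
mean F1 below 0.7 are flagged for manual relabeling review; the package
never mutates labels automatically.

## Synthetic pullbacks

No public IVOCT corpus with A-line labels exists at the granularity this
pipeline needs, so phantoms provide ground truth that is exactly consistent
across pixel masks, lumen contours and A-line labels. Each phantom has: a
circular-to-eccentric lumen (r(θ) = R(1 + ε·cos(θ−φ)) with slow drift along
z); per-tissue depth profiles — fibrous decay ~3 mm⁻¹ equivalent, lipid
bright cap then steep ~12 mm⁻¹ decay with diffuse rear border, calcium a
signal-poor pocket (12% of fibrous surface intensity, weak attenuation)
with sharp borders and preserved signal behind; optional lumen flattening
across calcium spans (the chord replaces the arc), exercising the best-fit
line features; a guidewire shadow sector with a faint sheath reflection; a
bright catheter sheath ring near r = 0 that segmentation must skip; and
multiplicative gamma speckle (shape 4, σ/μ = 0.5). VOI composition follows
the 34:37:13:27 calcium/lipid/both/none reference mix, largest-remainder
scaled to the requested cohort size.

A fixed fraction (0.35) of calcium lesions is rendered *ambiguous*: a
diffuse, lipid-like attenuation profile that still flattens the lumen. On
those A-lines intensity alone cannot separate the classes and only lumen
shape can — the situation the hybrid classifier exists for. Without such
lesions a sufficiently trained CNN is essentially perfect on phantoms and
the hybrid-vs-CNN comparison degenerates.

What the phantoms do **not** model: physical wave propagation, polarization,
NURD/motion artifacts, side branches, thrombus, stent struts, blood
artifacts, and the full histological diversity of plaque. Passing tests on
phantoms therefore demonstrates that the pipeline machinery is correct and
that the hybrid design behaves as intended under controlled contrast; it
does not certify clinical performance.

## Problem sizes and numerical choices

The end-to-end study runs at fixture scale chosen for a single CPU: 25 VOIs
× 40 frames, 96 A-lines per frame, 360 radial samples (lumen radius ~100 px
so the 205-sample ROI+pad band always exists after shifting), five folds;
CNN training capped at 9,000 class-proportionally subsampled A-lines per
fold (≤ 15 epochs), forest training at 8,000. The full study completes in
roughly ten minutes; the stage structure is identical to a full-scale run.

Other numerical choices: 0-based indices, θ counter-clockwise, frames
distal → proximal; Gaussian filter uses reflect boundaries; DP tie-breaks
follow numpy argmax (first maximum); forest and CNN randomness derive from
a single per-fold seed; probabilities are renormalized after CRF updates;
degenerate inputs (all-zero frames, < 3 valid contour points, single-class
training labels, empty parameter grids) raise errors rather than guessing.

## Known limitations

* The morphology inventory is a parameterized reconstruction of the feature
  *families*, not the historical 371-item list.
* "Line magnitude" is defined here as the chord projected on the fitted
  line; other readings exist.
* Lumen segmentation is per frame; a (θ, z)-coupled formulation would be
  more robust to single-frame dropouts.
* The CNN-only baseline uses the network's own softmax; the hybrid/CNN
  comparison therefore also reflects the forest's contribution, not purely
  the added features.
* Mean-field inference approximates the CRF optimum; the energy-optimality
  tests bound the gap only on tiny grids.
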