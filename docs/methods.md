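# Methods

This note records the models, estimators, numerical conventions and design
choices behind `inflorascan`, and what the synthetic benchmarks do and do
not establish about real photographs.

## Imaging model and calibration

A scene is one 8-bit RGB photograph of trimmed inflorescences on a
contrasting board, with square pixels of known physical edge length
p_l (cm/px), supplied per image by the user (typically read off an in-photo
ruler once per session). All absolute quantities follow from p_l: lengths
scale as n·p_l, areas as n·p_l². Coordinates put x on columns, y on rows,
origin top-left, pixel centers at integer positions. EXIF orientation is
applied at load; lens-distortion correction is assumed done in-camera and is
not modeled.

## Segmentation

1. **Blue band.** The blue channel is used unchanged. Chlorophyll-bearing
   material absorbs strongly in blue while a suitable board reflects it, so
   the channel histogram is close to a two-component Gaussian mixture.
2. **Minimum-error threshold.** For each candidate level T the histogram is
   split into classes ≤T and >T with priors P₁,P₂, means μ₁,μ₂ and
   variances σ₁²,σ₂², and

       J(T) = 1 + 2[P₁ln σ₁ + P₂ln σ₂] − 2[P₁ln P₁ + P₂ln P₂]

   is minimized by exhaustive scan over all 256 levels (exactness over the
   classical iterative scheme; 256 evaluations are free). Each class
   variance is floored at 1/12 gray² — the quantization variance of a
   single bin — so spike-only classes keep a finite log term and two-delta
   histograms are well defined. A single-bin histogram raises a degenerate-
   histogram error: a blank scene has no split to find.
   When the two modes are far apart the criterion's valley is nearly flat
   over the empty gap, so the chosen level can sit several gray levels from
   the analytic equal-posterior boundary while adding only a negligible
   (≪0.1%) misclassification excess; the benchmarks therefore track both the
   level deviation and the excess error, and the latter is the meaningful
   one.
3. **Polarity.** Default `object_side="below"` (dark buds on a bright-blue
   background), configurable because board color is a user choice.
4. **Manual edits.** Stray objects (tags, ruler fragments, shading) are
   handled as mask algebra: out = (mask AND NOT remove) OR add, with the
   edit masks painted in any external editor.
5. **Area opening.** Components smaller than ceil(min_area/p_l²) pixels
   (default min_area = 1 cm²) are deleted; the filter is anti-extensive and
   idempotent. Implemented with scikit-image's component filter; tests pin
   it to a brute-force flood-fill oracle.
6. **Labeling.** 8-connectivity by default (touching buds are split by
   manual edit, not by the labeler); labels are renumbered to raster-scan
   order of each component's first pixel so outputs are reproducible across
   library versions.

## Morphometry

Moments are taken over **all object pixels** (region mode). The axis
formulas' 2√2 constant is the filled-region calibration: for an ideal filled
ellipse they return the exact axis lengths, whereas boundary-only moments
inflate a disk's diameter by √2. Boundary mode is retained as an option for
comparison with tools that measure rims; the two modes must not be mixed in
one analysis.

The convex hull is computed by Andrew's monotone chain with collinear
vertices dropped, over **pixel corner points** by default (each pixel
contributes its four corners), which guarantees CH ≥ IS for every object;
pixel-center hulls are available for cross-tool comparison and are strictly
smaller. Hull area is the shoelace sum, perimeter the closed vertex loop
(a 2-vertex "polygon" counts its segment out and back).

Degenerate objects — single pixels or collinear runs — get IW = 0, an
undefined (NaN) shape ratio, and are excluded from ISH aggregates only.

## Plant aggregation and fresh/dry calibration

Per plant: IN = object count, TIC = Σ IS (exact float sum in object order),
and mean/sd of IS, IL, IW, CH, HP, ISH with the n−1 denominator (flagged
undefined for IN < 2).

Plants imaged fresh and plants imaged dry are unified through per-trait
ordinary least squares of dry on fresh, fitted on plants imaged in both
states (≥3, by design ~14). A trait is calibratable only when R² > 0.9;
means map affinely, standard deviations scale by |slope|, and dry→fresh
uses the exact inverse map, so round trips are identities.

## Heritability

Broad-sense heritability is estimated as clonal repeatability by one-way
random-effects method of moments on genotype groups:

    V_W = MS_within
    V_G = (MS_between − MS_within)/k₁,  k₁ = (N − Σnᵢ²/N)/(G−1)
    H²  = V_G/(V_G + V_W),  V_G truncated at 0

Truncation keeps H² in [0,1]; the estimator is invariant to affine trait
transforms. No spatial/field-design adjustment is applied, so on real trial
data this is a repeatability proxy, not a design-corrected heritability —
V_G and V_W are reported separately so users can form other ratios.
Correlations are Pearson with two-sided t-test p-values, blanked above
α = 0.05.

## Yield layer

Per-bud weights are never measured; they are apportioned from the plant's
weighed total as wᵢ = (IDB/TIC)·ISᵢ, which conserves Σwᵢ = IDB to
round-off and assumes within-plant areal density is constant — adequate for
ranking and cumulative shares, not for per-bud absolute weights. The
cumulative-yield fraction sorts weights descending (ties by object id) and
returns 100·k/N for the minimal k reaching q·IDB.

The predictor takes the arithmetic mean width of the k = 20 longest buds
(ties by length break toward larger width, then smaller id) and evaluates
β₀ + β₁·IW. Shipped defaults β₁ = 59.14 g/cm, β₀ = −134.97 g carry
provenance `published_default` and a fit domain of mean IW > 2.5 cm; they
encode one cultivation environment and should be refitted locally
(`refit_prediction`, OLS with R² and F(1, n−2) reported). Prediction expects
fresh-equivalent widths; dry summaries should pass through the dry→fresh
calibration first. The subsampling simulation draws m of the top-k widths
without replacement for a configurable number of rounds (default 10,
m ∈ {5, 10, 15}) to show how a reduced caliper survey disperses around the
full-set mean.

## Synthetic data

The scene generator renders non-overlapping filled superellipses
(|x/a|ᵉ + |y/b|ᵉ ≤ 1, e ∈ [2.0, 2.4]) at blue contrast 60 (object) vs 200
(background) with additive Gaussian pixel noise (sd 5) on a 40×40 cm board
at 0.05 cm/px. Exponents slightly above 2 make segmentation and moment
estimation non-trivial while keeping the axes analytically known: the
moment-equivalent axis of a superellipse is 2a·f(e) with
f(e) = 2√(B(3/e, 1/e+1)/B(1/e, 1/e+1)) (f(2) = 1, ≤1.033 on the default
range), and the truth table stores these expected axes. Non-overlap is
enforced by rejection sampling because splitting touching buds is out of
scope. Optional sub-floor "specks" exercise the area opening; optional
linear shading exercises its failure mode (the supported remedy is an edit
mask).

The population generator mirrors the design that motivated the package:
119 genotypes × 4 clones, ~250 buds per plant (Poisson with log-normal
plant rates), log-normal bud sizes (μ = 1.21, σ = 0.7 → mean ≈ 4.3 cm²,
strongly right-skewed), shape ratio ≈ 0.62, IDB = 0.12 g/cm² · TIC ·
(1 + ε), ε ~ N(0, 0.04²), and genotype/plant variance components on the
latent count, size and shape scales plus plant height and maturation traits.
Benchmarks in tests and the acceptance script use scaled-down populations
(40–100 genotypes) chosen to keep full runs within interactive times.

What passing these benchmarks shows: the geometry, estimators and pipeline
plumbing are correct against independent oracles and known ground truth.
What they do not show: robustness to real-world photography — uneven
lighting, shadows, touching buds, non-ideal backgrounds — which the original
workflow handled by manual mask editing, supported here but not simulated.

## Numerical conventions

* Sorts are stable everywhere ties matter (composite tiles, top-k selection,
  weight ordering), making all outputs deterministic for fixed inputs.
* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  the pipeline derives per-stage seeds from one top-level seed.
* The cumulative-share search uses a 1e-12 relative slack so exact-equality
  cases (equal weights) are not lost to float summation.
* Hull/axis tolerances in tests: 2% for digitized shapes with min axis
  ≥ 20 px (digitization error), 3% for rendered superellipse scenes
  (digitization + noise + analytic-factor truncation).
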