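# Methods

## Shape: symmetrization and generalized Procrustes analysis

A face is an ordered configuration of 72 two-dimensional points: 36
anatomically homologous landmarks and 36 semilandmarks sampling the face
outline and the brow/lip arcs.  Semilandmarks are treated as fixed
points; no sliding criterion is applied (the `kind_flags` field records
the distinction for future extension).  Frontal faces carry *object
symmetry*, so each configuration is symmetrized before alignment:
center, reflect across the vertical midline (negate x), swap the labels
within every bilateral pair, rotate the relabeled reflection onto the
original by the optimal rotation (reflections excluded), and average
pointwise.  The output is exactly symmetric under its own relabeled
reflection and the operation is idempotent to machine precision.  The
bilateral pairing table is a required input: it is not recoverable from
coordinates alone, so the package ships it alongside the template and
round-trips it as CSV.

GPA removes position, scale and orientation jointly across both sexes:
centroids are translated to the origin; each configuration is scaled to
unit centroid size (the pre-scaling sizes are recorded); orientations
are then iterated — rotate every configuration onto the current
consensus by the closed-form 2-D optimal rotation, recompute the
consensus as the plain arithmetic mean of the aligned configurations —
until the root-mean-square change of the consensus falls below `tol`
(default 1e-8, `max_iter` 100).  Design choices worth noting:

- **Consensus = arithmetic mean, not renormalized.**  Rotation targets
  are scale-insensitive, so leaving the consensus at its natural size
  keeps the identity "consensus equals the mean of aligned coordinates"
  exact, which downstream code and tests rely on.
- **Initialization = raw mean of the centered/scaled configurations**,
  falling back to the first configuration when arbitrary input
  orientations cancel the raw mean.  This makes already-aligned input a
  one-iteration fixed point and removes any dependence on input order.
- **Orientation anchor.**  After convergence the whole set is rotated so
  the consensus' principal axis is vertical.  The principal-axis
  covariance cannot distinguish a half-turn, so a third-moment sign
  convention (positive vertical skewness, then horizontal as
  tie-breaker) resolves the remaining 180° ambiguity, making the output
  rotation-unique and order-invariant.
- Degenerate configurations (zero centroid size) abort with the specimen
  named; reflections are never admitted into the rotation.

TPS files follow the tpsDig2 dialect (`LM=`, coordinate lines, optional
`IMAGE=`, `ID=`, `SCALE=`); `SCALE` multiplies coordinates on read, and
y-coordinates are stored as read (no image-origin flip).  Writing uses
shortest-round-trip float formatting so write∘read is bit-exact.

## Color: CIELAB measurement and facial contrast

sRGB values are converted to CIELAB (D65, 2° observer) via
scikit-image.  Region means are computed by converting pixels to Lab
*first* and then averaging over the mask — the measurement is taken on
the Lab-transformed image, matching colorimetric practice for selected
areas.  Overall skin color is the unweighted mean of five skin areas
(surroundings of eye, brow and lips, plus cheek and forehead) per
channel; the same five-area average is used for L\*, a\* and b\*.

Feature/skin contrast uses the adapted Michelson formula
C_f = (L_s − L_f)/(L_f + L_s) with the feature's *own* surrounding-skin
region as the reference.  The identical formula is applied to a\* and
b\*; for those channels operands can be negative, the |C| ≤ 1 bound is
not guaranteed, and values are stored unclipped.  Zero-denominator cases
and absent regions become missing values (NaN) rather than errors, so a
face with, say, an unmeasurable lip region is excluded only from the
analyses that need it.

## Dimorphism scores and the feature matrices

Both SShD and SCoD are mean-difference projections: with per-sex column
means FM and MM of a feature matrix, an individual row **x** scores
⟨x, MM − FM⟩.  The direction is deliberately left unnormalized — the
male−female difference in mean scores then equals ‖MM − FM‖² exactly,
an identity the tests verify to 1e-9 — with `normalize_axis=True`
available for distance-unit scores.  Scores may optionally be
mean-centered; no downstream statistic is affected.

The shape matrix is the aligned coordinates flattened to 144 columns
(x1, y1, …, x72, y72).  The color matrix has 15 columns by default:
cheek and forehead CIELAB (6) plus eye/brow/lips contrasts in all three
channels (9); a channel-selection option restricts to, e.g.,
luminance-only (5 columns).  Columns are *not* standardized by default —
the between-sex mean distances are reported in the mixed raw units the
measurements carry — but `standardize=zscore` exists because L\* (0–100)
otherwise dominates contrast columns (−1…1).  Missing data are handled
by listwise deletion per space, independently for shape and color, with
every exclusion logged into the run report.

## Inference

- **Permutation test.**  Observed statistic: Euclidean distance between
  the sex-mean vectors.  Null: sex labels shuffled without replacement,
  distance recomputed per replicate (vectorized), default 10,000
  replications.  p = (#{perm ≥ obs} + 1)/(B + 1), never exactly zero.
  The accompanying effect size is Cohen's *d* on the projection scores
  along the observed axis — the natural univariate reduction of the
  multivariate comparison — and is labelled "d (projection)" in output.
  Every result records its seed.
- **Cohen's d** uses the pooled SD with n₁+n₂−2 denominator, oriented
  male minus female.
- **One-way ANOVA** (two groups) reports F with df (1, n−2), p, R² =
  SS_between/SS_total and d; F equals the squared pooled t statistic.
  Degrees of freedom follow the classical n−2 convention throughout.
- **ICC(3,k)**: two-way mixed model, consistency, average measures,
  (BMS − EMS)/BMS from the two-way mean squares.  The matrix must be
  complete; incomplete designs (raters scoring random subsets) must be
  subset to complete cases upstream — the function refuses rather than
  imputes.

## The synthetic-data generator

The generator emulates the structure of a standardized frontal-photograph
study, with all parameters explicit and every draw deterministic given
the seed (independent substreams per population, purpose and stimulus
set).

- **Landmarks.**  Female faces are a bilaterally symmetric 72-point
  template plus isotropic Gaussian noise per coordinate (default SD
  0.03 template units ≈ 0.004 Procrustes units, i.e. total per-face
  shape deviation near 0.05 — the scale of real facial variation);
  males are additionally displaced by `m_shape` times a unit-norm
  male pattern (wider jaw, lowered brows, thinner lips), chosen for
  visual plausibility only — downstream code depends on its magnitude,
  never its anatomy.  Each raw configuration then receives a random
  rotation (±0.3 rad), scale (0.7–1.4) and translation, which the
  analysis must undo via GPA.
- **Colors.**  Region values are female means (plausible CIELAB skin and
  feature colors) plus per-region male offsets, a *person-level*
  per-channel deviation shared by all regions of a face
  (`color_noise_sd`, default L\* SD 3), and smaller independent
  per-region noise (`region_noise_sd`, default L\* SD 0.8).  The shared
  person effect is essential: with purely independent region noise the
  five-area average would shrink the noise by √5 and inflate every
  effect size; with a shared effect, an offset Δ over noise σ yields
  Cohen's d ≈ Δ/σ on the overall skin color, which the recovery tests
  exploit (Δ = −4, σ = 2 → d ≈ 2).
- **Ratings.**  rating = round(4 + stimulus effect + rater shift +
  noise) clamped to 1–7.  Expected ICC(3,k) ≈ σ_s²/(σ_s² + σ_e²/k);
  defaults (σ_s = 0.8, σ_e = 1.0, k = 30) target 0.95.  Rounding and
  clamping attenuate the coefficient slightly, which the test tolerances
  absorb.  An optional weight mixes a standardized per-stimulus
  covariate (overall skin L\*) into the stimulus effect so the
  attractiveness–lightness correlation step has signal of a controlled
  size.
- **Presets.**  Three populations mirror the qualitative dimorphism
  patterns and sample sizes of published three-population comparisons:
  Central-African-like (n = 113; male skin ~2 L\* units darker, no
  a\*/b\* dimorphism, moderate shape displacement), European-like
  (n = 98; negligible lightness difference, male b\* +1.2, largest
  shape displacement), Southeast-Asian-like (n = 91; skin-lightness
  dimorphism concentrated on cheek/forehead, none in b\*, strong
  brow/eye contrast dimorphism).  Offsets were set from the reported
  per-population effect sizes via d = Δ/σ and the corresponding mean
  distances; they are fixed study conditions, not free parameters.

What the generator does **not** model — and hence what passing tests do
not establish about real data: shape noise is isotropic and independent
across landmarks, whereas real facial variation is concentrated in a few
correlated modes.  One visible consequence: a realistic between-sex mean
distance (~0.02–0.04) over isotropic per-direction noise produces
projection-score effect sizes far larger (d ≈ 5–11) than the d ≈ 0.5–0.7
seen in real faces, where variance along the sex axis is much larger
than the isotropic split.  Distance estimates, permutation calibration
and ICC behavior are unaffected by this simplification; projected shape
effect sizes are not comparable to empirical ones.  There is also no
shape–color coupling and no photorealistic rendering.

## Numerical and design notes

- The between-sex mean distance is a positively biased estimator under
  noise: E‖M̂M − F̂M‖² ≈ ‖δ‖² + p·σ²(1/n_F + 1/n_M).  The recovery
  checks use sample sizes at which this closed-form bias is well below
  the 5% tolerance (shape: n = 500/sex, bias < 1%); the two-face
  noiseless fit supplies the exact Procrustes-space truth.
- Validation problem sizes (500 null datasets × 200 permutations for
  type-I error; 200/sex color recovery; 500/sex shape recovery; 100 × 30
  ICC) keep the full suite under a few seconds while leaving the
  binomial/simulation error bands comfortably informative.
- Reports are serialized with sorted keys and seeded randomness only, so
  identical configurations reproduce byte-identical JSON.
- ANOVA is restricted to two groups by contract (F = t²); the permutation
  test requires both sexes present and at least two specimens each.
- Known limitations: no sliding-semilandmark optimization, no 3-D
  landmarks, no automatic region segmentation or color calibration of
  photographs, no allometry decomposition of shape dimorphism, and no
  multiple-testing correction (none is part of the analysis design).
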