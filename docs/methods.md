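# Methods

## The model

`myoentropy` treats a transverse muscle section as a planar mosaic of
fibers and asks how far each fiber deviates from the population norm in
three structural traits: cross-sectional area (CSA), fiber-type
heterogeneity, and spatial connectivity. The working hypothesis is that
these deviations behave like an entropy: they accumulate with
disorganization, they agree with Shannon's information entropy when both
are computed on the same fiber groups, and at the participant level they
track functional decline.

### Feature extraction

A labeled segmentation mask (integer labels, 0 = background) is the sole
structural input; an aligned 3-channel MHC intensity image supplies fiber
types when they are not given directly.

- **CSA**: pixel count × pixel_size². `pixel_size` (µm/px) is a required
  configuration value because magnification alone does not determine it.
- **Typing**: per fiber, mean intensity per channel over the mask eroded by
  1 px (rook erosion), falling back to the full mask for 1–2-px fibers;
  the arg-max channel wins, ties resolving in the fixed order
  I > IIA > IIX. Hybrid (co-expressing) fibers are deliberately not
  modeled; arg-max typing understates true type complexity.
- **Adjacency**: two fibers are directly adjacent when they share an
  edge-adjacent (rook) pixel pair — a single corner contact is not a
  shared boundary. With `gap_tolerance` g ≥ 1 (default 1), fibers whose
  pixels lie within Chebyshev distance 1+g are also adjacent; this bridges
  the thin unlabeled laminin line that segmentation typically leaves
  between fibers. On synthetic masks, whose fibers touch directly,
  `gap_tolerance=0` recovers the generator's truth adjacency exactly.
- **Heterogeneity**: differing neighbors / total neighbors ∈ [0, 1];
  undefined (missing) for isolated fibers, which are excluded downstream
  with a logged count.
- **APL**: per participant sample, an undirected unweighted graph over the
  sample's fibers; each node's APL is the mean BFS distance to reachable
  nodes only (all-pairs shortest paths on a sparse matrix). Nodes with no
  reachable neighbor are missing. Graphs are built per sample, never
  pooled: cross-sample adjacency is physically meaningless.

### HDI_M

Features are z-scored within sex × fiber-type strata — up to six, using
sample mean and (n−1)-denominator SD per stratum; strata smaller than
`min_stratum_n` (default 10) raise by default or fall back to pooled
statistics (`on_small_stratum="pool"`). The reference centroid is the zero
vector; the covariance S is the (n−1)-denominator sample covariance of the
pooled z-features (fitted once on the whole population, not per stratum).
Then

    D_M = sqrt(xᵀ S⁻¹ x),   HDI_M = ln D_M   (no offset)

Fibers with a missing feature are dropped with per-stage counts; a fiber
exactly at the centroid raises by default (ln 0), or is dropped with
`on_zero_distance="drop"` — in practice the event has measure zero for
continuous features. The classical distance includes the square root;
`squared=True` logs D² instead, which exactly doubles HDI_M
(ln D² = 2 ln D) and therefore changes no rank-based or correlation
result. The participant-level index is the arithmetic mean of the sample's
fiber-level values (SD and fiber count are reported alongside).

**Internal referencing, a consequence worth stating**: because z-scores
and S come from the analyzed population itself, mean D² is always ≈ the
number of features. A cohort that is *uniformly* disorganized does not
look dysregulated relative to itself; contrasts exist only against a
shared reference population (this is why the theta-contrast test pools two
cohorts before scoring them, and why an all-older-adult cohort is expected
to deviate as a whole from a hypothetical young reference).

### Shannon-entropy validation

Retained fibers are stably sorted by (HDI_M, fiber id) and cut into k
contiguous groups with sizes ⌊n/k⌋ or ⌊n/k⌋+1, larger groups first; the
group median HDI_M is its representative value. Entropy of each component
is the plug-in estimator H = −Σ pᵢ ln pᵢ over one *global* histogram grid:
Freedman–Diaconis width 2·IQR/n^⅓ on the pooled standardized component
(IQR from linear-interpolation quantiles), anchored at the pooled minimum,
rightmost bin closed, out-of-range values clamped to end bins. If IQR = 0
the width falls back to Scott's rule (3.49·σ·n^-⅓) with a warning.
Normalized entropy is H/ln B over the B global bins (0 when B = 1), so a
group uniform over the global grid scores exactly 1. No bias-corrected
estimators (Miller–Madow etc.) are used — the plug-in estimator is the
convention being validated. Pearson r between group medians and group
entropies, with the two-sided t-distribution p, summarizes the agreement;
the modified index excluding area (restricting x and S to heterogeneity
and APL) provides the specificity contrast.

Group-size guidance: plug-in entropy is noisy below ~50 fibers per group
(a warning is logged). Analyses here keep ≈500 fibers per group — the
density implied by 300 groups over a ~148k-fiber population — and scale k
accordingly on smaller cohorts (e.g. k = n // 500). At 100 fibers/group
the area correlation degrades from ≈0.99 to ≈0.89 purely through
estimator noise.

### Association models

OLS with outcome and predictor z-scored on the complete-case analysis
sample per model (listwise deletion, logged; n varies by outcome), so the
predictor coefficient is a standardized β with normal-theory 95% CI and
two-sided p. Covariates stay on their raw scales; sex is coded F=0, M=1.
Model 1 = age + sex + BMI, with height replacing BMI for
weight-standardized outcomes (leg power, VO₂ peak); Model 2 = age + sex +
thigh muscle volume index + total abdominal adipose tissue index. The sex
interaction test adds sex × z(predictor) to Model 1 (Wald p). α = 0.05
two-sided, no multiplicity adjustment.

## The synthetic generator

The generator produces the study conditions every test runs under:

- **Tessellation**: Voronoi regions of an n-point jittered lattice
  (jitter default 0.35 of the pitch), rasterized by nearest-seed
  assignment with a 1-px background border at the field edge. This yields
  contiguous, convex-ish fiber-like regions with exactly known areas,
  centroids and rook adjacency. Default pitch 10 px per fiber.
- **Types**: i.i.d. draws from proportions (0.41, 0.35, 0.24) — the
  approximate population-median type shares renormalized over the three
  pure isoforms — or, with clustering c > 0, a random visiting order in
  which each fiber copies a random already-typed neighbor with
  probability c (denervation–reinnervation-style grouping).
- **Areas**: log-normal with exact type means (4535 / 3134 / 2238 µm² for
  I / IIA / IIX), area = mean·exp(σZ − σ²/2), so CV = √(e^σ² − 1).
- **Renders**: per-type channel-mean triplets (diagonally dominant) plus
  Gaussian pixel noise, clipped at 0; the returned mask is the label
  image itself, so noiseless renders round-trip exactly.
- **Cohort**: per participant, θ ~ Uniform(0,1) (configurable, including
  fixed ranges) maps linearly to σ ∈ [0.1, 0.8] and clustering ∈ [0, 0.9]
  — spanning realistic to extreme disorganization while keeping types
  identifiable. Covariates: sex (51.2% F), age ~ N(76.4, 5.3²) clipped to
  [70, 95], BMI ~ N(27.9, 4.8²) clipped to [18, 40] (the enrollment
  ceiling), sex-specific heights, muscle volume z ~ N(−0.8, 1), adipose
  index ~ N(4.4, 1.7²). Outcomes are β·z(θ) + standardized covariate
  effects + Gaussian noise on the standardized scale (residual SD chosen
  for unit total variance unless overridden), then rescaled to realistic
  units; planted β's default to the magnitude range −0.09…−0.27 across
  the seven outcome analogues (walk speed, SPPB, VO₂ peak, grip, leg
  power, max OXPHOS, ATPmax). All randomness descends from one integer
  seed via `numpy.random.SeedSequence` spawning, so every table and image
  is bit-reproducible.

**What the generator does not emulate**: real laminin-gap boundaries
(synthetic fibers touch; `gap_tolerance` matters only for real masks),
hybrid MHC co-expression, within-sample spatial gradients of θ,
non-convex or split fiber profiles, imaging artifacts, and any
age-dependence of θ. Passing tests therefore demonstrate the pipeline's
correctness and its ability to recover *planted linear* structure — they
do not certify the real-data effect sizes, which come from restricted
biopsy data.

## Numerical choices

- (n−1) denominators for every SD, covariance and IQR-adjacent statistic,
  so z-scores and S are bit-reproducible.
- Covariance singularity: condition number > 1e12 raises.
- Mahalanobis via explicit inverse of the (≤3×3) covariance; quadratic
  forms clipped at 0 against roundoff.
- Uniform bin occupancy returns the closed-form entropy maximum ln B and
  normalized entropy exactly 1; H/ln B is clamped to [0, 1] against ulp
  overshoot.
- Grouping ties: stable sort by (hdi, fiber id); remainder groups come
  first, so sizes are ⌊n/k⌋+1 × (n mod k) then ⌊n/k⌋.
- Sizing: a tessellation whose rasterization leaves any region empty
  raises rather than silently renumbering.

## Problem sizes

Default test and validation runs use 100-participant × 300-fiber cohorts
(30k fibers; ≈3 s end-to-end) and 1,000/500-replicate regression
calibrations at n = 300; the grouping-arithmetic check runs at the full
148,120-fiber scale, which is cheap because it is sorting, not imaging.
The package comfortably analyzes full-scale cohorts (299 × ~470 fibers)
in well under a minute on one CPU.

## Known limitations

- Arg-max typing cannot represent hybrid fibers; type shares of rare
  types are cohort-dependent (the population-median IIX share in real
  aged muscle is far below the generator's default 0.24, which was chosen
  so all six strata stay populated at test sizes).
- The adjacency gap rule is isotropic and pixel-based; it does not
  enforce a minimum shared-boundary length (a single rook contact
  suffices).
- Plug-in entropy is biased low in small groups; group sizes ≥ ~500 are
  recommended.
- Standardization of outcome/predictor happens per analysis sample, so
  βs across models with different missingness are not on literally
  identical scales (ns are reported per fit).
- The θ → (σ, clustering) maps are stand-ins for an unknown generative
  model of disorganization, not estimates of it.
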