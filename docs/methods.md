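# Methods

This note documents the models and procedures nichecast implements, the
choices made where a published description leaves the design open, and
what the synthetic test system does and does not establish.

## Data model

All computation happens on a regular geographic grid (`EnvGrid`): named
environmental layers sharing one shape, resolution (arc-minutes) and land
mask; masked cells carry NaN in every layer. Cell IDs are `(row, col)`
with row 0 at the northern edge. Point-to-cell binning uses half-open
intervals `[west, east)` × `[north, south)`, so a point on a boundary
belongs deterministically to the cell to its south-east. A grid cell is
one presence regardless of how many occurrence points fall in it; points
off-grid or in masked cells are dropped with a logged count. The
equatorial cell width uses a fixed 40,075 km circumference (10 arcmin →
18.55 km, printed as 18.6).

Background cells are sampled uniformly without replacement from the valid
cells and deliberately *include* presence cells: background represents
the available environment, not absence. Evaluation-time *pseudo-absences*
are the opposite — there they stand in for absences, so presence cells
are excluded from those draws to keep the labels coherent (a choice the
protocol description leaves open; it is logged, not hidden).

## Prevalence weighting

`class_weights(n_p, n_b, φ)` gives each presence row weight φ/n_p and
each background row (1 − φ)/n_b. Class totals are then φ and 1 − φ:
both published readings — "equal weight at 50%" and "a presence weighs
9× an absence at 90%" — hold simultaneously under this class-total
interpretation, which is why it was adopted over a per-row reading (the
two conflict when n_p ≠ n_b). All weights sum to 1; every weighted
likelihood here is invariant to rescaling them. `effective_prevalence`
returns n_p/n_b, matching the printed arithmetic 380/100,000 ≈ 0.004
(at that scale indistinguishable from n_p/(n_p + n_b); the docstring
records the distinction).

## Forward variable selection

Step 1 keeps the single predictor with the highest explained deviance of
a weighted binomial fit. Before each later step, candidates with
|Pearson r| ≥ r_max (default 0.8) against any selected predictor are
removed; correlations are computed over the training rows, unweighted —
the background dominates those rows, so this approximates the global
environmental correlation structure. The step's best candidate is
accepted when the χ² test on the weighted-deviance drop (df = parameters
added) has p ≤ α (default 0.05) *and* AIC decreases; the same rule
applies at step 1 against the intercept-only model, so pure noise yields
an empty selection. Ties on deviance resolve to the earlier candidate.

Numerical conventions: weights are rescaled to sum to the row count (AIC
is weight-scale dependent; a convention is required for cross-step
comparisons), and AIC is computed as deviance + 2k — for 0/1 responses
the saturated log-likelihood is zero, and this form stays finite when
fitted probabilities saturate at 0/1, where the textbook log-likelihood
expression overflows.

## Model families

* **GAM** — weighted binomial additive model with one degree-2 B-spline
  basis per predictor (boundary knots at the training min/max, one
  interior knot at the median, intercept-redundant column dropped: 3 free
  parameters per variable). This realizes "basis dimension 3" smooths as
  curvature-limited splines; prediction clamps each variable to its
  training range instead of extrapolating polynomial tails.
* **GLM** — weighted binomial regression on {x, x²} per predictor.
* **CART** — weighted classification tree; `ccp_alpha` chosen by
  stratified 5-fold CV on weighted Bernoulli deviance with the 1-SE rule
  (largest α within one SE of the minimum), so noise prunes to the root
  and leaves predict weighted presence proportions. Weights are
  normalized to mean 1 to keep the pruning path scale-invariant.
* **BRT** — gradient boosting (Bernoulli deviance, defaults: learning
  rate 0.01, depth 3, ≤500 trees); the stage count minimizing held-out
  deviance on an internal stratified 80/20 split is kept and the model is
  refitted on all rows at that count. Zero stages returns the constant
  weighted prevalence.
* **BIOCLIM** — per variable s_v = 1 − 2·|F_v(x) − 0.5| with F_v the
  mid-rank empirical CDF of the presence sample (mid-rank makes the
  presence median score exactly 1 for odd n); cell score = min over
  variables, 0 outside any presence range. The percentile-envelope form
  is the classic realization of the named method.
* **DOMAIN** — Gower similarity 1 − (1/V)Σ|x − p|/range_v (ranges over
  presence rows) to the most similar presence, clamped to [0, 1].
* **MAHAL** — raw score 1 − D² from the presence mean/covariance (1 at
  the centroid). Raw scores are rescaled linearly to [0, 1] over the
  region being predicted, so current and each scenario map individually
  span the unit interval (the reference region for rescaling is not fixed
  by the published description; per-target-grid rescaling keeps every map
  comparable). `predict_rows` on an arbitrary row batch rescales within
  that batch — rank-preserving, hence AUC-neutral. A singular presence
  covariance (degenerate variable) is an error, not a silent pinv.
* **MAXENT_LIKE** — presence/background exponential model
  q(x) ∝ exp(β·f(x)) with linear+quadratic features standardized against
  the background, fitted by maximizing the regularized presence
  log-likelihood over the background distribution; the L1 penalty is
  exact via the positive/negative-part split under L-BFGS-B bounds
  (default λ = 0.01). The logistic output uses the entropy transform at
  τ = 0.5: expit(H + η − log Z), so a model indistinguishable from the
  background predicts 0.5 everywhere. This is a reproducible,
  dependency-free approximation in the spirit of the well-known
  maximum-entropy SDM program, not a port: no hinge/threshold features,
  no per-feature regularization schedule.

Presence-only families (BIOCLIM, DOMAIN, MAHAL, MAXENT_LIKE) ignore the
prevalence weights — they have no likelihood term for background weight
to enter (the maxent-style model uses the background as a reference
distribution, not as weighted pseudo-absences).

## Evaluation, retention, consensus

AUC is Mann–Whitney concordance (ties count ½). The MST threshold scans
0, midpoints of consecutive unique scores, and 1, classifying
score ≥ t as presence; ties resolve to the lowest threshold. The
repeated-split protocol (default 10×) fits on 80% of presences + an
equal-count pseudo-absence draw and scores AUC and the MST triple on the
held-out presences + a disjoint equal-count draw; the threshold is
re-estimated on the test scores. Summaries are mean ± sample SD across
repeats. Retention keeps families with mean AUC ≥ 0.9 (inclusive); if
nothing qualifies the pipeline warns and falls back to the single best
family rather than emitting an empty consensus.

Consensus maps: cellwise mean/median, or `pca1` — first principal
component of the cells × members matrix with members centered, scores
oriented to correlate positively with the cellwise mean and min-max
rescaled to [0, 1] (sign and scale of a principal axis are conventions;
this pair makes it directly comparable to the other consensus maps).
Variance maps use denominator n − 1. Range change classifies binarized
current/future pairs as stable/contraction/expansion/absent; the
binarization threshold for consensus maps is the MST threshold of the
consensus scores at the training presences against the background sample
(which map the published figures were thresholded by is not stated; the
choice is recorded in each run's manifest).

## OMI

The environment is standardized by the mean/SD of the reference cell set
— the same globally sampled background used for modelling — so
marginality is in SD units of the available environment. The ordination
diagonalizes M = Σ w_k m_k m_kᵀ with taxon weights proportional to
presence counts (so the larger clade does not swamp the smaller under
equal weighting, nor vice versa); axes are unit-norm eigenvectors, the
eigenvalue sum equals Σ w_k‖m_k‖² (a trace identity the tests check to
1e-10). The specialization test draws `n_boot` random cell sets of the
presence count from the reference cells *without replacement* — the same
scheme a null taxon would be drawn by, making the test exact under
exchangeability — and reports p = (1 + #{boot ≥ observed})/(n_boot + 1).
Clade comparisons use Welch t-tests, one-sided in the direction of the
observed ordering (sidedness was specified without direction; the
direction is reported alongside p). The published OMI analysis used an
established multivariate implementation; this realization reproduces its
outputs (loadings, % variance, position/breadth, OMI statistic,
bootstrap p) but is documented on its own terms, not claimed identical.

## The virtual-species system

`make_env_layers` builds smooth, spatially autocorrelated fields
(Gaussian-smoothed white noise, σ = 6 cells, wrap-around boundaries),
standardized over valid cells, plus a decoy constructed from env1 and an
independent field's empirically orthogonal component so its correlation
with env1 is *exactly* the requested r (default 0.9 — the collinearity
level real bioclim variables routinely exceed). About 5% of cells are
masked as contiguous "sea" patches carved from another smooth field.

The true suitability is logistic(β₀ + Σβ₁x + Σβ₂x²) on two of the four
layers. Defaults put the niche optimum at (0.4, 0.3) SD with peak logit
4.5 and curvatures (−20, −16): a sharply bounded, *marginal* specialist
(mean suitability ≈ 0.08) occupying the warm side of the environment.
Marginality matters because OMI measures exactly that: a species whose
optimum coincides with the environmental mean has niche position ≈ 0 and
is correctly declared unspecialized however narrow its niche. The
steepness is what makes the species easy in the discrimination sense
(truth-model CV AUC ≈ 0.96) while keeping presences concentrated.
Presences are drawn without replacement with probability ∝ suitability
(one presence per cell, mirroring the gridding rule). "Future" climates
are deterministic layer shifts; the `strong` preset exceeds `mild` on
every shifted layer, standing in for a harsher emission scenario. Clade 1
(288 presences) samples the species surface; clade 2 (73) samples it with
the optimum shifted +1.5 SD along env1 — sizes and ratio follow the
two-clade invasion the analysis is designed around.

What the generator does *not* emulate: the covariance structure of the
real 19 bioclim variables, continents, spatial sampling bias, or
observation error. Passing tests therefore demonstrate the machinery
recovers known structure under clean conditions, not that any particular
real-world inference is correct.

Two knock-on properties of the chosen conditions are worth knowing:

* With a 0.5 SD-wide niche and a 1.5 SD clade offset, the pooled species
  response along env1 is bimodal. A curvature-limited GAM cannot
  represent two modes, so species-level forward selection ranks env2
  first and may admit weakly informative layers after it. The two-clade
  OMI fixtures therefore run on the true niche gradients.
* Tree-ensemble maps are piecewise constant. In the logistic-saturated
  tail (~90% of cells for a specialist this sharp) the truth still varies
  continuously at ~1e-6 scale, which no split can resolve; BRT's
  map-wide rank correlation with the truth is consequently capped near
  0.7 even while its CV AUC exceeds 0.95. This is a structural property
  of trees under rare-species conditions, not a fitting failure; smooth
  families (GAM/GLM/maxent-style) reach rank correlations ≥ 0.95 on the
  same maps.

## Pipeline and reproducibility

Three experiments from one YAML config: the prevalence sweep (one GAM per
φ), the family sweep at φ = 0.5 (fit, evaluate, retain, consensus +
variance over retained members, plus an all-members variance map for
contrast), and the clade analysis (per-clade GAMs reusing the
species-level selection, per-clade range-change maps, OMI). Variable
selection runs once at species level and is reused for the clades. Every
randomized stage derives its seed from the run seed; a fixed config
yields byte-identical outputs, and each stage writes a manifest with the
config hash and SHA-256 of every file. Fixture-scale defaults (100×100
grid, 5,000 background cells) keep a full run around half a minute on
one CPU; the global-scale template raises the background sample to
100,000 and expects real rasters.

## Known limitations

* Geographic lat/lon grids only; no projections, no area weighting of
  cells by latitude.
* Raster IO is ESRI ASCII grid only.
* The maxent-style model is intentionally limited to linear+quadratic
  features — capacity-matched to the other families rather than
  feature-rich.
* Evaluation splits are random, not spatially blocked; AUC against
  pseudo-absences inherits the usual optimism of that protocol (the
  equal-count design limits, but does not remove, it).
* OMI taxon and row weighting conventions differ between published
  implementations; results are documented for this one.
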