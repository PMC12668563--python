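# Methods

## The prediction problem

We model a binary disease outcome y ∈ {0,1} from a feature vector
containing demographics (standardized age, 0/1 sex), one polygenic risk
score (PRS) per disease, genotype principal components ("global" PCs
computed across ancestries and local PCs within one), and a metabolite
panel, for individuals from several ancestry groups with heavy imbalance.
All three model families are logistic regressions with different
regularization structure; discrimination is measured by ROC-AUC per
ancestry on a shared held-out test set.

## Penalized logistic regression (the substrate)

The solver minimizes the average negative log-likelihood plus a weighted
L1 penalty,

    (1/n) Σᵢ [log(1+e^{ηᵢ}) − yᵢηᵢ] + λ Σⱼ pfⱼ|βⱼ|,   ηᵢ = offsetᵢ + μ + xᵢᵀβ.

Conventions and numerical choices:

* **1/n loss normalization** so λ is sample-size-free; a sum-form loss is
  the same problem with λ relabeled by a factor n.
* **Standardization.** Penalized columns are scaled to unit variance
  internally; coefficients are reported on the original scale. The
  intercept and the offset are never penalized or standardized. The
  penalty therefore applies to the standardized coefficients; `objective`
  and `kkt_residuals` evaluate the same convention.
* **Penalty factors.** pfⱼ ∈ [0, ∞]; ∞ excludes a feature exactly, 0
  leaves it unpenalized. By default finite factors are rescaled to mean
  one (all-equal factors — including all-zero — rescale to one); the
  rescaling can be switched off to apply factors literally. This default
  matters for the pretrained lasso's α = 1 edge case (below).
* **λ path.** λmax = maxⱼ |xⱼᵀ(y − p̂⁰)| / (n·pfⱼ) over penalized features,
  with p̂⁰ the intercept-plus-offset-only fit; 100 log-spaced values down
  to λmax·10⁻⁴ (10⁻² when n < p). At λ ≥ λmax the fit is exactly the null
  model.
* **Solver.** Iteratively reweighted least squares with cyclic coordinate
  descent and soft-thresholding on the weighted quadratic subproblem
  (weights p(1−p) floored at 10⁻⁵), active sets grown by KKT screening,
  warm starts down the path, and an objective backtracking step that
  guards the Newton approximation. Convergence: maximum coefficient
  change < 10⁻⁷ on the standardized scale, with a final full KKT sweep.
  Solutions match an independent convex optimizer to ≤ 10⁻⁶ in objective
  on small problems (tested).
* **Cross-validation.** Stratified K-fold (default K = 3, seeded, folds
  recorded), held-out mean binomial deviance, λ chosen at the CV minimum.
  The grid is computed once on the full data and shared across folds.

## glinternet (hierarchical interactions)

Candidate interactions are all pairs (c, v) of a candidate covariate c
(default: age, sex, ancestry, the trained disease's PRS) with any other
column. Product columns are built from standardized parents and
re-standardized; reported effects live on that standardized scale. A
categorical covariate coded one-hot (ancestry; reference level = largest
group) acts as one block: a pair (ancestry, v) contributes one product
per level, kept together in its group.

Two grouping modes:

* **per-pair (default).** One singleton group per main effect plus, per
  pair, a group {copy of main i, copy of main j, product i:j} in the
  latent/duplicated-variable formulation (the reported main effect is the
  sum over copies). Group sparsity then implies the strong hierarchy:
  θ_{i:j} ≠ 0 ⇒ θ_i ≠ 0 and θ_j ≠ 0, which the test suite asserts on
  every returned fit.
* **per-variable.** Groups partition the design: G_u = {mains of u} ∪
  {products of pairs led by u} (a pair is led by its lower-indexed unit).
  Only a group-level hierarchy holds; the mode is kept because the
  literature describes both group definitions, and they differ.

Group weights γ_g = √|g| (standard group-lasso sizing). The solver is a
majorized block coordinate descent: each outer iteration builds the IRLS
quadratic model and sweeps active groups with per-group step sizes from
the weighted Gram's largest eigenvalue and group soft-thresholding
(`(1 − λγ_g·s/‖z_g‖)₊` scaling); KKT screening grows the active set and an
objective backtracking step guards the local approximation. The inner
sweeps run in a compiled (numba) kernel with a pure-numpy fallback. The
path starts at λmax = max_g ‖Z_gᵀ(y − ȳ)‖₂/(nγ_g) (all groups zero) with
50 grid points to λmax/100 by default (the study pipeline uses 25–30 for
throughput); an optional stop rule ends the path once a pre-specified
number of interactions is selected. Activity along the path is
effectively monotone; rare re-entry events are tolerated and logged by
the tests, not failed.

## Pretrained lasso (two-stage transfer)

Stage 1 fits the pooled lasso and keeps β̂⁰, μ̂⁰ and support S at the
CV-minimizing λ. Stage 2 fits each ancestry k a lasso on its own rows
with offset (1−α)(X_k β̂⁰ + μ̂⁰) and penalty factors
pfⱼ = (1−α)·[I(j∉S)/α + I(j∈S)]:

* α = 0: offset is the full pooled prediction; off-support features get
  pfⱼ = ∞ (excluded), on-support pfⱼ = 1 — the second stage can only
  re-weight the pooled model's own features.
* α = 1: zero offset and, literally, pfⱼ = 0 everywhere — an unpenalized
  second stage. With the default mean-one penalty-factor normalization
  the all-zero factors rescale to one, recovering an ordinary per-group
  lasso; both behaviors are selectable (`normalize_pf`).
* Default α = 0.5 with an optional sweep over {0, 0.25, 0.5, 0.75, 1}
  scored by the mean second-stage CV deviance.

Each group's second-stage λ is chosen by its own stratified CV (sharing λ
across groups is a plausible alternative; per-group tuning was chosen
because group sizes differ by an order of magnitude). Groups whose rows
contain a single outcome class fall back to the overall model, logged.
Predictions route each row through its ancestry's second stage including
its offset; unseen ancestries fall back to the overall model with a
warning.

## Evaluation

* **AUC** is the tie-corrected Mann–Whitney statistic (mid-rank
  convention), so `auc(s, y) + auc(−s, y) = 1` exactly.
* **DeLong test** for paired ROC curves: placement-value structural
  components give Var(AUC_a − AUC_b) including the covariance; z = Δ/√Var
  with a one-sided normal p-value. The directional hypothesis is
  "candidate > baseline" (candidates are only compared against the
  baseline trained on the same dataset configuration, so test sets are
  paired by construction). Degenerate zero-variance cases: p = 0.5 when
  Δ = 0 (flagged), else p ∈ {0, 1} with a warning. No multiple-testing
  correction by default (a switch exists); significance tiers are `*`
  p < 0.05 and `**` p < 0.01.
* **Win counts.** Each (ancestry, disease) column's best AUC is a "win"
  for its method; under the chance null a method trained on d of D
  method-dataset combinations wins a column with probability d/D. The
  test is the exact binomial upper tail (exact rather than normal because
  the study grids are small, e.g. 24 columns).

## Study pipeline

One stratified train/test split (default 80/20, strata = ancestry ×
joint outcome pattern; singleton strata are merged into their ancestry's
largest stratum) is reused for every model and dataset configuration, so
all comparisons are paired. Training sets are Specific ⊂ Mix ⊂ All row
selections from the training side. The baseline is trained on all three;
glinternet and the pretrained lasso on Mix and All (7 combinations per
cell). Only the trained disease's PRS column enters the design (leakage
guard; other diseases' PRS are excluded by default). A disease×ancestry
cell requires ≥ 20 positive cases to be evaluated. Three named seeds
(generation, split, CV) make runs bit-reproducible end to end.

## Synthetic cohorts: what they emulate, and what they don't

The generator reproduces the statistical features the models are
sensitive to: ancestry imbalance via largest-remainder rounding of
configurable proportions; global PCs as ancestry centroids (separation
2.5 SD) plus unit noise, with a two-subcluster ±1.2 SD substructure on
global PC 4 so PRS×PC4-style interactions have something real to find;
exchangeable (compound-symmetry) correlation within metabolite blocks —
the simplest structure that produces the collinearity motivating grouped
selection; a PRS per disease whose main-effect coefficient is derived
from a target PRS–liability correlation (c = ρ·sd(η)/√(1−ρ²), with the
remaining-liability sd estimated on the generated sample, floored at 1);
and per-ancestry outcome intercepts calibrated by Brent root-finding so
realized prevalences hit their targets to 10⁻⁶ in the mean. `bayes_auc`
simulates a single-ancestry population through the same machinery and
scores outcomes with the true liability — an upper-bound reference for
any fitted model (for that function the PRS coefficient is derived from
the single-ancestry liability sd).

Not emulated: linkage disequilibrium or any real-genotype structure (the
PRS is an abstract correlated score, as consumed — not computed — by the
models), measurement error and missingness, non-logistic outcome
mechanisms, and correlation between diseases (outcomes are independent
given the features). Passing tests therefore demonstrate correctness of
the estimators and the qualitative behavior of the methods under the
assumed liability model, not performance on real biobank data.

Default study conditions used by the shipped tests and the acceptance
script are desk-scale: cohorts of 1,600–4,000 rows with 2–3 ancestries
and 17–30 columns for end-to-end runs, and n = 2,000–5,000 with up to 50
features for recovery checks; `cohort.ukb_like_spec()` exposes the
full-scale configuration (n = 96,913; 249 metabolites, 40 global and 10
local PCs; five ancestry groups at the real cohort's imbalance, with
per-ancestry disease prevalences taken from its case table)
for users who want realistic proportions at any n_total.

## Known limitations

* The per-pair hierarchy guarantee is structural (group-level); a summed
  main effect could in principle cancel to exactly zero across copies,
  though this has measure zero and has never been observed in the test
  battery.
* The group-lasso solver's IRLS curvature is a local (not global) bound;
  the backtracking safeguard makes every accepted step a descent step,
  and final solutions are KKT-certified, but worst-case iteration counts
  are not theoretically bounded.
* The win-count null assumes exchangeable columns; correlated diseases or
  ancestries would make the binomial reference anti-conservative.
* `alpha_sweep` selects α by second-stage CV deviance, which ignores the
  stage-1 fit's own uncertainty.
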