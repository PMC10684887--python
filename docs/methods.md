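# Methods

`repsample` corrects selection bias in a tabular sample by reweighting it
against a representative reference sample. This note records the models,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Setting

Two cohorts share a feature schema: a representative reference sample R
(drawn so that its empirical distribution matches the target population)
and a non-representative sample N whose inclusion mechanism distorted its
distribution. The goal is a nonnegative weight per row of N such that the
weighted N is indistinguishable from R. An optional outcome column is
held out of the features: weighting never sees it; it is used only to
monitor how well a *hidden* variable is corrected (possible exactly to
the extent the features carry information about it — see *Limits* below).

The framing is positive-unlabeled discrimination: label R as one class
and N as the other, train a classifier, and read each N row's predicted
cohort probability as a measure of how over-represented it is.

## Distribution distance

Progress is measured with the empirical maximum mean discrepancy between
R and (weighted) N under an RBF kernel,

MMD(X, Y) = [ m^-2 Σ K(x_i,x_j) − 2(mn)^-1 Σ K(x_i,y_j) + n^-2 Σ K(y_i,y_j) ]^{1/2},
K(x, y) = exp(−‖x−y‖² / 2σ²).

The V-statistic form (self-pairs included) is used; it is nonnegative up
to round-off, and tiny negative round-off of the bracket is clamped to
zero before the root. σ is the mean Euclidean distance over distinct
pairs of the pooled sample (self-distances excluded — the zero diagonal
would shrink σ systematically). Features are z-scored with pooled R∪N
mean/sd before any kernel computation, because the distances are
scale-sensitive; tree classifiers see raw encoded features (trees are
scale-invariant). For weighted N the empirical mean embedding is replaced
by the weight-normalized embedding; the weighted form reduces exactly to
the unweighted one under uniform weights and is invariant to positive
rescaling of the weights.

Within one iterative run σ is frozen at iteration 0, so the MMD
trajectory is comparable across iterations; a moving bandwidth would make
the greedy minimization chase a moving target. A flag on the trajectory
runner allows recomputing σ per iteration instead.

## MRS: iterative hard removal

Each iteration: pool R with the active rows of N, run a stratified 5-fold
CV, fit a random forest per fold, and collect out-of-fold probabilities
of belonging to N. The `drop_count` active rows with the highest
probability get weight 0 (ties broken by stable input order, for
reproducibility). The loop stops when a cost-complexity-pruned decision
tree can no longer separate the cohorts: its pooled out-of-fold AUROC
satisfies |AUROC − 0.5| ≤ δ (default δ = 0.001). Retained rows keep
weight exactly 1, so the result is a plain subsample usable by methods
without weight support.

Choices that matter:

* **Removal classifier.** Random forest with 25 trees and
  `min_samples_leaf = 5`, fixed across iterations — per-iteration
  hyperparameter search would multiply the (already dominant) refit cost.
  The leaf-size floor smooths leaf probabilities; fully pure leaves
  saturate many rows at exactly 1.0, which turns removal order into a
  tie-break artifact.
* **Stopping tree.** Resubstitution AUROC of an unpruned tree is ≈ 1 and
  would never stop, so the check uses pooled out-of-fold scores of a
  pruned tree. Pruning strength is chosen per fold by an internal 3-fold
  CV minimizing held-out misclassification over ≤ 6 alphas subsampled
  from the cost-complexity path. The terminal path alpha (root collapse,
  constant scores, AUROC exactly 0.5) is excluded from the candidates,
  and ties go to the smaller alpha: total pruning must strictly win,
  otherwise the stop would fire as a tie-break accident rather than a
  property of the data.
* **Floors.** `min_active` (default max(2·folds, 20)) keeps the CV
  well-posed. Trajectory studies run with `exhaust=True`, which ignores
  the AUROC rule for termination (it is still recorded as the
  would-have-stopped iteration) and runs down to the given floor.
* Stratification is on the cohort label only. The positive/unlabeled
  test split is realized implicitly by the CV folds.

## Soft-MRS: multiplicative reweighting

All rows keep strictly positive weights. Per iteration and per candidate
tree size (grid of `min_weight_fraction_leaf` values, default
{0.01, 0.02, 0.05, 0.1, 0.2}), a single unpruned tree is fitted on the
pooled cohorts — no cross-validation — and every N row receives

w_i ← w_i · (0.5 + p_rep,i),

where p_rep is the tree's probability of the representative cohort: a
confidently representative-looking row gains 50%, a confidently
non-representative one loses 50%, p = 0.5 leaves the weight unchanged.
The candidate grid value whose updated weights give the lowest weighted
MMD is committed (greedy), and the run stops when the best-so-far MMD has
not improved for `patience` = 25 consecutive iterations (or at the
iteration cap, default 500). The returned weights are the best-so-far
iterate — the stale weights of the final stalled iteration would by
construction be worse than the optimum the patience window was tracking.

Numerical choices: weights are renormalized to mean 1 after every update
(pure multiplicative updates drift in scale; the weighted MMD is
scale-invariant, so normalization changes nothing the optimizer sees).
The reference cohort's total training weight is scaled to match N's
current total, so the discriminating tree cannot collapse onto the larger
cohort. Within a run the kernel matrices are precomputed once (σ frozen),
making each candidate evaluation a quadratic form rather than a fresh
kernel pass. A degenerate single-leaf tree yields a constant factor that
normalization absorbs — the update is then a fixed point, not an error.

## Baselines

* **Uniform** — weight 1 everywhere; the no-correction reference.
* **PSA** — ridge-penalized logistic regression for cohort membership on
  the pooled cohorts; with π the probability of the non-representative
  cohort, each N row gets (1 − π)/π, upweighting representative-looking
  rows. π is clipped to [10⁻⁶, 1 − 10⁻⁶] under separation (with a
  warning).
* **KMM** — minimize ½βᵀKβ − κᵀβ over 0 ≤ β ≤ B, |Σβ − n| ≤ nε, with K
  the RBF kernel matrix over N (ridge 10⁻⁸ on the diagonal) and
  κ_i = (n/m) Σ_j k(n_i, r_j); σ from the pooled-sample heuristic.
  Defaults B = 1000 and ε = (√n − 1)/√n follow the method's original
  formulation. The quadratic program is solved by scipy's trust-constr
  with exact gradient and Hessian behind an injected-solver contract, so
  tests can substitute a dense grid-search oracle on tiny instances.

## Evaluation statistics

Relative bias |(Ȳ − ȳ_w)/Ȳ|·100 compares the weighted mean of a held-out
variable in N with its representative mean (undefined at Ȳ = 0). AUROC is
the rank statistic (ties at ½); AUPRC is the step-integral average
precision; the 1-D Wasserstein distance operates on weighted empirical
quantile functions; method ranks use average ranks for exact ties. The
downstream statistical demo fits a weighted logistic regression (GLM with
frequency weights) and tests the slope with a likelihood-ratio test
against χ²₁.

## Synthetic data and bias injection

The generator draws a two-group mixture: four numeric features with
group-specific means (unit covariance), one three-level categorical
feature with group-specific frequencies, and a binary outcome from a
logistic model on the encoded features. Two injectors distort a cohort:

* **mean-distance selection** — keep row i with probability proportional
  to exp(−s·‖x_i − x̄‖³), s = 0.05, anchored so the row nearest the mean
  is kept with probability ~1; distances use z-scored numeric features
  (indicator columns unscaled). Rows far from the center are
  under-selected, shrinking the spread — the classic covariate-shift
  mechanism.
* **class-ratio selection** — keep a uniform 10% of one outcome class and
  every row of the other, mimicking outcome-dependent participation.

What the generator does *not* emulate: real survey data has many more
features, mixed missingness, measurement error and cluster/strata
structure. Passing recovery tests show the algorithms correct the two
injected mechanisms on clean tabular data; they do not certify
performance on any particular survey.

## Limits of covariate reweighting — and experiment design

Class-ratio selection conditions on the outcome, which shifts p(y|x) as
well as p(x). Reweighting on features can only remove the p(x) part, so
the attainable relative-bias correction for the hidden outcome is capped
by how strongly the features determine it: with perfect density-ratio
weights the weighted prevalence equals E_R[q(x)/(q(x) + 0.1(1 − q(x)))],
q(x) = p(y=1|x). The class-ratio recovery experiments therefore use a
strongly coupled population (`strong_coupling_spec`, log-odds
coefficients 5× the defaults) for which this cap sits near 25% of the
uniform-weights bias, so the experiment measures the algorithm rather
than the information-theoretic ceiling. With the default moderate
coupling the soft reweighter already sits within a few points of the cap
— the residual bias is conditional shift no covariate method can remove.

A second structural limit affects the planted-outlier experiment: the
removal forest scores a lone remaining outlier by the leaf it falls into,
and once no other outlier is left in the training folds that leaf is just
the bulk's extreme tail, whose cohort composition is a coin flip. The
last one or two planted outliers are therefore not reliably ranked above
the noisiest in-distribution rows — removal precision is high but not
exactly 100%, and the experiments report it as a measured precision
rather than asserting perfection.

## Problem sizes and runtime posture

The bundled experiments run at desk scale, chosen once: null and planted
MRS runs use cohorts of 300 (20 seeds), the soft-recovery experiment a
population of 2000 split 1000/1000 (10 seeds), and the downstream
comparison a population of 600 with 20 trials (δ = 0.02 at these sizes —
the AUROC noise floor at n ≈ 300 is far above 0.001, which is tuned to
cohort sizes in the thousands). The acceptance script uses the same
protocols with fewer repeats.
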