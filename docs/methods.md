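# Methods

This note documents the statistical procedures implemented in `netsurv`,
the parameters that matter, the design choices made where the design was
genuinely open, and the known limitations — in particular what the
synthetic-cohort experiments do and do not establish.

## Cohort model and preprocessing

The package operates on a gene × sample TPM matrix joined to a per-sample
clinical table (patient ID, overall survival in months, death indicator,
primary/recurrent timepoint). Patients may own several samples; outcomes
are per patient, and every operation that could leak information across a
patient's samples (cross-validation, path patient-pooling) works at the
patient level.

Preprocessing follows the conventions of consortium TPM releases:

* **Zero filter.** A gene is removed when *more than* `zero_fraction_max`
  (default 0.8) of its values are exactly zero; the boundary is kept.
* **Normalization.** log2(x+1), then per-gene z-scores. The SD uses
  `ddof=1` (sample SD) so that a three-point log2 row (0, 1, 2) maps to
  (−1, 0, 1); zero-variance genes become all-zero rows with a warning
  rather than NaNs. Train and test folds are normalized separately —
  each fold is treated as its own cohort, so no training statistics are
  reused on held-out data (the reuse variant is available by normalizing
  up front).
* **Folds.** Patients (sorted, then shuffled by the seed) are split into k
  near-equal folds; samples inherit their patient's fold. Default k = 5.
* **Screen.** Each gene is dichotomized at its median (ties to the low
  group) and tested with a two-group log-rank test; the `top_n` (default
  1,000) smallest p-values survive, with ties broken by descending
  statistic then gene ID. Constant genes get p = 1.

## The network marker-discovery stage

Per training fold:

1. **Nodes.** For each screened gene, the ⌈0.1·n⌉ samples with largest
   |z-score| (ties by sample ID) form the extreme set. One-dimensional
   single-linkage clustering groups them: on the line, single-linkage merge
   heights are the sorted adjacent gaps, and the tree is cut where those
   heights jump the most (at most `max_clusters` = 4 clusters; equally
   spaced gaps mean no structure and give one cluster). Clusters smaller
   than `min_cluster_size` = 3 are discarded. Clustering only the extreme
   set keeps nodes interpretable as "patients in which this gene is
   extreme".
2. **Graphs.** Each of `n_graphs` (default 1,000) iterations draws one
   cluster per gene uniformly and connects two nodes when they share at
   least `min_overlap` = 1 patients, weighted by the shared-patient count.
   One node per gene prevents within-gene edges from dominating.
3. **Walks.** `walks_per_graph` (default 100) self-avoiding walks start at
   a uniformly chosen non-isolated node and step to an unvisited neighbor
   with probability proportional to edge weight, stopping when stuck or at
   `max_len` = 10 nodes. Walks of fewer than 2 nodes are dropped.
4. **Path tests.** Distinct node sequences are deduplicated; each path
   pools the union of its nodes' patients and is tested patient-vs-rest
   with a two-group log-rank test (significance at `alpha` = 0.05). Pools
   smaller than `min_group` = 10 patients, or leaving fewer than
   `min_group` patients outside, are untestable and excluded from all
   margins.
5. **Enrichment.** Per gene, the 2×2 table (significant/non-significant ×
   contains/doesn't contain the gene) over testable paths is tested with a
   one-sided Fisher exact test (hypergeometric upper tail), BH-corrected
   across genes; selection at q < 0.05.
6. **Consensus.** Genes selected in ≥ `min_folds` = 3 of the 5 folds.

All randomness flows from one seed through per-fold substreams, so runs are
bit-reproducible. The per-path log-rank tests and the gene screen use an
internal vectorized log-rank kernel that the test suite pins to the
lifelines implementation.

### Known limitation: path-level enrichment is liberal at high walk counts

The Fisher test treats each distinct path as an independent observation.
Paths are not independent: with a dense graph (any shared patient makes an
edge) nearly every walk reaches `max_len` and pools a large patient group,
path patient-sets overlap heavily, and the number of distinct paths grows
with `n_graphs × walks_per_graph` while the underlying cohort information
does not. Consequently the per-gene evidence against independence grows
without bound in enumeration effort: any gene whose extreme clusters have
even a small, fixed, within-cohort chance association with survival will
eventually reach arbitrarily small q-values. At the default scale (1,000
graphs × 100 walks per fold, ~10⁵ paths) this manifests as a tail of
low-confidence consensus calls beyond the planted markers, and as a
non-empty consensus set even on cohorts simulated with no survival signal.
Planted markers are nevertheless recovered with overwhelming margins (their
enrichment odds are an order of magnitude larger), and ranking the
consensus by mean q separates them cleanly. Users who need a calibrated
false-discovery rate should either run few walks (evidence bounded by the
graph count), treat the consensus as a ranking rather than a fixed-level
test, or validate calls on held-out data. This behavior is a property of
path-counting enrichment itself, not of a particular parameter setting.

## Penalized Cox comparators

The comparator selectors minimize the penalized negative Breslow partial
log-likelihood L(β) = −ℓ(β) + λ[α‖β‖₁ + (1−α)‖β‖₂²] (ridge α = 0, lasso
α = 1, elastic net default α = 0.5) on standardized inputs. Smooth problems
(no L1 term) use L-BFGS; otherwise a monotone proximal-gradient iteration
with backtracking and soft-thresholding, so lasso/elastic coefficients are
exactly zero when shrunk out. Convergence is an objective change below
1e−7 (relative). λ is chosen by inner 5-fold cross-validated
Verweij–van Houwelingen partial-likelihood deviance on the training fold.
Across outer folds, genes are ranked per fold by |β| (ties by gene ID) and
the `top_k` smallest rank sums are selected (ties by mean |β|); `top_k`
defaults to the size of the network consensus set so the feature sets are
comparable.

## Model evaluation

Four model families sit behind one risk-score / survival-function API:
Cox PH (lifelines), elastic-net Cox (the package's solver with a Breslow
baseline), random survival forest (scikit-survival; 500 trees, log-rank
splits, √p features per split, bootstrap per tree), and a linear ranking
survival SVM (scikit-survival; regularization 1.0). The SVM has no native
survival curves, so curves come from a univariate Cox calibration of its
decision values on the training data — used only where an evaluation needs
S(t).

* **C-index** is Harrell's: among pairs with t_i < t_j and subject i an
  observed event, the fraction where risk_i > risk_j, ties counting ½.
* **Brier score** at horizon t uses inverse-probability-of-censoring
  weights from the Kaplan–Meier estimate of the censoring distribution G:
  events by t contribute S(t)²/G(T⁻), subjects beyond t contribute
  (1−S(t))²/G(t), censored-by-t subjects contribute nothing. The
  **integrated** score is the trapezoid integral over {0} ∪ unique event
  times, normalized by the last grid time; grid points with G = 0 are
  dropped with a log message.
* **Stratification** splits subjects into 2 (median) or 3 (tertile)
  near-equal groups by prognostic-index rank (stable order on ties, group
  sizes within one), tested with the standard k-group log-rank; hazard
  ratios between groups come from a univariate Cox fit, reported pairwise
  against the low-risk group with Wald 95% intervals.
* The cross-validated harness re-normalizes train and test separately,
  fits on training samples only, and reports per-fold/replicate metrics
  with means and SDs (default 10 replicates of a 5-fold split).

## Log-normal AFT inference

The AFT likelihood for (β, σ) is Σ_events [log φ(z) − log(σt)] +
Σ_censored log(1 − Φ(z)), z = (log t − xβ)/σ. Optimization runs over
(β, log σ) (keeping σ positive) with analytic gradients from β = 0,
intercept at the mean log event time, σ at the SD of log event times; the
covariance is the inverse observed information (numeric Hessian),
transformed to the (β, σ) scale. Wald 95% limits use z = 1.96; the
chi-square column is (estimate/SE)². A singular information matrix (e.g. a
constant covariate) falls back to a pseudo-inverse with a warning.

Hazard ratios are HR = exp(−β/σ): covariates that lengthen survival time
(β > 0) have HR < 1. Interval estimates apply the delta method to
g = −β/σ with gradient (−1/σ, β/σ²) on the (β_j, σ) covariance block.
Weibull (Gumbel error) and log-logistic (logistic error) variants share
the same machinery for AIC-based family comparison (AIC = 2k − 2ℓ̂;
non-convergent families are excluded from the choice with a warning).

## Recurrence screen

For each gene, an unpaired two-sided Mann–Whitney test compares all primary
versus all recurrent samples, and a Wilcoxon signed-rank test compares
matched pairs (one pair per patient; when a patient has several samples at
a timepoint the lowest sample ID — a proxy for resection order — is used,
logged). Tests run on log2(x+1) values, not z-scores: per-set z-scoring
would erase exactly the group shifts under test. Exact null distributions
are used up to 25 observations without ties, otherwise tie-corrected normal
approximations with continuity correction. Zero paired differences are
dropped; all-zero differences give the degenerate (0, p = 1) output.
P-values are BH-corrected per test across genes, and a gene is flagged when
both q-values fall below 0.05 (a raw-p mode exists behind a flag).

## Synthetic cohorts

`simulate.generate_cohort` emulates the target data structure: 158 patients
/ 180 recurrent samples (the first 22 patients contribute a replicate
sample with extra log2 noise of SD 0.3), gene baselines uniform on 1–6
log2-TPM with unit noise, and 5% of genes made ~90% zero so the filter has
work. Survival follows the log-normal AFT generative model with intercept
3.25 (median ≈ 26 months) and scale 0.567; the planted prognostic genes
(default 3) act through their z-scored patient-level expression with
β* = −0.25 each — the top of the coefficient-magnitude range a
multivariable fit of this size reports, so planted markers are detectable
but not cohort-dominating. The planted genes share one over-expressed
patient block (default 25 patients, +2.5 log2 units), which both shortens
those patients' survival and guarantees that the planted genes' extreme
clusters share patients — the structure the network stage is designed to
detect. Censoring is independent Uniform(0, c) with c solved by Brent's
method so the expected censored fraction matches the target (default
11.1%). `generate_paired_samples` adds a primary sample per patient and a
recurrent sample for a configurable fraction, with planted log2 shifts in
designated genes.

What the simulations do **not** emulate: realistic gene–gene correlation
beyond the single planted block, batch structure, or any relationship
between expression and censoring. Passing recovery tests therefore shows
the machinery is correct and powered under its own generative assumptions,
not that the method's selections on real cohorts are calibrated (see the
limitation above).

## Numerical conventions

* Ties: median dichotomization sends values equal to the median to the low
  group; extreme sets and rank selections break ties by ID for
  determinism; stratification uses stable rank order.
* The log-rank kernel assigns zero variance contributions to risk sets of
  size ≤ 1 and returns (0, p = 1) for degenerate splits.
* All stochastic stages draw from `numpy` Generators seeded from a single
  master seed (per-fold substreams via `SeedSequence.spawn`), making every
  pipeline bit-reproducible.
* Experiment scales in the test suite (cohort sizes of 40–200 patients,
  60–200 genes, hundreds of graph iterations for module tests and the full
  1,000 × 100 walk budget for the recovery experiment) were chosen as the
  smallest sizes at which each property is identifiable with comfortable
  margins.
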