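# netsurv

Network-based discovery and evaluation of prognostic gene-expression markers
in right-censored survival cohorts, built around the study design of
recurrent IDH wild-type glioma transcriptomics: ~158 patients contributing
~180 tumor samples, TPM expression for >20,000 genes, overall survival in
months with ~11% right-censoring, and paired primary/recurrent samples for a
subset of patients.

## What it does

The core method (`netsurv.network`) discovers markers from *patient-sharing
graphs*:

1. per gene, take the samples with the top 10% highest absolute normalized
   (log2, z-scored) expression and group them by one-dimensional
   single-linkage clustering — each retained cluster of patients is a
   candidate node;
2. repeatedly (default 1,000×) sample a graph with one cluster per gene,
   connecting nodes that share patients (edge weight = shared-patient count);
3. run weight-proportional self-avoiding random walks; each walk's pooled
   patients form a candidate risk group, tested against the rest of the
   cohort with a log-rank test;
4. call markers by one-sided Fisher enrichment of each gene in significant
   paths (BH-corrected), and keep genes selected in ≥3 of 5 patient-grouped
   cross-validation folds (the consensus set).

Around it, the package provides the full evaluation stack used to study such
markers:

* `preprocess` — zero-fraction gene filter, log2/z normalization, patient-
  grouped k-fold splits, median dichotomization, univariate log-rank screen;
* `penalized` — ridge / lasso / elastic-net Cox comparators,
  L(β) = −ℓ(β) + λ[α‖β‖₁ + (1−α)‖β‖₂²] with Breslow ties, plus rank-sum
  feature selection across folds;
* `evaluate` — Harrell's C-index, IPCW (integrated) Brier score, prognostic
  indices (Xβ for Cox models, ensemble mortality for random survival
  forests, decision values for ranking survival SVMs), median/tertile risk
  stratification with log-rank tests and hazard ratios;
* `aft` — censored maximum likelihood for the log-normal accelerated failure
  time model log T = Xβ + σW, W ~ N(0,1), with per-gene hazard ratios
  HR = exp(−β/σ), delta-method confidence intervals, and AIC comparison
  against Weibull and log-logistic alternatives;
* `recurrence` — paired (signed-rank) and unpaired (rank-sum) Wilcoxon
  screens of primary-vs-recurrent expression with BH correction;
* `simulate` — synthetic cohorts with planted prognostic patient blocks,
  calibrated censoring, and planted recurrence shifts, so every stage is
  testable with known ground truth.

## Worked example

```python
from netsurv.simulate import SimConfig, generate_cohort
from netsurv.network import NetSurvivalConfig, run_netsurvival
from netsurv.preprocess import filter_low_expression_genes, log_z_normalize
from netsurv.cohort import Cohort
from netsurv.aft import fit_aft_lognormal

config = SimConfig(n_patients=80, n_samples=88, n_genes=60,
                   n_prognostic=3, block_size=16)
cohort, truth = generate_cohort(config, seed=7)     # truth.prognostic = G00000..G00002
cohort = Cohort(expression=filter_low_expression_genes(cohort.expression),
                clinical=cohort.clinical)
net = NetSurvivalConfig(n_graphs=200, walks_per_graph=30, k_folds=4, min_folds=3)
result = run_netsurvival(cohort, net, seed=7)
print(result.consensus.head(5))
```

prints

```
  gene  folds_selected       mean_q  consensus
G00001               4 5.032957e-08       True
G00000               4 2.549650e-06       True
G00005               4 4.269129e-04       True
G00002               4 1.155341e-03       True
G00054               4 6.233135e-03       True
```

The three planted prognostic genes (G00000–G00002) head the consensus
ranking; the tail of weaker calls below them illustrates the liberal
behavior of path-level enrichment at high walk counts discussed in
`docs/methods.md`. Fitting the log-normal AFT model to the top markers:

```python
genes = result.consensus_genes[:3]
normalized = log_z_normalize(cohort.expression).subset_genes(genes)
fit = fit_aft_lognormal(normalized.values.T,
                        cohort.clinical["time"].to_numpy(),
                        cohort.clinical["event"].to_numpy(), terms=genes)
print(fit.params.round(3))
```

```
parameter  estimate    se  ci_lower  ci_upper  chi_square     p    hr
Intercept     3.309 0.068     3.176     3.442    2382.998 0.000   NaN
   G00001    -0.268 0.085    -0.434    -0.101       9.935 0.002 1.552
   G00000    -0.275 0.085    -0.442    -0.109      10.504 0.001 1.572
   G00005    -0.105 0.071    -0.244     0.034       2.176 0.140 1.188
    Scale     0.609 0.049     0.513     0.705         NaN   NaN   NaN
```

A negative coefficient shortens log survival time, so its hazard ratio
exp(−β/σ) exceeds 1: higher expression of G00000/G00001 accelerates death,
as planted.

The same pipeline is scriptable from the shell:

```sh
netsurv simulate --seed 7 --out-dir run --set n_genes=60
netsurv select-net --expression run/expression.tsv --clinical run/clinical.tsv \
    --seed 7 --out-dir run --set n_graphs=200 --set walks_per_graph=30
netsurv aft --expression run/expression.tsv --clinical run/clinical.tsv \
    --features run/features.txt --out-dir run
```

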