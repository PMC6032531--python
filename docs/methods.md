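# Methods

## The statistical model

### Random-variance-model moderated t-test

For gene g with pooled two-group sample variance s_g² on m = n₁ + n₂ − 2
residual degrees of freedom, the model assumes the gene-wise precision
1/σ_g² is Gamma-distributed with shape a and scale b (equivalently σ_g² is
inverse-gamma). Under this hierarchy a·b·s_g² follows an F distribution with
(m, 2a) degrees of freedom. The prior is fitted by maximizing the
F-likelihood of {a·b·s_g²} over (log a, log b) with Nelder–Mead, started
from method-of-moments estimates (derived from E[s²] and E[s⁴]; the moment
solution is only valid for a > 2, so the start is clipped to [1.2, 100] and
the MLE does the real work). If the optimizer fails, the moment start is
returned with a warning.

The moderated variance is a precision-weighted compromise

    σ̃_g² = (m·s_g² + 2/b) / (m + 2a),

the moderated t is the mean difference over √(σ̃_g²·(1/n₁ + 1/n₂)), and
two-sided p-values use a t reference with m + 2a degrees of freedom. Under
the hierarchical model with the true (a, b) this statistic is exactly
t-distributed, which is why the synthetic null calibration test can demand
a 5% rejection rate at α = 0.05 to binomial accuracy. As a → 0 with the
prior-target term 2/b → 0, the statistic reduces to the ordinary
pooled-variance Student t (asserted to 1e-6 in the tests).

Genes with zero pooled variance are assigned p = 1 and flagged rather than
dropped, so downstream tables never silently lose rows.

### Fold change and screening

Expression values are log2-scale by convention (linear input can be log2
transformed on load; non-positive values are rejected). log2 FC is the
difference of group means (responder − non-responder) and FC = 2^log2FC;
whether published fold changes are ratios of linear means or 2^(Δ of log2
means) is generally ambiguous, and the latter is what this package
computes. The screen keeps |log2 FC| > 0.5 and p < 0.05, both strict
inequalities; both thresholds are parameters. (Published descriptions of
this workflow also mention a fold-change-1.2 criterion in places; the
procedural |log2 FC| > 0.5 rule is the default here.)

### Network prioritization

Edges strictly above the median combined score survive the edge filter
(with all scores equal, nothing survives — a documented degenerate case).
The network is the undirected, deduplicated subgraph on the screened genes;
isolated genes are excluded. Centralities: degree is the incident-edge
count by default (the "sum of connection strengths" reading — a weighted
sum of combined scores — is available behind `weighted_degree`, but
published major-gene tables show small integers consistent with counts);
closeness is (n_c − 1)/Σd within each connected component; betweenness is
unnormalized shortest-path betweenness over all pairs (cross-component
pairs contribute nothing). All shortest paths are unweighted. Because the
selection rule is "strictly above the median" on each feature, it is
invariant to any monotone rescaling of a centrality; the absolute closeness
values published for the original network match no standard normalization,
and no attempt is made to reproduce them — only ranks matter here.
Centralities are computed on the median-filtered, DEG-restricted subgraph
(filter → subset → centralities).

Candidates are the major genes with p < p_threshold and FC strictly above
fold_threshold or strictly below its reciprocal, sorted alphabetically.

### PLS patient score

Per-gene standardization uses the training mean and SD (ddof = 1); the
response is coded +1/−1 and centered, which makes the weight-sign property
exact: for one component the maximizer of cov²(Xw, y) is w ∝ Xᵀy normalized
to unit length, so sign(W_i) equals the sign of the training covariance of
gene i with the response. With n_components > 1 the standard NIPALS
deflation runs and the aggregated per-gene coefficient vector W(PᵀW)⁻¹q is
stored; the default is one component, appropriate for six genes and a dozen
samples. A candidate gene with zero training variance raises an error
naming it.

The classification threshold T maximizes Youden's J over candidate cutoffs
at midpoints between adjacent distinct training scores, plus one cutoff
below the minimum and one above the maximum. Ties break toward maximal
accuracy and then toward the lower cutoff, so the scan is deterministic;
when even the best cutoff has J = 0 the result is flagged degenerate. The
"ROC-derived cutoff" phrasing common in the field is read as this Youden
maximization, since AUC itself is cutoff-free.

Model JSON serialization stores gene order, center, scale, weights, T and
labels at full float precision; round-trips are lossless.

### Cross-platform validation

Weights and threshold describe standardized expression, so they transfer
across measurement platforms; the stored center/scale do not (microarray
log2 intensities sit near 7, comparative-Ct log2 relative quantities near
0). `validate(..., restandardize=True)` — used automatically for
qPCR-derived matrices — refits the per-gene center/scale on the validation
cohort and keeps W and T. Without this, scores are shifted by a platform
constant: ranking (AUC) is unaffected but thresholded accuracy collapses.

### Evaluation

ROC curves sweep distinct score cutoffs with ties grouped; trapezoidal
integration makes the AUC equal the Mann–Whitney U/(n₁·n₂) with ties
counted half. Cross-validation is stratified k-fold (default k = 5)
repeated R times (default 5) with per-repeat seeded shuffles; "5-fold
cross-validation (five times)" descriptions are ambiguous between folds
and repeats, and R × k reporting covers both readings. Standardization,
weights and threshold are all refit on each training fold (the per-fold
threshold and training center are exported in the report so leakage is
testable). Correlated AUCs are compared with DeLong's variance estimator
(the field standard when the comparison statistic is unnamed); a
zero-variance, zero-difference comparison returns p = 1. Group comparisons
use one-way ANOVA via `scipy.stats.f_oneway`, with all-identical input
returning p = 1 by convention.

### Enrichment

Over-representation uses the plain hypergeometric upper tail against a
user-supplied background (default: the expression platform's genes), with
Bonferroni and Benjamini–Hochberg corrections side by side and
"significant" meaning both corrected values < 0.05. This is a deliberate,
documented substitution for web-service enrichment scores (e.g. DAVID's
EASE-modified Fisher statistic), whose internals are a service rather than
a specification.

### Comparative-Ct quantification

Replicate Ct values are averaged per (sample, gene) before ΔCt (the common
convention; the per-replicate-first order is available and agrees exactly
for balanced replicates). ΔCt = Ct_gene − Ct_reference; the calibrator
defaults to the non-responder group's mean ΔCt (overridable to a named
sample), so the calibrator group's geometric-mean rq is 1 and group
contrasts read directly off responder rq values. rq = 2^−ΔΔCt with
amplification efficiency fixed at 2; no efficiency correction or replicate
outlier rejection. Each reference gene (GAPDH, RPS18) yields its own
relative-expression table and expression matrix; no geometric-mean
combination of references is attempted. Replicate SDs of ΔCt are
propagated as √(sd_gene² + sd_ref²).

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes, no more:

- gene variances from the inverse-gamma-type prior with a = 3, b = 1
  (prior mean variance 1/(b(a−1)) = 0.5 on the log2 scale — a realistic
  spread for moderately noisy arrays) and baselines N(7, 1) log2 units;
- a `de_fraction` (default 5%) of genes whose groups are separated by
  exactly `log2_effect` with random sign, half up and half down in
  responders (the fixed magnitude makes the planted truth unambiguous for
  recovery experiments; the canonical effect of 2 log2 units is a strong
  but realistic biomarker magnitude);
- an Erdős–Rényi background network (mean degree 2) over all genes with
  uniform integer scores in [150, 999], the STRING-like score dialect;
  each planted hub (10% of DE genes) gains 12 spokes to other DE genes
  with scores from the upper half of the range, so hub edges survive both
  the median filter and the DEG-subgraph restriction;
- triplicate Ct tables with two group-independent reference genes (GAPDH
  base 18 cycles, RPS18 base 16), candidate baselines uniform in [22, 28],
  a shared per-sample offset (SD 0.5 cycles) that cancels in ΔCt, Gaussian
  replicate noise (SD 0.2 cycles), and responder Ct lowered by the planted
  log2 fold change.

Everything derives from one integer seed via independent per-stage
substreams; a `cohort_id` selects the sampling-noise stream while the
planted structure depends on the seed alone, so a discovery cohort and an
independent validation cohort share their ground truth.

What the generator does **not** emulate: probe-level microarray artifacts,
normalization residuals, batch effects, missing data, gene–gene
correlation beyond the planted network (expression noise is independent
across genes), or realistic PPI topology (scale-free degree
distributions). Passing recovery tests therefore demonstrates that the
pipeline's logic is correct under its own assumptions, not that those
assumptions hold for any particular clinical dataset.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run at desk scale: 2,000-gene
cohorts (null calibration over 20 seeds, i.e. 40,000 null p-values;
end-to-end hub recovery over 20 seeded runs at 8+8 samples), 10,000-gene
prior-recovery fits, and a discovery/validation experiment at the original
design's sample sizes (6+6 training, 15+16 qPCR validation). These sizes
give stable Monte-Carlo estimates in seconds while exercising every stage;
all randomness flows from the `--seed` argument or explicit test seeds.

## Known limitations

- The published cohort-dependent numbers (212 DEGs, 16 major genes, the
  printed CV accuracies and validation AUCs) depend on a specific
  discovery microarray matrix and undeposited validation qPCR data; the
  package reproduces the *procedures* and checks them against planted
  synthetic truth instead.
- The published weights/threshold fixture is used only for the scoring
  contract; the expression scale those weights were derived on is not
  stated, so refitting them is out of scope.
- Identifier namespaces are the caller's responsibility: expression and
  edge tables must share one gene namespace.
- DeLong p-values are asymptotic and optimistic at very small n; at the
  31-sample validation scale they are indicative, not exact.
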