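# Methods

`subtype-awa` evaluates competing multi-omics cancer-subtyping methods on one
cohort. Each method contributes only its cluster assignment (sample → subtype
label, with a configured cluster count K); the harness computes validity and
clinical-relevance metrics, harmonizes them across methods, and aggregates
them into a single accuracy-weighted average (AWA) per method.

## Input model and alignment

Three artifact kinds, all TSV: per-omics feature matrices (samples × features;
copy number, DNA methylation β values, mRNA, miRNA, optionally proteomics and
phosphoproteomics), a clinical table (`os_time` in days, `os_event` ∈ {0,1},
plus a typed covariate set defaulting to gender, age at diagnosis, pathologic
T/M/N/stage), and one assignment file per method with 1-based integer labels.

Real cohorts rarely align perfectly, so differing sample sets are resolved by
intersection (with a logged report of dropped samples) rather than an error;
the canonical sample order is the omics order restricted to the intersection.
A cluster emptied by the intersection is an error — the method's configured K
would silently change otherwise. Alignment is idempotent.

## Preprocessing

Per omics kind, applied feature-wise (the sample set and order never change):

* **Copy number** — duplicate regions (identical value vectors, missing
  compares equal to missing) are removed, keeping the first by input order.
* **Methylation** — probes are kept when their mean β across non-missing
  samples is ≥ `beta_threshold` (default 0.3, boundary inclusive). The source
  rule ("features with β values ≥ 0.3") is ambiguous between mean/any/all;
  mean is the least brittle reading and the one implemented. Array platforms
  (HM27/HM450) are modeled as a plain union of probe ids.
* **mRNA / miRNA** — `log2(x + 1)`, then removal of the lowest-MAD fraction
  of features (`mad_quantile`, default 0.5, computed per feature on the log
  scale, ties broken by input order), then removal of features with variance
  ≤ `variance_threshold` (default 0). The MAD→variance order is part of the
  contract; no absolute MAD cutoff exists in the source procedure, so a
  quantile is the configurable stand-in.
* **Proteomics / phosphoproteomics** — features with missing fraction
  > `missing_fraction_max` (default 0.5, strictly greater) are dropped,
  remaining gaps are imputed with the feature mean, the top-MAD features are
  kept (same quantile rule), and each sample is median-centered.

All kinds finish with imputation of remaining missing entries using the
*sample* (row) mean within the omics — the literal reading of "imputed using
the sample mean"; the conventional feature-mean variant is available via
`PreprocessConfig(imputation="feature_mean")` — followed by per-feature
z-scoring with population (1/n) variance. Constant features become all-zero
columns with a warning instead of being dropped, so downstream shapes stay
predictable.

## Internal validity metrics

Computed with Euclidean distances on a sample representation that defaults to
the horizontal concatenation of all standardized omics layers (fixed kind
order). The alternative `per_omics_mean` strategy computes each metric per
omics layer and averages; neither choice is canonical, and the default was
fixed once (concatenation uses all evidence in one geometry).

* **Silhouette S** ∈ [−1,1]: per sample, `a` = mean distance to its own
  cluster's other members, `b` = mean distance to the nearest other cluster;
  the width is (b−a)/max(a,b), averaged over samples. Samples in singleton
  clusters contribute 0 (a is undefined there; 0 is the common convention),
  as do duplicate points with a = b = 0.
* **Calinski–Harabasz CH** = (tr B_k · (n−k)) / (tr W_k · (k−1)) with
  tr B_k = Σ_c n_c‖x̄_c − x̄‖² and tr W_k = Σ_c Σ_{i∈c}‖x_i − x̄_c‖².
* **Dunn D** = min over cluster pairs of the single-linkage (minimum
  pairwise) inter-cluster distance, divided by the maximum cluster diameter.

Degenerate geometries (all clusters point masses for CH; all singletons for
D) return +inf sentinels with a warning rather than raising, so the scoring
layer can still rank; a single cluster is an error because the indices are
undefined there.

## Clinical metrics

* **LRT** — unstratified k-sample log-rank chi-square (k−1 df) comparing
  survival across subtypes, with standard simultaneous risk-set handling of
  tied event times. Samples missing survival are dropped for this test only;
  zero events overall yields p = 1 with a warning.
* **ECP** — the count of clinical covariates associated with the subtype
  labels: Pearson χ² without continuity correction for discrete covariates
  (a warning flags expected counts < 5), Kruskal–Wallis for numeric ones,
  counted at α = 0.05. No multiple-testing correction is applied by default
  (the count is of nominally enriched parameters); Benjamini–Hochberg is
  available via `adjust="bh"`. Missing covariate values are dropped per test
  (pairwise deletion); an all-missing covariate leaves the ECP denominator.

## Harmonization and AWA

Raw metrics live on incomparable scales, so each is oriented (larger =
better; the log-rank p becomes −log10 p with p floored at 1e-300; +inf
sentinels map just above the largest finite value) and min–max rescaled
across the evaluated methods onto [0,10]. When all methods tie on a metric,
every method receives the neutral 5. The published score construction is not
printed anywhere; min–max was chosen because it reproduces the observed 0–10
range and admits non-half-integer values, unlike rank scoring — this remains
the single largest open interpretation in the package. A consequence worth
remembering: scores are *relative to the method set*, so adding or removing
a method changes scores (never raw metrics) through renormalization, and at
least two methods are required.

The five scores combine as

    AWA = ((S_S + S_CH + S_D)·w1 + (S_LRT + S_ECP)·w2) / (3·w1 + 2·w2)

with default w1 = w2 = 0.5 (internal and clinical evidence equally weighted).
AWA is a weighted mean: it is bounded by the five scores, monotone in each,
invariant to positive rescaling of (w1,w2), and at equal weights reduces to
(3·Ī + 2·C̄)/5 for the internal/clinical score averages. Ranking is by
descending AWA with deterministic tie-breaks (internal average, then method
name). A weight sweep recomputes AWA over a list of (w1,w2) pairs. Runtime
(RT) is reported from optional assignment metadata and never enters AWA.

## Synthetic cohorts

The generator states a simple world in which every stage is testable:

* **Omics** — per cluster, a centroid with offsets of magnitude δ (signs
  random) on a random half of the features; samples are centroid + N(0, σ²).
  Expression layers are generated as 2^(latent+5) so values are nonnegative
  and the log2 step recovers the latent scale; methylation is generated in
  logit space and squashed to (0,1) so β filtering is exercised; entries are
  masked missing uniformly at `missing_rate`. Defaults (δ = σ = 1, 2%
  missing, 40–100 features per layer, 50 samples per cluster, K = 3) give a
  detectable but non-trivial signal at desk scale; real TCGA marginals,
  copy-number segmentation and batch structure are deliberately not imitated,
  so a green test establishes correct *mechanics and ordering behaviour*, not
  realism of any absolute metric value.
* **Survival** — exponential event times with per-cluster multiplicative
  hazards (defaults: baseline 0.001/day ≈ 1000-day mean survival, multipliers
  (1,2,3)); independent exponential censoring with its rate solved by
  bisection so the expected censored fraction matches `censoring_rate`
  (default 0.3, typical of TCGA-like cohorts).
* **Clinical covariates** — discrete covariates are drawn from cluster-tilted
  category distributions, probability (1−s)/m + s on the cluster's preferred
  category, where s is the association strength; age is Normal(60 + 10·s·c,
  10²). The default schema associates three of the six covariates (age,
  pathologic T, pathologic stage) and leaves three null.

One `numpy.random.default_rng(seed)` generator drives all draws in a fixed
documented order, so a seed fully determines every output byte.

`perturb_labels` degrades an assignment by giving a uniformly chosen fraction
of samples labels drawn uniformly over **all** K clusters. The alternative —
drawing only from *other* clusters — was rejected after measurement: at K = 2
a full flip is then exactly the label-swapped truth (the identical
partition), and at K = 3 it produces a structured rotation-mixture that
retains survival and covariate signal, so "fully perturbed" would not be the
worst method. With uniform redraw, flip fraction 1 is chance-level labels by
construction; the price is that a redrawn sample can keep its label, so the
expected fraction of changed labels is f·(K−1)/K rather than exactly f.

## Numerical conventions

* Population (1/n) variance throughout standardization and scatter traces.
* Min–max scores are clipped to [0,10] against floating-point overshoot.
* p-values floored at 1e-300 before −log10.
* All orderings (duplicate retention, MAD ties, rankings) are stable with
  documented tie-breaks, so identical inputs give byte-identical outputs.

## Known limitations

* The 0–10 score mapping is a reconstruction (see above); comparisons against
  published score tables are therefore qualitative.
* ECP counts uncorrected nominal significances: with three null covariates
  the chance that at least one is falsely counted is ≈ 1 − 0.95³ ≈ 14% per
  cohort. This is inherent to the counting rule, not a defect of the tests —
  the `ecp_recovery` acceptance check documents the resulting ceiling
  (ECP recovers the exact ground-truth count in ~86%, not ≥95%, of
  replicates).
* Internal metrics are O(n²) in memory via the pairwise distance matrix;
  fine for cohort sizes in the hundreds-to-thousands range, not for
  single-cell scale.
* No Cox modelling, no pairwise post-hoc survival contrasts, no plotting.
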