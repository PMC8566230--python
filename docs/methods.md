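# Methods

`nbgf` implements an expression-to-phenotype analysis pipeline for
neuroblastoma-style bulk transcriptomes: subtype discovery on growth-factor
gene expression, a MYCN-stratified penalized survival model, pathway
activation scoring, pre-ranked gene set enrichment, gene-set prognostic
scoring (GPScore), and dose-response / synergy analysis. This note records
the models, their assumptions, the defaults that matter, and what the
synthetic-data validation does and does not demonstrate.

## Data model and normalisation

Expression lives in an `ExpressionMatrix`: samples x genes, non-negative
linear-scale values, with an explicit normalisation state. Two
normalisations are used downstream:

- **fold-from-mean** — each gene divided by its mean over the dataset's
  samples, applied per dataset before merging (`merge_datasets` keeps only
  genes present in every dataset, logging the dropped count). A fold value
  of 2 reads "twice the cohort-average expression". Used for clustering,
  the survival model, and sample-level set scores.
- **quantile** — all samples forced onto the common rank → mean-of-sorted
  distribution; ties receive the average of their tied target values, which
  preserves each sample's total signal. Used before case-to-normal pathway
  scoring.

Clinical annotations (`ClinicalTable`) carry overall-survival time/event,
MYCN status, INSS stage, metastasis, and therapy response; "no response",
partial response, and relapse all count as poor response.

## Subtype discovery

Tumors are embedded with UMAP (correlation metric, `n_neighbors=50`,
`min_dist=0`) on log2 fold-from-mean expression and clustered with HDBSCAN
(`min_samples=50`, `min_cluster_size=100`); density outliers keep the label
−1 ("no cluster"). The defaults assume a cohort of roughly a thousand
tumors; for smaller cohorts `min_cluster_size` should scale down (we use
`max(10, n/12)` in the validation runs). Raw fold ratios are right-skewed,
so the embedding works on their log2; fold values below 1e−6 are floored
before the log.

Cluster markers are called gene-by-gene with two-sided Mann–Whitney tests,
cluster vs all other clustered samples, Benjamini–Hochberg-corrected over
every (cluster, gene) pair. The reported log2 fold change is taken against
the mean over **all** clustered samples, so a shift planted in a cluster
holding a fraction *f* of samples appears diluted: a +s log2 shift yields
log2fc = s − log2(f·2^s + 1 − f). Cell lines are assigned to the cluster
maximising S = Σᵢ log2(expᵢ)·cᵢ over that cluster's significant markers
(cᵢ = +1 up, −1 down); exact ties are reported as ambiguous.

## Survival model

The outcome model is elastic-net-penalized logistic regression of survival
probability, p(z) = 1/(1+e^(−z)) with z = y₀ + Σᵢ ωᵢ·expᵢ on fold-from-mean
expression, fitted separately for MYCN-amplified and non-amplified tumors
(MYCN dominates prognosis and flips the sign of several gene effects).
The binary label is survival past a landmark of 1825 days (5 years);
patients censored before the landmark carry no label and are excluded from
fitting. Training is two-round on a stratified 70/30 split: round 1 fits
all candidate genes with (α, l1) chosen by 5-fold cross-validation on the
training split (α over a 7-point log grid 10⁻³…10³, l1 over 0.1…0.9, F1
scoring); round 2 refits on the top fraction of genes by |ω|, scanning keep
fractions 10–50% and keeping the fraction with the best F1 on the held-out
30% (ties favor the smaller panel). The keep count is floor(fraction·n),
minimum 1. Samples with unknown MYCN status are scored with the
non-amplified parameters. Predicted probabilities map onto five contiguous
risk bins: [0, .40) "<40%", [.40, .60), [.60, .85) "60-80%", [.85, .95),
[.95, 1] ">95%" — the gap between 80% and 85% in the conventional labels is
closed by extending the 60–80% bin to 0.85.

## Pathway activation level (PAL)

A pathway is a gene list with activator/repressor roles
ARR ∈ {−1, −0.5, 0, 0.5, 1}. For a case sample, CNR_g is its expression
over the control-group mean (pseudocount 1e−6 on both sides, so 0/0 → 1),
and

PAL = Σ_g ARR_g · log2(CNR_g) / Σ_g |ARR_g|.

The log base is a pure rescaling and is fixed at 2; the denominator is the
total role weight, so PAL is the role-weighted mean log-ratio and an
ARR = 0 member is inert. Differential activation between phenotype groups
first prefilters genes by a two-sided t-test (p < 0.05), computes PAL per
sample against the reference-group mean over the surviving members, and
compares groups with an unpaired t-test, BH-corrected over pathways. The
reference group is the good-response (or localized) group, so PAL > 0 means
activation in the aggressive phenotype; swapping the labels negates every
PAL difference exactly. Note the prefilter makes the pathway-level p-values
deliberately anti-conservative under the global null (it selects genes with
group differences); null calibration of the t-test machinery is therefore
done with the prefilter disabled.

## Pre-ranked GSEA

Genes are ranked by Pearson correlation with a target gene (ties broken by
gene id; zero-variance genes get metric 0 with a warning). The enrichment
score is the weighted Kolmogorov–Smirnov statistic: hits advance the
running sum by |metric|^p / Σ_hits |metric|^p (p = 1, the "weighted"
scheme), misses retreat by 1/(N − N_hits); ES is the extremum by absolute
value. Significance uses a gene-set-membership permutation null of matched
size (not phenotype permutation — standard for pre-ranked mode and cheap at
desk scale): NES divides ES by the mean |null ES| of the same sign, nominal
p is the empirical same-sign tail with the (r+1)/(n+1) convention, and the
FDR follows the sign-stratified pooled-null procedure. Sets passing nominal
p < 0.05 and FDR < 0.25 are reported, best NES first, capped at 100.

## GPScore

Each gene is classified by splitting the cohort at its median expression
and running a log-rank test between the halves: "unfavorable" when the
high-expression half has more events than expected, "favorable" otherwise,
significant only below 0.05 after Bonferroni correction over the number of
genes tested per dataset. (An optional scan mode tries expression quantiles
0.1–0.9 and adds a Bonferroni factor for the cutoffs tried; the median
split is the deterministic default.) A gene set scores

GPScore = Nu / (Nu + Nf)

over its prognosis-significant members; sets with Nu + Nf = 0 are flagged
and excluded from calibration. The null baseline draws 20 random gene sets
(sizes uniform over a configured range, 50–1000 for genome-scale universes)
from the measured genes and reports their mean, SD and mean ± 3σ.
Cross-dataset significance compares each set's per-dataset scores with the
per-dataset null means by a two-sided one-sample t-test on the deviations,
BH-corrected, significant at q < 0.01. The sample-level companion score is
the mean squared fold-from-mean expression of the set's genes, split into
quartiles Q1 (highest) … Q4 for Kaplan–Meier stratification; an all-equal
score vector is flagged degenerate.

The Kaplan–Meier estimator and the one-degree-of-freedom log-rank test are
implemented directly on numpy arrays because the per-gene scans evaluate
them thousands of times per cohort; both are cross-checked in the test
suite against hand-derived oracles and against lifelines.

## Dose-response and synergy

Viability is blank-subtracted and scaled to the DMSO control, clipped to
[0, 1.5] (the upper slack tolerates growth stimulation). Single-agent
curves are four-parameter logistic fits (top, bottom, IC50, hill) by
`least_squares` with soft-L1 loss (`f_scale=0.03`, i.e. residuals beyond
about 3% viability count roughly linearly), with IC50 parametrised on the
log scale; the robust loss keeps a single gross outlier among 8 points from
moving the IC50 by more than ~10%. Bliss synergy takes inhibition
f = 1 − viability, expected combination inhibition f_a + f_b − f_a·f_b, and
reports the observed excess per well plus 100 × the mean excess over the
combination wells (the mean-over-matrix summary; the full excess matrix is
returned for region-level readings). Growth-factor protection compares the
per-cell-line viability fold (drug+GF)/(drug) against the matching DMSO
fold with a Friedman test blocked by cell line; the two-treatment case uses
the tie-corrected rank statistic directly since scipy requires three or
more treatments.

## Synthetic cohorts: what they emulate, and what passing means

`nbgf.simulate` generates the validation conditions: log-normal background
expression (per-gene level uniform on log2 3–8, multiplicative noise
sd 0.5 log2 units, matching microarray-intensity behavior), three planted
subtypes with 20 cluster-specific genes shifted by 2 log2 units,
MYCN-amplification as a cluster-dependent Bernoulli flag (48%, 10%, 1% —
aggressive cluster enriched), and Weibull proportional-hazards survival
(shape 1.5, scale 3000 days, uniform censoring on [0, 6000]) whose log
hazard is shifted by Σ β·log2(expression) over planted prognostic genes.
For model-recovery runs, "strong" planted effects mean β = 2 per unit log2
expression: the discrimination of the *true* predictor is then AUC ≈ 0.95
on a fresh cohort, leaving headroom for estimation loss; at β = 1 the
information ceiling itself is ≈ 0.85 and no estimator can beat it.

For prognostic-set recovery, the planted poor-prognosis and protective
programs are co-regulated: genes of the same effect sign share a latent
per-sample program activity (loading 0.6 log2 units) and carry small
per-gene hazard coefficients (±0.1). This mirrors how real gene sets
behave — the members of a process co-vary — and is what makes "most genes
of the set are individually prognosis-significant" achievable at n = 300;
with fully independent effects, many individually-significant genes would
require an implausibly noisy total hazard. The module option is off by
default.

Dose-response grids place seven concentrations per drug from IC50/16 to
4×IC50 plus the zero dose; the cap at 4×IC50 keeps combination wells below
full inhibition so that clipping inhibition to [0, 1] does not erase the
planted Bliss excess (a small residual downward bias, ~0.5 on the ×100
scale, remains from occasional clipping at the top corner).

What the synthetic cohorts do **not** emulate: probe-level microarray
artifacts, platform batch effects beyond per-dataset scaling, correlated
gene-gene structure outside the planted modules, informative censoring, and
the real composition of growth-factor pathway databases. Passing the
recovery and calibration suites shows the algorithms are implemented
correctly and behave as designed under their stated assumptions — not that
the biological findings of any particular cohort would replicate.

## Problem sizes used in validation

Clustering recovery runs at n = 600 (scaled `min_cluster_size=50`,
`min_samples=15`); model recovery at n = 500 with 150 candidate genes;
pathway contrasts at 30 vs 30 samples; GPScore recovery over cohorts of
three n = 300 datasets with a 200-gene universe and random-set sizes
50–150; Bliss recovery over 100 seeded grids. These sizes give stable,
seed-robust outcomes while keeping a full validation run within a few
minutes on one CPU.

## Known limitations

- The survival model fits fold-scale expression directly (matching its
  z = y₀ + Σ ω·exp definition); heavy-tailed genes can dominate the penalty
  path, and a log-transform variant may recover a few extra AUC points on
  log-linear data.
- GSEA's gene-set permutation null is anti-conservative relative to a
  phenotype-permutation null when genes are strongly co-expressed.
- The GPScore direction call uses the sign of observed-minus-expected
  events in the high-expression half; with very few events the call is
  unstable even when the log-rank p is small.
- `differential_pal` inherits the anti-conservative DE prefilter by design
  (see above); its q-values rank pathways rather than control a strict
  error rate under the global null.
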