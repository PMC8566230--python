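# nbgf — growth-factor signaling analysis for neuroblastoma transcriptomes

Neuroblastoma carries few recurrent mutations, so risk stratification and
therapy-escape analysis lean heavily on expression phenotypes — in
particular on growth-factor receptors and their downstream kinases. `nbgf`
is a Python library for that analysis style: it takes bulk expression
matrices plus clinical tables and provides, end to end,

- **subtype discovery** — UMAP (correlation metric) + HDBSCAN clustering of
  tumors on fold-from-mean growth-factor gene expression, cluster marker
  calling by Mann–Whitney tests with FDR, and marker-score assignment of
  cell lines to subtypes;
- **survival modeling** — a MYCN-stratified elastic-net logistic model,
  p(z) = 1/(1+e^(−z)), z = y₀ + Σᵢ ωᵢ·expᵢ, trained in two rounds
  (cross-validated fit on all candidates, then a refit on the top genes by
  |ω| with the keep fraction chosen by held-out F1) and read out as five
  survival-probability risk groups;
- **pathway activation levels** — PAL = Σ ARR·log2(CNR) / Σ|ARR| over a
  pathway's activator/repressor-annotated members, with case-to-normal
  ratios against a reference group and t-test/FDR contrasts between
  phenotypes (therapy response, metastasis);
- **pre-ranked GSEA** — correlation ranking against a target gene, the
  weighted Kolmogorov–Smirnov enrichment score, and a permutation
  null with NES, nominal p and sign-stratified FDR;
- **GPScore** — a gene-set prognostic statistic: each gene is classified
  favorable/unfavorable by median-split Kaplan–Meier/log-rank with
  Bonferroni correction, a set scores Nu/(Nu+Nf) over its significant
  members, calibrated against 20 random gene sets (3σ band) and tested
  across datasets; plus a sample-level mean-squared-expression set score
  with quartile risk groups;
- **dose-response analysis** — robust four-parameter-logistic IC50 fits,
  Bliss-independence synergy scoring of dose grids, and growth-factor
  protection statistics (Friedman test across cell-line panels);
- **synthetic cohorts** — generators with planted ground truth (expression
  subtypes, MYCN strata, prognostic genes/programs, pathway shifts,
  Bliss-consistent viability grids) so every stage is testable without any
  external download.

The package is used from Python; the `examples/` directory holds one short
narrative script per capability.

## Worked example

Train the two-round survival model on a synthetic 500-tumor cohort with 10
planted prognostic genes among 150 candidates, then score a fresh cohort
(`examples/02_survival_model.py`):

```text
amplified: 45 genes, alpha=0.001, l1=0.1
non_amplified: 15 genes, alpha=0.001, l1=0.1
planted prognostic genes recovered in panel: 10/10
held-out ROC AUC: 0.877, F1 at 0.5: 0.764
risk groups on the held-out cohort:
    >95% predicted survival: 121 patients
  85-95% predicted survival: 49 patients
  60-80% predicted survival: 56 patients
  40-60% predicted survival: 24 patients
    <40% predicted survival: 250 patients
```

All ten planted genes end up in the final panel, and the model's held-out
discrimination (AUC 0.877) approaches the information ceiling of the
generating process (the true predictor scores ≈ 0.95 on these cohorts).
The risk bins translate each predicted survival probability into the
conventional five-group stratification.

Other examples print, among else: a perfect adjusted Rand index for the
three planted expression subtypes (`01`), a planted pathway standing out at
PAL difference ≈ 1 log2 unit with q ≈ 10⁻²⁸ (`03`), a planted co-regulated
gene set scoring GPScore 1.0 against a random-set null of 0.5 ± 0.08
(`05`), and a planted Bliss excess of 10 recovered as 9.8 (`06`).

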