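# rbpflow

A tested, reusable pipeline for identifying candidate metastasis-suppressor
RNA-binding proteins (RBPs) and their stabilized target transcripts from
expression, RIP-seq, transcription-inhibition, cohort, and survival data.
A synthetic-data module generates every input with planted ground truth, so
the whole pipeline is exercisable (and is tested) without any external data.

## Modules

| Module | Purpose |
| --- | --- |
| `rbpflow.synthetic` | Seeded generators for all pipeline inputs: two-group expression matrices with planted down-regulated RBPs, copy-number tables, negative-binomial RIP-seq and stability counts, decay time courses, cohorts with planted correlations, survival tables, and an exact Venn membership fixture. |
| `rbpflow.screening` | Median centering, per-gene two-sample t-tests, percentile ranking of significantly down-regulated RBP genes, the three-rule high-priority union (all-three / top-5%-any-one / top-10%-any-two), and the >5% deletion filter. |
| `rbpflow.targets` | RPKM, RIP-seq bound calling (enrichment over input and IgG with an expression floor), peak region annotation against minimal gene models (0-based half-open; 3'UTR priority), steady-state down-regulation (fold > 1.1, BH q < 0.05), destabilization from the late-minus-early knockdown/control log-fold-change contrast, triple intersection with summary percentages, the secreted-gene filter, and the 3'UTR-length qPCR assay. |
| `rbpflow.decay` | Delta-delta-Ct quantification, endogenous-control normalization, exponential decay fitting (log-linear OLS primary, nonlinear least squares optional), half-life t1/2 = ln2/k, and condition comparison via a slope-difference test. |
| `rbpflow.coexpression` | log2-CPM transform, single- and two-gene composite high/low quantile groups, immune-factor differential expression (Welch + BH with a log2 fold-change gate), Pearson correlation, and heatmap-ready Z-score matrices. |
| `rbpflow.survival` | Kaplan-Meier product-limit estimation, the two-sample log-rank (Mantel-Cox) test, and best-cutoff stratification over a quantile grid with a mandatory grid-size Bonferroni adjustment alongside the raw minimum p. |

## Command-line interface

Generate a full synthetic input suite, then run each stage:

```sh
rbpflow simulate --out-dir sim/ --seed 1

rbpflow screen --datasets sim/expr_cancer_state.tsv,sim/expr_metastasis.tsv,sim/expr_stemness.tsv \
               --groups sim/groups_cancer_state.tsv,sim/groups_metastasis.tsv,sim/groups_stemness.tsv \
               --rbp-list sim/rbp_list.txt --cna sim/cna.tsv

rbpflow targets --rip sim/rip_counts.tsv --expr-kd kd.tsv --expr-ctrl ctrl.tsv \
                --stab stab.tsv --peaks sim/peaks.bed --gtf sim/models.gtf

rbpflow decay fit  --input sim/timecourse.tsv --method loglinear
rbpflow decay ddct --input ct.tsv --reference 18S --calibrator shCTRL_t0

rbpflow coexpress --counts sim/cohort_counts.tsv --genes IDX --quantile 0.30 \
                  --immune immune.txt

rbpflow survival --input sim/survival.tsv --mode best-cutoff
```

All formats are plain text: TSV matrices (genes in rows), two-column group
TSVs, one-id-per-line gene lists, BED6 peaks, and GTF gene models restricted
to gene/exon/CDS features.

## Notes on method choices

- The decay constant is primarily estimated as the OLS slope of
  ln(abundance) on time (the best-fit line on a semilog plot); a direct
  nonlinear exponential fit is available via `method="nls"`.
- Fold-change thresholds ("fold change down > 1.1") are interpreted on the
  linear scale with strict inequality; FDR control is Benjamini-Hochberg.
- Best-cutoff survival stratification scans expression quantiles
  0.10-0.90 (step 0.05) for the minimum log-rank p; because this scan is
  anti-conservative, a grid-size Bonferroni-adjusted p is always reported
  next to the raw minimum.
- Row Z scores use the population standard deviation (divisor n).
- Bound-calling thresholds (2-fold over input and IgG, input CPM >= 1) are
  explicit defaults exposed on the CLI.
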