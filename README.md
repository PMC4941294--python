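# lncarray

Microarray probe-set reannotation to long non-coding RNAs (lncRNAs) and
cross-dataset differential-expression signature analysis for case/control
expression studies, with a fully synthetic study generator for testing.

## The problem

Classic expression microarrays (e.g. Affymetrix HG-U133Plus 2.0) predate
modern lncRNA catalogues: many of their probe sets interrogate transcripts
that vendors annotated poorly or not at all. A large amount of archived
tumor/normal expression data can therefore be mined for lncRNA biology —
but only after the probe sets are *reannotated* against a current
transcript catalogue by sequence matching.

`lncarray` implements that workflow end to end:

1. **Reannotation.** Non-coding RefSeq transcripts (`NR_`/`XR_` accessions
   longer than 200 nt) are retained, every probe of every probe set is
   aligned to every transcript (exhaustive ungapped scan on both strands;
   optional Smith–Waterman for indels), and a probe set is assigned to a
   lncRNA when at least 90 % of its probes individually match at ≥ 90 %
   identity. The sequence-derived table can be merged with an external
   annotation table.
2. **Differential expression.** Each cohort is tested feature-wise with a
   Welch *t*-test or an empirical-Bayes variance-moderated *t*-test
   (posterior variance s̃²ᵍ = (d₀s₀² + dᵍs²ᵍ)/(d₀ + dᵍ), prior estimated by
   moments), with Benjamini–Hochberg adjustment. A lncRNA enters the
   signature only if it is significant (adjusted *P* < 0.01), with a
   consistent direction, in **every training and every validation cohort**.
3. **Characterization.** Hierarchical clustering (1 − Pearson, average
   linkage), chromosome/biotype tallies, intersection with external
   candidate lists, median-split survival analysis (Kaplan–Meier,
   log-rank, univariate Cox via Newton–Raphson on the Breslow partial
   likelihood), coexpression ranking, weighted-KS gene-set enrichment
   (GSEA-style ES with a sign-stratified permutation *p*), hypergeometric
   over-representation, and nearest-TSS distances.
4. **Synthetic studies.** `lncarray.synthdata` generates the whole input
   universe — transcript FASTA/BED/TSV, probe-tab files with planted
   per-probe identities, four GCT/CLS cohorts with planted differential
   lncRNAs, a survival cohort with a planted hazard, and GMT gene sets
   with planted enrichment — together with a ground-truth file, so every
   stage is testable without downloads.

## Worked example

```bash
lncarray run --config configs/synthetic.yaml --outdir out/ --seed 0
```

runs the full pipeline on a synthetic four-cohort study (two training
cohorts of 45 v 65 and 85 v 15 samples, two validation cohorts of 60 v 60
and 25 v 25) and prints:

```
completed stages: simulate, annotate, diffexpr, survival, downstream, tss
```

Key outputs in `out/`:

* `annotation.tsv` — probe set → lncRNA assignments with
  `probe_match_fraction` and `mean_identity`; `annotation_summary.json`
  reports 66 of 120 probe sets retained (the generator plants probe
  identities of 1.0/0.96/0.92/0.88/0.80 across sets, so exactly the
  ≥ 0.90 levels plus none of the decoys survive the 90 % rule).
* `signature.tsv` — the cross-cohort signature (40 lncRNAs under the
  bundled config, matching the 40 planted differential lncRNAs).
* `survival_report.tsv` — under seed 0:

  ```
  hr      ci_low  ci_high  cox_p    logrank_chi2  logrank_p  n_events
  2.659   1.924   3.675    3.2e-09  37.58         8.8e-10    166
  ```

  an elevated hazard for the high-expression group, consistent with the
  planted `surv_true_loghr = ln 2` (single-cohort estimates scatter
  around HR 2; the mean over replicates, reported by the acceptance
  script, is within a few percent of 2).
* `gsea_report.tsv`, `coexpression.tsv`, `go_enrichment.tsv`,
  `tss_distances.tsv` — enrichment and localization reports for the top
  up-regulated signature lncRNA.

Every subcommand (`simulate`, `annotate`, `de`, `survival`, `gsea`,
`coexpr`) is also usable standalone on user-supplied files in the standard
formats (FASTA, probe-tab TSV, GCT/CLS, GMT, BED, survival TSV); see
`lncarray <cmd> --help`.

Runs are deterministic: identical config and seed reproduce every output
file byte for byte, and `manifest.json` records SHA-256 hashes of all
inputs and outputs.

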