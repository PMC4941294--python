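# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `lncarray`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Probe-set reannotation

**Transcript filter.** A transcript is treated as a lncRNA iff its
accession prefix (the token before the first underscore+digit run) is
`NR` or `XR` *and* its length is strictly greater than 200 nt. The
inequality is strict by the standard lncRNA definition (transcripts
larger than 200 nt); a 200-nt transcript is excluded. Versioned
accessions (`NR_123.2`) are accepted and version-stripped for joins.
Records with unrecognizable accessions are skipped with a logged count,
not errors — vendor files routinely contain control rows.

**Probe alignment.** The default aligner is an exhaustive ungapped scan:
identity = (matching bases)/(probe length), maximized over every offset
on the transcript and on its reverse complement (probe orientation
relative to the transcript is not assumed). `N` never matches. Ties
prefer the forward strand, then the smallest offset. A Smith–Waterman
local aligner (match +1, mismatch −1, gap −2, linear) is available for
probes carrying indels; its identity is the maximum match count over all
optimal-score local alignments divided by probe length. We report the
maximum over ties rather than the match count of one arbitrary
traceback because tied optima can differ in match count, which would
make "identity" ill-defined; the reported offset still comes from a
deterministic traceback (diagonal > gap-in-transcript > gap-in-probe,
first maximal cell). One consequence of true local-alignment semantics
worth knowing: gapped identity is *not* always ≥ ungapped identity,
because the zero-clipping of Smith–Waterman can truncate a placement
whose prefix score reaches 0 (a probe with a mismatch right after its
first base loses that base from the local alignment). This only shaves
single bases in near-threshold corner cases; the default pipeline uses
the ungapped scan.

**Set-level rule.** A probe set is assigned to a transcript when at
least `set_fraction_min` (default 0.90) of its probes individually reach
`probe_identity_min` (default 0.90) — the `probe_fraction`
interpretation of the "≥ 90 % of a probe set" rule. The alternative
`base_fraction` mode instead requires the mean best identity over probes
(matched bases over total probe bases) to reach the threshold. The rule
is genuinely ambiguous as usually stated; `probe_fraction` is the
default because "sequences of a probe set" most naturally counts member
probe sequences and because 25-mer alignment identities are nearly
binary in practice. The probe-level identity threshold is our own
parameter (short-probe matching needs one); both thresholds are exposed.
Probe sets matching transcripts of more than one gene symbol are flagged
`ambiguous`, not dropped (`--drop-ambiguous` applies the stricter
convention).

**Seed-and-verify search.** The all-pairs scan is accelerated by a
pigeonhole argument: a placement with ≥ 90 % identity over a 25-mer has
at most 2 mismatches, so one of 3 contiguous probe chunks must occur
exactly at its implied offset. The search enumerates exact chunk
occurrences (`str.find`) and verifies the full window at each implied
offset; a pair with no qualifying placement is provably below threshold.
This is exact, not heuristic: `build_annotation_table(prefilter=True)`
equals the exhaustive `prefilter=False` path, and the test suite asserts
equality against an independently-written brute-force oracle on a
50 × 200 instance. `base_fraction` mode and gapped alignment always use
the exhaustive path (sub-threshold probes still contribute bases there).

**Merging.** The sequence-derived table can be unioned with an external
annotation (`probeset_id`, `accession`[, `gene_symbol`]). Pairs present
in both keep the primary's numeric fields with `source="both"`;
conflicting assignments are all retained with provenance; output order
is (probeset_id, accession).

## 2. Differential expression and the signature

**Tests.** Per feature, tumor vs normal on log2 values. `welch` is the
Welch t-test with Satterthwaite df; degenerate zero-variance features
resolve by the limit (equal means → p = 1, unequal → p = 0) instead of a
division error. `moderated` (default) is an empirical-Bayes
variance-moderated t: per-feature pooled variances s²ᵍ (df dᵍ = n₁+n₂−2)
are shrunk to s̃²ᵍ = (d₀s₀² + dᵍs²ᵍ)/(d₀+dᵍ) with the prior (d₀, s₀²)
estimated by moments of log s²ᵍ across features (digamma/trigamma
moment equations; trigamma inverted by Newton). The statistic is
referred to t with d₀+dᵍ df, capped at the summed residual df of all
features; d₀ → 0 recovers the ordinary pooled t and d₀ → ∞ the
common-variance t (prior variance then the arithmetic mean of s²ᵍ).
The moderated route mirrors what web front ends for archived microarray
series do; exact numerical parity with any particular service is not
claimed, but the test suite checks agreement with Bioconductor limma on
a shared fixture (rtol 1e-4 on t) and null type-I calibration at
α = 0.05 within [0.04, 0.06] over 50 simulations.

**Multiplicity.** Benjamini–Hochberg step-up within each cohort
(p_adj(i) = min over j ≥ i of m·p₍ⱼ₎/j, clipped at 1), implemented
in-house and tested to 1e-12 against a brute-force step-up and against
statsmodels.

**Signature scheme.** A feature enters the signature iff p_adj < α
(default 0.01, strict) in *every* training and *every* validation cohort
and its fold-change sign agrees across all cohorts. This is the
strictest reading of a training/validation design; `min_support` and
`require_direction=False` relax it. Features absent from any cohort are
excluded and counted. Ranking for top-k extraction uses the combined
evidence Σ log₁₀ p_adj (ascending) — a ranking criterion has to be
chosen, and the product of adjusted p-values is the natural symmetric
one; ties break by feature id. Multiple probe sets per lncRNA collapse
to the best-scoring one after the annotation join (`collapse=False`
keeps all).

**Clustering and tallies.** Agglomerative clustering uses
1 − Pearson distance and average linkage by default (the common defaults
of desktop clustering tools for expression heatmaps); both are
configurable, scipy supplies the linkage, and constant rows are rejected
by name under correlation distance. Chromosome and biotype tallies
partition the signature by direction with an `unlocated` bin so totals
are conserved.

## 3. Downstream characterization

**Survival.** Patients split at the median expression of the target
lncRNA (ties to the low group, so |high| ≤ |low|); the cutpoint is a
convention, not an optimized threshold. Kaplan–Meier is the standard
product-limit estimator. The log-rank test sums observed-minus-expected
events with the hypergeometric variance over distinct event times
(χ² with 1 df). The Cox model is univariate with the binary group
covariate, maximized by Newton–Raphson on the Breslow partial likelihood
(tolerance 1e-8, max 50 iterations, steps clipped at 5); the Wald 95 %
CI is exp(β ± 1.96·SE). Monotone likelihood (all events one side) caps
|β| at 15 and reports `converged=False`. Breslow tie handling is the
simplest correct choice; cross-checks against lifelines use tie-free
fixtures (lifelines defaults to Efron). Accuracy is verified by
parameter recovery: planted log HR ln 2, n = 200, ~20 % censoring, 200
replicates — mean β within 10 % and CI coverage in [0.90, 0.98].

**Rankings.** Coexpression ranks genes by Pearson r against the target
(constant rows get score 0 and a flag). The GSEA-style phenotype metric
is signal-to-noise (μ₁−μ₂)/(σ₁+σ₂) with σ floored at 0.2·|μ| (0.2 when
μ = 0), the classic convention. All orderings are made strict with a
gene-id tie-break.

**GSEA.** The enrichment score is the signed extremum of the weighted
Kolmogorov–Smirnov running sum: hits add |score|^p/Σ_hits|score|^p
(p = 1 by default; if every hit scores exactly 0 the step falls back to
uniform), misses subtract 1/(N−N_hits); the sum ends at 0 by
construction. The leading edge is the hits at or before (positive ES)
or at and after (negative ES) the extremum. The permutation null either
permutes phenotype labels and re-ranks (default) or draws random
equal-size gene sets from the ranked list. The p-value is
sign-stratified: p = (1 + #{|ES*| ≥ |ES|, same sign})/(1 + #{same-sign
ES*}). Dividing by all permutations instead would be anti-conservative
by up to 2× when permutation ES signs are balanced (the observed |ES|
is then compared against only half the draws but normalized by all of
them); the sign-stratified form is the classic convention and is
verified null-uniform by a KS check over 100 random sets.
NES = ES / mean(|same-sign ES*|). Across a collection of sets, p-values
are BH-adjusted; the full NES-pooling FDR of the original GSEA procedure
is out of scope.

**Set enrichment and TSS distances.** Over-representation of a query
list is the upper-tail hypergeometric p per set (sets intersected with
the universe; the query must be a subset of the universe), BH-adjusted —
a deliberately simple stand-in for web-service GO tooling. Nearest-TSS
distances are strand-aware (TSS = start on `+`, end−1 on `-`), signed
relative to the coding gene's strand (upstream negative), zero when the
lncRNA TSS falls inside a coding gene's interval, and flagged when the
chromosome has no coding TSS — a simple proxy for regulatory-domain
association tools, not a reimplementation of them.

**Utilities.** qPCR relative quantification 2^(−ΔΔCt) with
ΔΔCt = (Ct_target,case − Ct_ref,case) − (Ct_target,ctrl − Ct_ref,ctrl);
xenograft volume length × width² × 0.5 (mm³); group comparison is Welch
for two groups and classical one-way ANOVA for more.

## 4. The synthetic study generator

The generator emulates the statistical structure the analysis assumes,
at a scale that runs in seconds:

* **Transcriptome.** `n_coding` = 400 `NM_` transcripts and `n_lnc` =
  150 non-coding transcripts (alternating `NR_`/`XR_`), uniform-random
  A/C/G/T sequences, non-overlapping intervals on chr1–chr22/chrX,
  biotypes drawn from {antisense, lincRNA, processed_transcript,
  sense_intronic}. Exactly round(`short_fraction`·n_lnc) lncRNAs
  (default 10 %) are ≤ 200 nt to exercise the length filter. One
  designated marker lncRNA is fixed at 2616 nt, antisense, on chr1 —
  the profile of the survival marker in the emulated study design.
* **Probe sets.** 110 sets of 11 25-mers (the array design the workflow
  targets), each planted on one lncRNA with a per-set identity level
  cycling through {1.0, 0.96, 0.92, 0.88, 0.80}: each probe is a random
  window of the target carrying exactly round((1−identity)·25)
  base-changing substitutions, randomly sense or antisense. Ten decoy
  sets are unrelated random 25-mers. An `indel_fraction` option plants
  1-nt deletions to exercise the gapped aligner. Ground truth records
  every planted identity.
* **Expression.** Four cohorts sized (45 v 65), (85 v 15) — training —
  and (60 v 60), (25 v 25) — validation, matching the emulated design's
  cohort sizes. Log2 values are Normal(baseline_f, σ²) with baselines
  Uniform(4, 12) shared across cohorts and σ = 0.7 — i.i.d. Gaussian
  noise on the log scale, the simplest model matching the t-test
  assumptions. `n_de` = 40 planted lncRNAs (drawn from those with
  recoverable probe sets, half up / half down at |log2FC| = 1.5) receive
  their effect in tumor samples of all four cohorts; a config switch
  restricts effects to a cohort subset to test the intersection logic.
  The marker lncRNA is up-regulated and shares a per-sample latent
  factor with a 30-gene coding module at loading 0.8 (gene–marker
  correlation ≈ 0.64 within a class; across tumor+normal the marker's
  differential shift dilutes it, which is why module recovery is
  asserted by rank, not by absolute r).
* **Survival.** 200 patients; marker expression Normal(8, σ); the
  above-median group has hazard h₀·exp(β) with β = ln 2 (an effect size
  of the magnitude the emulated study reports) and h₀ = ln 2 / 30
  months⁻¹ (median survival ~30 months in the low group, a realistic
  figure for a mixed-stage lung adenocarcinoma cohort). Censoring is
  independent Uniform(0, u) with u solved numerically so the expected
  censored fraction equals `censor_rate` (default 0.2).
* **Gene sets.** 20 sets of 15–50 genes; 3 planted-enriched sets draw
  from the planted coexpression module (capped at module size) so their
  enrichment is genuinely present in the generated data; the rest sample
  coding genes uniformly. Enrichment status lives only in the truth
  file, not in set names.

Everything is driven by `numpy.random.default_rng` seeded per stage from
the single config seed; repeated runs are byte-identical, which the
suite asserts file-by-file.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: microarray hybridization physics,
background correction and normalization artifacts (matrices are born
log2-normalized), probe GC/affinity biases, correlated noise and batch
effects, heavy-tailed expression distributions, transcript splice
structure (transcripts are single intervals with uniform-random
sequence), realistic genomic clustering of lncRNAs, and non-proportional
hazards. Results on real archived series additionally depend on the
transcript catalogue and external annotation supplied by the user.

## 5. Problem sizes and numerics

Default/bundled sizes (400 coding + 150 lncRNA transcripts, 120 probe
sets, four cohorts totalling 380 samples, 200 permutations per gene set
in the orchestrated run) keep a full pipeline execution in the tens of
seconds and the complete test suite under two minutes; they are chosen
as the smallest scale at which every planted effect is comfortably
detectable by design (e.g. |log2FC|/SE ≈ 7 at the smallest cohort).
Statistical checks in the suite use the sizes stated alongside them
(e.g. 5000 features × 300 planted for signature recovery, 200 Cox
replicates, 1000 GSEA permutations).

Numerical conventions: alignment tie-breaks as above; BH implemented on
sorted arrays with a reverse cumulative minimum; Newton iterations stop
at |Δβ| < 1e-8; permutation p-values use the +1 "add the observation"
convention and are therefore never 0; p_adj clipping at 1e-300 before
log10 in the combined-evidence score; all file writers emit
deterministic float formatting (GCT at 6 significant digits).

## 6. Known limitations

* The ≥ 90 % set rule's original intent (probes-per-set vs aggregate
  bases vs per-probe BLAST coverage) is unknowable from its usual
  statement; both implemented modes are documented, neither claimed as
  authorial.
* The moderated test approximates, not reproduces, any specific online
  DE service; its guarantees here are calibration and limma agreement on
  the tested fixtures.
* Single-probe-level BLAST parity is not attempted; users preferring
  BLAST can feed its tabular output through the same set-level rule via
  the external-annotation pathway.
* Survival analysis is univariate by design; no clinical covariates,
  stratification, or time-varying effects.
* GSEA reports per-set permutation p with BH across sets, not the
  original NES-pooled FDR.
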