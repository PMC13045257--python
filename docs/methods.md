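# Methods

`tcdtyper` implements a pan-cancer style T-cell dysfunction (TCD)
analysis as a reusable library: per-sample enrichment profiling over
four TCD signature states, consensus subtyping, differential feature
selection, a multi-miRNA Cox risk model, and subtype classifiers,
together with a synthetic cohort generator that provides ground truth
for every stage. This note records the models, the defaults and why
they are what they are, and what the synthetic test bed does and does
not establish.

## The TCD profile

For each tumour sample, genes are called differentially expressed
(DEGs) by fold change against the averaged normal reference,

    FC_g = x_g / (mean over normals of x_g + pseudocount),

with a gene a DEG iff FC > 2 or FC < 0.5 (both strict). Each of the
four signature sets — exhaustion, senescence, exclusion, dysfunction —
is then tested for DEG over-representation with a hypergeometric test.
With N the universe size, M the DEG count, n the signature size inside
the universe and k the DEG count inside the signature, the profile
entry is the upper tail

    p = P(X >= k),  X ~ Hypergeom(N, M, n).

Choices worth stating:

* **Tail, not point mass.** The enrichment p-value is the upper tail;
  a point probability is not a test statistic.
* **Log-space evaluation.** The mass function is computed from
  log-binomial coefficients (`gammaln`) and summed with `logsumexp`.
  Severely dysfunctional samples produce p-values far below 1e-100;
  naive factorial ratios would overflow long before that.
* **Universe.** Genes present in the matrix whose normal mean plus
  pseudocount is positive. The pseudocount (default 0.01) guards
  against FPKM zeros in the denominator. Signature genes outside the
  universe are dropped from n, which keeps k <= n.
* **Normal reference scope.** A global normal pool by default; a
  per-group reference (e.g. per cancer type) is available through
  `normal_groups`.

## Consensus subtyping

The profile columns are clustered with partitioning around medoids
(PAM) under the Manhattan metric, with consensus over 100 subsampled
runs at item fraction 0.8, k = 2..8. consensus(i, j) is the fraction
of co-sampled resamples in which i and j co-clustered. Final per-k
labels come from PAM on 1 − consensus, keeping a single clustering
primitive. The number of subtypes is the smallest k whose successor's
relative delta-area of the consensus-CDF first drops below 0.1
(configurable); the delta-area at k = 2 is the area itself.

**Clustered view.** Clustering operates on −log10(p) by default. Raw
p-values saturate: two strongly enriched subtypes both sit at p ≈ 0
and become indistinguishable under any distance, while the log view
preserves the severity gradient. Raw mode remains available
(`transform="raw"`).

**PAM.** BUILD then best-improvement SWAP with a lowest-index tie
rule, so runs are deterministic. Single-swap local optima are real —
on a few percent of tiny random instances textbook BUILD+SWAP (and
the canonical R implementation) stops one plateau short of the global
optimum — so standalone `pam()` repeats SWAP from eight seeded random
initialisations and keeps the best solution; a 2000-instance sweep at
n <= 8 found no miss against exhaustive medoid search. Inside the
consensus loop the restarts are off by default: averaging over 100
subsampled runs is already the robustness mechanism there, and the
restart machinery would multiply the dominant cost of the procedure.

**Severity ordering.** Clusters are ranked by mean −log10(p) over the
four states; ascending rank gives T-low, T-middle, T-middle2, ...,
T-high. The extreme names are used for any k; for k = 4 this yields
the conventional four labels.

## Differential features

Two-group comparisons use Welch's unequal-variance t-test per feature:
on log2(x + 1) for expression (the effect is a log2 fold change), on
the raw beta scale for methylation (the effect is Δbeta, the absolute
difference of group mean betas). Empirical-Bayes variance moderation
is deliberately not used; Welch's test is self-contained and holds its
nominal level in the package's calibration tests, and the selection
thresholds transfer directly. DE miRNAs require |log2FC| > 1 and
p < 0.01; DMPs require Δbeta > 0.15 and Benjamini–Hochberg q < 0.05 —
all strict inequalities. Multi-group contrasts default to one-vs-rest
per subtype, with an extreme (T-high vs T-low) contrast available;
which contrast a given study means by "differential among subtypes"
is genuinely ambiguous, so both are exposed.

Degenerate rows where both groups are constant get p = 1 when the
means agree and a floor of 1e-300 when they differ (perfect
separation is more extreme than any resolvable p).

## Survival models

The Cox model h_i(t) = h_0(t) exp(x_i'β) is fit by Newton–Raphson on
the Breslow partial likelihood with step-halving; convergence when the
maximum score component falls below 1e-8 (or the Newton step falls
below 1e-10 — rounding puts a floor on the achievable score for large
cohorts), at most 50 iterations. Breslow tie handling was chosen over
Efron because it admits a transparent brute-force likelihood oracle;
with continuous synthetic event times the two coincide. Standard
errors come from the inverse observed information; per-covariate
p-values are Wald. The baseline hazard is never estimated: risk
ranking needs only the linear score f(X) = x'β.

Risk stratification splits at the median score; scores exactly at the
median go to the high-risk group. A split that leaves either group
empty (e.g. β = 0) is refused rather than silently broken. External
validation applies the frozen β to the new cohort, re-splits at the
external median, and compares the groups by Kaplan–Meier and log-rank.
KM estimation and the log-rank test delegate to lifelines.

The univariate screen fits one single-covariate Cox model per feature
and keeps Wald p < 0.05 (strict); failed fits are skipped with a
warning rather than aborting the screen.

## Classifiers

Random forests (500 trees, seeded) on small feature panels — the
three-miRNA T-high and T-low panels in the pipeline. Splits are
deterministic largest-remainder allocations, optionally stratified by
class; the pipeline uses 70/30 for the miRNA classifiers and exposes
60/20/20 for score-based classification. Evaluation is threshold-free:
AUC equals the tie-corrected Mann–Whitney probability, verified
against brute-force pair counting.

## The synthetic cohort generator

The generator emulates the statistical shape the analysis assumes,
with planted ground truth:

* **mRNA** — log2 expression Gaussian (mean 5, sd `noise_sd`),
  exponentiated to an FPKM-like scale; tumour samples add the
  subtype's severity effect (default 0 / 0.5 / 1.0 / 2.0 log2) to all
  signature genes. Signature sizes default to 26/25/292/90.
* **miRNA** — same family; six planted miRNAs move linearly with
  severity, three up and three down, to ±2 log2 units at the top.
* **methylation** — logit-normal betas; 25 planted probes lose 0.8
  logit units of mean per severity step (progressive hypomethylation).
* **survival** — exponential event times with log-hazard
  log(h0) + severity·logHR (default logHR 1.0); censoring times are
  uniform on (0, c) with c solved numerically so the expected censored
  fraction equals `censor_fraction` (default 0.3).

`noise_sd` defaults to 0.5. The value matters more than it looks:
because the normal reference is an *arithmetic* mean of log-normal
samples, its log2 is offset by sd²·ln2/2 above the log-scale mean.
At sd = 1 that offset is ~0.35, and a +0.5 log2 signature shift then
*loses* more down-regulated DEG calls than it gains up-regulated ones
— total signature DEG rates become non-monotone in severity and the
mildest subtypes invert. At sd = 0.5 the offset is ~0.09 and the
planted gradient is monotone, which is the behaviour the generator is
supposed to plant. This is a property of the fold-change rule against
an arithmetic-mean reference, not of the generator alone.

One seed sequence spawns independent child streams per modality, so
cohorts are exactly reproducible and partially regenerable.

**What passing tests show — and don't.** The generator plants clean,
homoscedastic, batch-free signals: no tissue composition, no
cancer-type structure, no correlated gene modules beyond the planted
ones, no informative censoring, no real miRNA-target biology.
Recovery results on this bed demonstrate that the implementation is
correct and calibrated (type-I error, coefficient recovery, ranking),
not that the thresholds would select the same features in TCGA-scale
data.

## Problem sizes

The test-suite and `scripts/acceptance.py` use cohorts of 50–150
samples per subtype, 2000 genes, 50 miRNAs and 500 probes; calibration
studies use 500 log-rank replicates, 50 Cox replicates at n = 1000,
and 2000-feature null DE matrices; the enumeration oracles cover every
hypergeometric parameter combination up to N = 12 and 200 random PAM
instances up to n = 8. These sizes resolve the tested properties to
their stated tolerances while keeping a full run in the minutes range.

## Known limitations

* GSVA-style kernel scores are not implemented; signature scores are
  the documented mean-z (default) and rank-z methods.
* No probe-to-gene genomic annotation; probe→gene links are inputs.
* No moderated DE statistics; no time-dependent covariates or
  proportional-hazards diagnostics; no baseline-hazard estimate.
* Infiltration estimates are consumed as a plain numeric table; no
  deconvolution is performed.
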