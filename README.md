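# tcdtyper

Quantifying **T-cell dysfunction (TCD)** from bulk tumour expression,
subtyping patients by its severity, and modelling the consequences —
for computational oncologists who want the full chain as tested,
scriptable Python rather than a one-off analysis.

The core object is the **TCD profile**: for every tumour sample,
genes are called differentially expressed against the averaged normal
reference (fold change FC > 2 or FC < 0.5), and each of four TCD
signature states — exhaustion, senescence, exclusion, dysfunction —
is scored with a hypergeometric enrichment test

$$p = \sum_{j \ge k} \frac{\binom{M}{j}\binom{N-M}{n-j}}{\binom{N}{n}}$$

where *N* is the gene universe, *M* the sample's DEG count, *n* the
signature size and *k* their overlap. Consensus clustering of the
profile (PAM, Manhattan distance, k = 2..8, delta-area k-selection)
yields severity-ordered subtypes T-low … T-high. Downstream, the
package selects differential miRNAs (|log2FC| > 1, p < 0.01) and
methylation probes (Δβ > 0.15, FDR < 0.05), screens features by
univariate Cox regression, fits a multivariate Cox model
$h_i(t) = h_0(t)\,e^{x_i'\beta}$ whose linear risk score
$f(X) = x'\hat\beta$ stratifies patients into high/low risk at the
median, and trains random-forest classifiers for the extreme subtypes
with ROC/AUC evaluation.

A synthetic cohort generator plants all of these signals with known
ground truth, so the entire pipeline is testable without any external
download.

## Worked example

```python
from tcdtyper import CohortConfig, generate_cohort
from tcdtyper.pipeline import PipelineConfig, run_pipeline

cohort = generate_cohort(CohortConfig(seed=7))          # 400 tumour + 25 normal
report = run_pipeline(PipelineConfig(seed=7, out_dir="tcd_run"), cohort)
for stage in report.stages:
    print(stage)
```

prints (abridged):

```
{'stage': 'profile', 'n_states': 4, 'n_samples': 400}
{'stage': 'subtype', 'chosen_k': 4, 'subtype_sizes': {'T-low': 111, 'T-middle2': 100, 'T-high': 100, 'T-middle': 89}}
{'stage': 'de_mirna', 'n_selected': 6, 'selected': ['miR-001', ..., 'miR-006'],
 'panels': {'T-high': ['miR-001', 'miR-002', 'miR-003'], 'T-low': ['miR-004', 'miR-005', 'miR-006']}}
{'stage': 'dmp', 'n_dmps': 25}
{'stage': 'cox', 'screened': ['miR-001', ..., 'miR-006'], ...}
{'stage': 'classify', 'test_auc': {'T-high': 0.970, 'T-low': 0.970}, 'fractions': [0.7, 0.3]}
{'stage': 'survival', 'logrank_p': 1.05e-47, 'statistic': 221.3, 'groups': [...]}
```

Reading it: the consensus delta-area rule picked **k = 4** subtypes,
matching the four planted severity groups (the ~11 samples shifted
between T-low and T-middle sit on the mildest effect boundary); all
**6 planted miRNAs** pass the DE filter and split into the expected
up-/down-regulated panels; all **25 planted probes** are recovered as
DMPs; the three-miRNA panels classify the extreme subtypes at test
**AUC ≈ 0.97**; and survival differs across subtypes at χ² = 221
(log-rank), as planted. Artifacts (profile, consensus matrices,
labels, DE/DMP tables, the Cox model JSON, risk groups, ROC points,
run report) land in `tcd_run/`.

The same flow runs from files via the CLI — `tcdtyper simulate` writes
a cohort as TSV/GMT inputs, `tcdtyper run --config cfg.yaml` executes
the pipeline on any conforming inputs.

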