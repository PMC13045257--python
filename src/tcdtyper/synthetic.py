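"""Synthetic tumour cohorts with planted T-cell-dysfunction structure.

The generator emulates the statistical shape of the inputs the pipeline
expects — FPKM-like mRNA expression with normal and tumour samples,
miRNA expression, methylation beta values, and overall-survival
clinical data — with known ground truth, so every downstream stage can
be tested for recovery of planted effects.

Model
-----
* mRNA: log2 expression is Gaussian (normal samples: mean
  ``base_log2_expr``, sd ``noise_sd``); tumour samples add the
  subtype's ``severity_effects`` shift on every signature gene; values
  are exponentiated to the FPKM-like scale.  Closed-form mean on the
  raw scale: ``2**(mu) * exp((sd*ln2)**2 / 2)``.
* miRNA: same log-normal family; a small panel of planted miRNAs
  shifts linearly with severity, half upward ("T-high" markers), half
  downward ("T-low" markers), reaching ``mirna_max_shift`` log2 units
  at the highest severity.
* methylation: beta values are logit-normal; planted probes lose
  ``beta_trend`` logit units of mean per severity step (progressive
  hypomethylation), the rest are null.
* survival: event times are exponential with log-hazard
  ``log(surv_base_hazard) + severity * surv_log_hr_per_severity``;
  independent uniform censoring is calibrated so the expected censored
  fraction equals ``censor_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._core import NORMAL, TUMOUR, ConfigError, ExpressionMatrix, GeneSetCollection

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "generate_survival"]

STATE_NAMES = ("exhaustion", "senescence", "exclusion", "dysfunction")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort; defaults define the reference
    study conditions used throughout the test-suite."""

    n_subtypes: int = 4
    samples_per_subtype: int | Sequence[int] = 100
    n_normal: int = 25
    n_genes: int = 2000
    signature_sizes: Sequence[int] = (26, 25, 292, 90)
    severity_effects: Sequence[float] = (0.0, 0.5, 1.0, 2.0)
    n_mirnas: int = 50
    n_planted_mirnas: int = 6
    mirna_max_shift: float = 2.0
    mirna_effects: Sequence[Sequence[float]] | None = None
    n_probes: int = 500
    n_dmp_probes: int = 25
    beta_trend: float = 0.8
    surv_base_hazard: float = 0.02
    surv_log_hr_per_severity: float = 1.0
    censor_fraction: float = 0.3
    noise_sd: float = 0.5
    base_log2_expr: float = 5.0
    mirna_base_log2: float = 4.0
    beta_base_logit: float = 0.85
    beta_logit_sd: float = 0.3
    seed: int = 0

    def group_sizes(self) -> list[int]:
        if isinstance(self.samples_per_subtype, int):
            return [self.samples_per_subtype] * self.n_subtypes
        return list(self.samples_per_subtype)

    def validate(self) -> None:
        if self.n_subtypes < 1:
            raise ConfigError("n_subtypes must be positive")
        sizes = self.group_sizes()
        if len(sizes) != self.n_subtypes or any(s < 1 for s in sizes):
            raise ConfigError("samples_per_subtype must give a positive count per subtype")
        for name in ("n_normal", "n_genes", "n_mirnas", "n_probes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if len(self.signature_sizes) != len(STATE_NAMES):
            raise ConfigError("signature_sizes must provide four counts")
        if any(s < 1 for s in self.signature_sizes):
            raise ConfigError("signature_sizes must be positive")
        if sum(self.signature_sizes) > self.n_genes:
            raise ConfigError("signature_sizes exceed n_genes")
        eff = list(self.severity_effects)
        if len(eff) != self.n_subtypes:
            raise ConfigError("severity_effects must give one value per subtype")
        if any(b < a for a, b in zip(eff, eff[1:])):
            raise ConfigError("severity_effects must be nondecreasing with severity")
        if not 0 <= self.n_planted_mirnas <= self.n_mirnas:
            raise ConfigError("n_planted_mirnas must be between 0 and n_mirnas")
        if not 0 <= self.n_dmp_probes <= self.n_probes:
            raise ConfigError("n_dmp_probes must be between 0 and n_probes")
        if self.mirna_effects is not None:
            m = np.asarray(self.mirna_effects, dtype=float)
            if m.shape != (self.n_planted_mirnas, self.n_subtypes):
                raise ConfigError(
                    "mirna_effects must be n_planted_mirnas x n_subtypes"
                )
        if self.surv_base_hazard <= 0:
            raise ConfigError("surv_base_hazard must be positive")
        if not 0 <= self.censor_fraction < 1:
            raise ConfigError("censor_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.beta_logit_sd <= 0:
            raise ConfigError("beta_logit_sd must be positive")

    def mirna_effect_matrix(self) -> np.ndarray:
        """Planted-miRNA x subtype matrix of log2 shifts.

        Default: the first half of the panel rises linearly to
        ``+mirna_max_shift`` at the top severity, the second half falls
        to ``-mirna_max_shift``.
        """
        if self.mirna_effects is not None:
            return np.asarray(self.mirna_effects, dtype=float)
        grad = (
            np.arange(self.n_subtypes) / max(1, self.n_subtypes - 1)
        ) * self.mirna_max_shift
        n_up = (self.n_planted_mirnas + 1) // 2
        rows = [grad if i < n_up else -grad for i in range(self.n_planted_mirnas)]
        return np.asarray(rows) if rows else np.empty((0, self.n_subtypes))


@dataclass
class CohortTruth:
    """Ground truth planted into a synthetic cohort."""

    subtype: pd.Series  # tumour sample -> severity index (0 = least severe)
    severity_effects: list[float]
    signature_genes: dict[str, list[str]]
    planted_mirnas: list[str]
    mirna_effects: np.ndarray
    planted_probes: list[str]
    beta_trend: float
    surv_log_hr_per_severity: float


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    mirna: ExpressionMatrix
    beta: ExpressionMatrix
    clinical: pd.DataFrame
    signatures: GeneSetCollection
    truth: CohortTruth
    config: CohortConfig


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_survival(
    severity_labels: Sequence[int],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with severity-dependent hazard and uniform censoring.

    Returns a frame with columns ``os_time`` (always > 0) and
    ``os_event`` (1 = death observed, 0 = censored).
    """
    if config.surv_base_hazard <= 0:
        raise ConfigError("surv_base_hazard must be positive")
    sev = np.asarray(severity_labels, dtype=float)
    if sev.size == 0:
        raise ConfigError("severity_labels must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = config.surv_base_hazard * np.exp(sev * config.surv_log_hr_per_severity)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_fraction == 0:
        time, event = t_event, np.ones(sev.size, dtype=int)
    else:
        # expected censored fraction with C ~ U(0, c): mean over samples
        # of (1 - exp(-lam*c)) / (lam*c); decreasing in c, so solve by root.
        def frac(c: float) -> float:
            x = lam * c
            return float(np.mean(-np.expm1(-x) / x)) - config.censor_fraction

        lo, hi = 1e-9, 1.0
        while frac(hi) > 0:
            hi *= 2.0
            if hi > 1e12:
                break
        c = brentq(frac, lo, hi)
        t_cens = rng.uniform(0.0, c, size=sev.size)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"os_time": time, "os_event": event})


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort (expression, miRNA, beta, clinical) with ground truth.

    Deterministic given ``config.seed``: one seed sequence spawns
    independent child streams for each data modality, so regenerating
    the cohort reproduces every matrix exactly.
    """
    config.validate()
    rng_expr, rng_mirna, rng_beta, rng_surv, rng_age = _child_rngs(config.seed, 5)

    sizes = config.group_sizes()
    n_tumour = sum(sizes)
    severity = np.repeat(np.arange(config.n_subtypes), sizes)
    tumour_ids = [f"T{i + 1:04d}" for i in range(n_tumour)]
    normal_ids = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    # Signature sets occupy the leading genes, disjoint by construction.
    sig_sets: dict[str, list[str]] = {}
    offset = 0
    for name, size in zip(STATE_NAMES, config.signature_sizes):
        sig_sets[name] = gene_ids[offset : offset + size]
        offset += size
    n_sig = offset

    # mRNA: log2-normal; tumour signature genes shifted by severity effect.
    log2_normal = rng_expr.normal(
        config.base_log2_expr, config.noise_sd, size=(config.n_genes, config.n_normal)
    )
    log2_tumour = rng_expr.normal(
        config.base_log2_expr, config.noise_sd, size=(config.n_genes, n_tumour)
    )
    effects = np.asarray(config.severity_effects)[severity]  # per tumour sample
    log2_tumour[:n_sig, :] += effects[None, :]
    expr_values = pd.DataFrame(
        np.exp2(np.concatenate([log2_tumour, log2_normal], axis=1)),
        index=gene_ids,
        columns=tumour_ids + normal_ids,
    )
    roles = {s: TUMOUR for s in tumour_ids} | {s: NORMAL for s in normal_ids}
    expression = ExpressionMatrix(expr_values, roles)

    # miRNA: tumour samples only; planted panel shifts with severity.
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    eff_mat = config.mirna_effect_matrix()  # planted x subtype
    log2_mirna = rng_mirna.normal(
        config.mirna_base_log2, config.noise_sd, size=(config.n_mirnas, n_tumour)
    )
    if eff_mat.size:
        log2_mirna[: eff_mat.shape[0], :] += eff_mat[:, severity]
    mirna = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_mirna), index=mirna_ids, columns=tumour_ids),
        {s: TUMOUR for s in tumour_ids},
    )

    # methylation: logit-normal betas; planted probes hypomethylate with severity.
    probe_ids = [f"cg{i + 1:05d}" for i in range(config.n_probes)]
    logit_mu = np.full((config.n_probes, n_tumour), config.beta_base_logit)
    logit_mu[: config.n_dmp_probes, :] -= config.beta_trend * severity[None, :]
    betas = expit(rng_beta.normal(logit_mu, config.beta_logit_sd))
    betas = np.clip(betas, 1e-12, 1 - 1e-12)
    beta = ExpressionMatrix(
        pd.DataFrame(betas, index=probe_ids, columns=tumour_ids),
        {s: TUMOUR for s in tumour_ids},
    )

    surv = generate_survival(severity, config, rng_surv)
    clinical = pd.DataFrame(
        {
            "sample_id": tumour_ids,
            "os_time": surv["os_time"].to_numpy(),
            "os_event": surv["os_event"].to_numpy(),
            "age": np.round(rng_age.normal(60, 10, size=n_tumour), 1),
            "group": [f"sev{g}" for g in severity],
        }
    )

    truth = CohortTruth(
        subtype=pd.Series(severity, index=tumour_ids, name="subtype"),
        severity_effects=list(config.severity_effects),
        signature_genes=sig_sets,
        planted_mirnas=mirna_ids[: eff_mat.shape[0]],
        mirna_effects=eff_mat,
        planted_probes=probe_ids[: config.n_dmp_probes],
        beta_trend=config.beta_trend,
        surv_log_hr_per_severity=config.surv_log_hr_per_severity,
    )
    return SyntheticCohort(
        expression=expression,
        mirna=mirna,
        beta=beta,
        clinical=clinical,
        signatures=GeneSetCollection(sig_sets),
        truth=truth,
        config=config,
    )
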