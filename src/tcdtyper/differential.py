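"""Differential miRNA expression and differential methylation.

Feature-wise two-group comparisons use Welch's unequal-variance t-test
— on log2(x + 1) for expression (so the effect estimate is a log2 fold
change) and on the raw beta scale for methylation (so the effect is
Δbeta, the absolute difference of group mean betas).  Multiple testing
is controlled with Benjamini–Hochberg throughout.

Selection rules are strict inequalities: DE miRNAs require
|log2FC| > 1 and p < 0.01; differentially methylated probes (DMPs)
require Δbeta > 0.15 and BH q < 0.05.  For a multi-group subtyping,
differential features are obtained one-vs-rest per subtype by default,
with an extreme-vs-extreme (T-high vs T-low) contrast available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._core import ExpressionMatrix, InputError

__all__ = [
    "DifferentialRecord",
    "two_group_de",
    "bh_adjust",
    "select_de_features",
    "find_dmps",
]

MIN_P = 1e-300


@dataclass
class DifferentialRecord:
    feature: str
    log2fc: float  # group A mean - group B mean on the tested scale
    delta: float  # |mean_A - mean_B| on the raw scale (Δbeta for betas)
    p: float
    q: float


def _records_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.log2fc, r.delta, r.p, r.q) for r in records],
        columns=["feature", "log2fc", "delta", "p", "q"],
    )


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return []
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with degenerate rows made explicit.

    Rows where both groups are constant get p = 1 when the means agree
    and the floor ``MIN_P`` when they differ (perfect separation).
    """
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate, np.where(same, 1.0, MIN_P), p)
    return np.clip(np.nan_to_num(p, nan=1.0), MIN_P, 1.0)


def _resolve_groups(
    X: ExpressionMatrix | pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    values = X.values if isinstance(X, ExpressionMatrix) else X
    ga, gb = list(map(str, group_a)), list(map(str, group_b))
    overlap = set(ga) & set(gb)
    if overlap:
        raise InputError(f"groups overlap: {sorted(overlap)[:5]}")
    missing = [s for s in ga + gb if s not in values.columns]
    if missing:
        raise InputError(f"unknown sample ids: {missing[:5]}")
    if len(ga) < 2 or len(gb) < 2:
        raise InputError("each group needs at least 2 samples")
    return values, ga, gb


def two_group_de(
    X: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    log_transform: bool = True,
) -> list[DifferentialRecord]:
    """Feature-wise Welch t-test of group A vs group B.

    With ``log_transform`` the test runs on log2(x + 1) and ``log2fc``
    is the difference of group means on that scale; otherwise both are
    computed on the raw values.
    """
    values, ga, gb = _resolve_groups(X, group_a, group_b)
    raw_a = values.loc[:, ga].to_numpy(dtype=float)
    raw_b = values.loc[:, gb].to_numpy(dtype=float)
    a, b = (np.log2(raw_a + 1), np.log2(raw_b + 1)) if log_transform else (raw_a, raw_b)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    delta = np.abs(raw_a.mean(axis=1) - raw_b.mean(axis=1))
    p = _welch(a, b)
    q = bh_adjust(p)
    return [
        DifferentialRecord(str(f), float(lfc[i]), float(delta[i]), float(p[i]), float(q[i]))
        for i, f in enumerate(values.index)
    ]


def select_de_features(
    records: Sequence[DifferentialRecord],
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.01,
) -> list[DifferentialRecord]:
    """Strict-threshold selection: |log2FC| > min_abs_log2fc and p < max_p."""
    return [r for r in records if abs(r.log2fc) > min_abs_log2fc and r.p < max_p]


def find_dmps(
    beta: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_delta: float = 0.15,
    max_q: float = 0.05,
) -> list[DifferentialRecord]:
    """Differentially methylated probes between two sample groups.

    Probes are tested on the raw beta scale; retained iff
    Δbeta > ``min_delta`` and BH q < ``max_q`` (strict).
    """
    values = beta.values if isinstance(beta, ExpressionMatrix) else beta
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise InputError("beta values must lie in [0, 1]")
    values, ga, gb = _resolve_groups(values, group_a, group_b)
    a = values.loc[:, ga].to_numpy(dtype=float)
    b = values.loc[:, gb].to_numpy(dtype=float)
    delta = np.abs(a.mean(axis=1) - b.mean(axis=1))
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = _welch(a, b)
    q = np.asarray(bh_adjust(p))
    keep = (delta > min_delta) & (q < max_q)
    return [
        DifferentialRecord(str(f), float(lfc[i]), float(delta[i]), float(p[i]), float(q[i]))
        for i, f in enumerate(values.index)
        if keep[i]
    ]


def records_table(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Tabular view of differential records (feature, log2fc, delta, p, q)."""
    return _records_frame(records)
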