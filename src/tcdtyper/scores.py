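"""Per-sample signature scoring and group-level summaries.

Signature scores condense a gene set into one number per sample.  Two
documented methods are provided:

* ``mean-z`` (default): each gene is z-scored across samples
  (population sd, ddof 0) and the score is the mean z over set
  members.  Invariant to affine rescaling of any single gene.
* ``rank-z``: expression is first replaced by within-sample ranks
  scaled to (0, 1], then z-scored per gene and averaged.  Invariant to
  any monotone transform of each sample column.

The module also hosts the group summaries (median infiltration, mean
checkpoint expression, proportions against a reference subtype),
Pearson co-expression, the anti-correlated miRNA-target screen, and a
generic hypergeometric over-representation test with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._core import ExpressionMatrix, GeneSetCollection, InputError
from .consensus import SubtypeAssignment
from .differential import bh_adjust
from .enrichment import HypergeomParams, hypergeom_tail

__all__ = [
    "SignatureScoreMatrix",
    "signature_score",
    "group_summary",
    "pearson_matrix",
    "anticorrelated_targets",
    "overrepresentation",
]


@dataclass
class SignatureScoreMatrix:
    scores: pd.DataFrame  # signature x sample
    method: str


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance features excluded from z-scoring"
        )
    z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=values.index[keep], columns=values.columns)


def signature_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    method: str = "mean-z",
) -> SignatureScoreMatrix:
    """Score each gene set in each sample; see module docstring for methods."""
    if method not in ("mean-z", "rank-z"):
        raise InputError(f"unknown scoring method {method!r}")
    values = expr.values
    if method == "rank-z":
        arr = values.to_numpy(dtype=float)
        ranks = np.apply_along_axis(rankdata, 0, arr) / arr.shape[0]  # in (0, 1]
        values = pd.DataFrame(ranks, index=values.index, columns=values.columns)
    z = _zscore_rows(values)
    rows = {}
    dead: list[str] = []
    for name in sets.names:
        members = [g for g in sets[name] if g in z.index]
        if not members:
            dead.append(name)
            continue
        rows[name] = z.loc[members].mean(axis=0)
    if dead:
        raise InputError(
            f"score undefined for sets with no scorable genes: {dead}"
        )
    return SignatureScoreMatrix(scores=pd.DataFrame(rows).T, method=method)


def group_summary(
    values: pd.DataFrame,
    labels: pd.Series,
    stat: str = "median",
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-group medians or means of a feature x sample table.

    With ``reference`` set, each entry is additionally divided by the
    reference group's value, giving proportions relative to that group
    (e.g. immune-infiltration levels relative to T-high).
    """
    if stat not in ("median", "mean"):
        raise InputError(f"unknown statistic {stat!r}")
    unlabelled = [str(s) for s in values.columns if s not in labels.index]
    if unlabelled:
        raise InputError(f"samples without group label: {unlabelled[:5]}")
    lab = labels.loc[values.columns]
    out = values.T.groupby(lab.to_numpy()).agg(stat).T
    if reference is not None:
        if reference not in out.columns:
            raise InputError(f"unknown reference group {reference!r}")
        out = out.div(out[reference], axis=0)
    return out


def pearson_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Feature x feature Pearson correlation; zero-variance rows give NaN."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise InputError("Pearson correlation needs at least 3 samples")
    if not np.isfinite(arr).all():
        raise InputError("correlation input must be finite")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance features; correlations set to NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=X.index, columns=X.index)


def anticorrelated_targets(
    mirna_row: pd.Series,
    gene_rows: pd.DataFrame,
    assignment: SubtypeAssignment,
    low_name: str = "T-low",
    high_name: str = "T-high",
) -> list[str]:
    """Candidate miRNA targets: negative Pearson r with the miRNA and
    higher mean expression in T-low than in T-high."""
    named = assignment.named
    low = [s for s in named.index[named == low_name] if s in gene_rows.columns]
    high = [s for s in named.index[named == high_name] if s in gene_rows.columns]
    if not low or not high:
        raise InputError(f"assignment must contain {low_name!r} and {high_name!r} samples")
    common = [s for s in gene_rows.columns if s in mirna_row.index]
    if len(common) < 3:
        raise InputError("need at least 3 shared samples")
    x = mirna_row.loc[common].to_numpy(dtype=float)
    G = gene_rows.loc[:, common].to_numpy(dtype=float)
    xc = x - x.mean()
    Gc = G - G.mean(axis=1, keepdims=True)
    denom = np.sqrt((Gc**2).sum(axis=1) * (xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gc @ xc) / denom
    higher_in_low = (
        gene_rows.loc[:, low].mean(axis=1) > gene_rows.loc[:, high].mean(axis=1)
    ).to_numpy()
    keep = (r < 0) & higher_in_low
    return [str(g) for g in gene_rows.index[keep]]


def overrepresentation(
    hits: list[str],
    universe: list[str],
    pathways: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each pathway.

    Returns one row per pathway with columns N, M, n, k, p, q (BH).
    """
    uni = set(universe)
    stray = sorted(set(hits) - uni)
    if stray:
        raise InputError(f"hits outside the universe: {stray[:5]}")
    hit_set = set(hits)
    rows = []
    for name in pathways.names:
        members = set(pathways[name]) & uni
        k = len(hit_set & members)
        p = hypergeom_tail(
            HypergeomParams(N=len(uni), M=len(hit_set), n=len(members), k=k)
        )
        rows.append((name, len(uni), len(hit_set), len(members), k, p))
    out = pd.DataFrame(rows, columns=["pathway", "N", "M", "n", "k", "p"])
    out["q"] = bh_adjust(out["p"].to_list())
    return out
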