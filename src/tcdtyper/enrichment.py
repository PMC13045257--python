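"""Per-sample T-cell-dysfunction (TCD) enrichment profiles.

For each tumour sample, genes are called differentially expressed (DEGs)
by fold change against the averaged normal reference (FC > 2 or
FC < 0.5, strict), and each of the four TCD state signatures
(exhaustion, senescence, exclusion, dysfunction) is tested for DEG
over-representation with a hypergeometric upper-tail test.  The
resulting state x sample matrix of p-values is the TCD profile, the
input to consensus subtyping.

The hypergeometric mass is computed in log space from log-binomial
coefficients, so it stays exact far into the tails (p ~ 1e-300), which
matters because strongly dysfunctional samples produce extreme
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from ._core import ExpressionMatrix, GeneSetCollection, InputError

__all__ = [
    "HypergeomParams",
    "TCDProfile",
    "mean_normal_expression",
    "call_degs",
    "hypergeom_pmf",
    "hypergeom_tail",
    "build_tcd_profile",
]

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of the enrichment test for one sample and one state.

    N: universe size; M: DEGs in the universe; n: signature genes in the
    universe; k: DEGs inside the signature.
    """

    N: int
    M: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise InputError(f"invalid hypergeometric params {self}")
        if self.k < 0:
            raise InputError(f"invalid hypergeometric params {self}")


@dataclass
class DEGSet:
    """Genes differentially expressed in one tumour sample, by direction."""

    sample_id: str
    up: list[str]
    down: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class TCDProfile:
    """State x sample matrix of enrichment p-values in [0, 1]."""

    pvalues: pd.DataFrame  # states in rows, tumour samples in columns

    def __post_init__(self) -> None:
        arr = self.pvalues.to_numpy()
        if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
            raise InputError("profile entries must be p-values in [0, 1]")

    @property
    def states(self) -> list[str]:
        return [str(i) for i in self.pvalues.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.pvalues.columns]

    def neglog10(self, cap: float = 320.0) -> pd.DataFrame:
        """-log10(p) view, capped to keep zero p-values finite."""
        with np.errstate(divide="ignore"):
            t = -np.log10(self.pvalues.to_numpy())
        return pd.DataFrame(
            np.minimum(t, cap), index=self.pvalues.index, columns=self.pvalues.columns
        )


def _log_binom(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    """log C(a, b); -inf outside 0 <= b <= a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


def hypergeom_pmf(p: HypergeomParams) -> float:
    """P(X = k) = C(M,k) C(N-M, n-k) / C(N,n), exactly zero when impossible."""
    if p.k > min(p.M, p.n) or p.n - p.k > p.N - p.M:
        return 0.0
    logp = (
        _log_binom(p.M, p.k)
        + _log_binom(p.N - p.M, p.n - p.k)
        - _log_binom(p.N, p.n)
    )
    return float(np.exp(logp))


def hypergeom_tail(p: HypergeomParams) -> float:
    """Upper tail P(X >= k); the enrichment p-value. Equals 1 when k = 0."""
    kmax = min(p.M, p.n)
    if p.k > kmax:
        return 0.0
    if p.k <= max(0, p.n - (p.N - p.M)):
        return 1.0
    js = np.arange(p.k, kmax + 1, dtype=float)
    logs = (
        _log_binom(p.M, js)
        + _log_binom(p.N - p.M, p.n - js)
        - _log_binom(p.N, p.n)
    )
    return float(min(1.0, np.exp(logsumexp(logs))))


def mean_normal_expression(
    expr: ExpressionMatrix, normal_ids: Sequence[str] | None = None
) -> pd.Series:
    """Arithmetic per-gene mean over the named normal samples."""
    ids = list(normal_ids) if normal_ids is not None else expr.normal_ids
    if not ids:
        raise InputError("no normal samples to average")
    missing = [s for s in ids if s not in expr.values.columns]
    if missing:
        raise InputError(f"normal ids absent from matrix: {missing[:5]}")
    return expr.values.loc[:, ids].mean(axis=1)


def call_degs(
    sample_col: pd.Series,
    normal_mean: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    up: float = 2.0,
    down: float = 0.5,
    sample_id: str = "",
) -> DEGSet:
    """Call per-sample DEGs by fold change vs the normal reference.

    FC = tumour / (normal mean + pseudocount); a gene is a DEG iff
    FC > ``up`` or FC < ``down`` — both strict, so FC exactly at a
    threshold is excluded.
    """
    if not sample_col.index.equals(normal_mean.index):
        raise InputError("sample and normal-mean vectors use different gene universes")
    fc = sample_col / (normal_mean + pseudocount)
    up_genes = [str(g) for g in fc.index[fc > up]]
    down_genes = [str(g) for g in fc.index[fc < down]]
    return DEGSet(sample_id=sample_id or str(sample_col.name), up=up_genes, down=down_genes)


def build_tcd_profile(
    expr: ExpressionMatrix,
    signatures: GeneSetCollection,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    up: float = 2.0,
    down: float = 0.5,
    normal_groups: dict[str, str] | None = None,
) -> TCDProfile:
    """Build the TCD profile over all tumour samples.

    For each tumour sample: N = genes in the shared universe (normal
    mean + pseudocount > 0), M = number of DEGs, and per state
    n = signature genes inside the universe, k = DEGs inside the
    signature; the profile entry is the hypergeometric upper tail.

    ``normal_groups`` optionally maps each sample id to a group label
    (e.g. cancer type); fold changes are then taken against the group's
    own normal mean instead of the global normal pool.
    """
    tumour_ids = expr.tumour_ids
    normal_ids = expr.normal_ids
    if not normal_ids:
        raise InputError("profile construction requires at least one normal sample")
    if not tumour_ids:
        raise InputError("profile construction requires at least one tumour sample")

    sig = {name: set(signatures[name]) for name in signatures.names}
    if all(len(s) == 0 for s in sig.values()):
        raise InputError("all signatures are empty")

    def group_of(s: str) -> str:
        return normal_groups.get(s, "__all__") if normal_groups else "__all__"

    normal_means: dict[str, pd.Series] = {}
    for g in {group_of(s) for s in tumour_ids}:
        ids = normal_ids if g == "__all__" else [s for s in normal_ids if group_of(s) == g]
        if not ids:
            raise InputError(f"no normal samples for group {g!r}")
        normal_means[g] = mean_normal_expression(expr, ids)

    # Per normal group: the gene universe and, per state, a boolean
    # membership vector over that universe (signature genes are dropped
    # from n when absent from the universe).
    group_env: dict[str, dict] = {}
    for g, ref in normal_means.items():
        universe = ref.index[(ref + pseudocount) > 0]
        uni_set = set(map(str, universe))
        masks = {}
        for name in signatures.names:
            members = sig[name] & uni_set
            if not members:
                warnings.warn(
                    f"signature {name!r} has no overlap with the gene universe; p set to 1"
                )
            masks[name] = np.fromiter(
                (str(gid) in members for gid in universe), dtype=bool, count=len(universe)
            )
        group_env[g] = {
            "universe": universe,
            "denom": (ref.loc[universe] + pseudocount).to_numpy(),
            "masks": masks,
        }

    rows: dict[str, dict[str, float]] = {name: {} for name in signatures.names}
    for s in tumour_ids:
        env = group_env[group_of(s)]
        universe = env["universe"]
        N = len(universe)
        fc = expr.values.loc[universe, s].to_numpy() / env["denom"]
        deg_mask = (fc > up) | (fc < down)
        M = int(deg_mask.sum())
        for name in signatures.names:
            smask = env["masks"][name]
            n = int(smask.sum())
            if n == 0:
                rows[name][s] = 1.0
                continue
            k = int((deg_mask & smask).sum())
            rows[name][s] = hypergeom_tail(HypergeomParams(N=N, M=M, n=n, k=k))

    mat = pd.DataFrame(rows).T.loc[signatures.names, tumour_ids]
    return TCDProfile(pvalues=mat)
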