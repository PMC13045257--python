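"""Independent oracles used across the test-suite.

Everything here is deliberately naive — exhaustive enumeration, brute
force, direct formula transcription — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def enum_hypergeom_pmf(N: int, M: int, n: int, k: int) -> float:
    """P(X = k) by exhaustive enumeration of all n-subsets of N items,
    of which the first M are 'marked'."""
    items = range(N)
    marked = set(range(M))
    total = 0
    hits = 0
    for sub in itertools.combinations(items, n):
        total += 1
        if len(marked.intersection(sub)) == k:
            hits += 1
    return float(Fraction(hits, total)) if total else 0.0


def enum_hypergeom_tail(N: int, M: int, n: int, k: int) -> float:
    items = range(N)
    marked = set(range(M))
    total = 0
    hits = 0
    for sub in itertools.combinations(items, n):
        total += 1
        if len(marked.intersection(sub)) >= k:
            hits += 1
    return float(Fraction(hits, total)) if total else 0.0


def exhaustive_pam_cost(D: np.ndarray, k: int) -> float:
    """Global minimum of the k-medoids objective by trying every medoid set."""
    n = D.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, list(medoids)].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def product_limit(times: np.ndarray, events: np.ndarray) -> dict[float, float]:
    """Kaplan-Meier by direct formula: S(t) = prod (1 - d_i/n_i)."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times, float)[order], np.asarray(events, int)[order]
    S = 1.0
    out: dict[float, float] = {}
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        S *= 1.0 - d / n_at_risk
        out[float(t)] = S
    return out


def bh_step_up(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q.tolist()


def auc_pair_count(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability over all positive x negative
    pairs, ties counted one half."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def breslow_loglik_direct(beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """One-covariate Breslow partial log-likelihood, written out directly."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        at_t = (times == t) & (events == 1)
        risk = times >= t
        ll += float(beta * x[at_t].sum()) - at_t.sum() * np.log(np.exp(beta * x[risk]).sum())
    return ll
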