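"""Survival analysis: Kaplan–Meier, log-rank, Cox risk models.

Clinical data travel as a plain DataFrame with ``os_time`` (> 0),
``os_event`` (1 = death observed, 0 = censored) and any covariate
columns; ``sample_id`` is carried when present.

The Cox proportional-hazards model h_i(t) = h_0(t) exp(x_i'β) is fit
by Newton–Raphson maximisation of the Breslow partial likelihood with
step-halving; the baseline hazard h_0 is never estimated because risk
ranking only needs the linear risk score f(X) = x'β.  Patients are
stratified into high/low risk at the median score (ties at the median
go to high risk), and a frozen model can be transferred to an external
cohort without refitting.

Kaplan–Meier estimation and the log-rank test delegate to lifelines,
repackaged into the toolkit's container types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._core import FitError, InputError

__all__ = [
    "KMCurve",
    "CoxRiskModel",
    "RiskStratification",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "risk_scores",
    "validate_model",
]

TIME_COL = "os_time"
EVENT_COL = "os_event"


def _check_frame(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise InputError("no survival records")
    for col in (TIME_COL, EVENT_COL):
        if col not in records.columns:
            raise InputError(f"survival table must contain {col!r}")
    if (records[TIME_COL] <= 0).any():
        raise InputError("survival times must be positive")
    ev = records[EVENT_COL]
    if not ev.isin([0, 1]).all():
        raise InputError("event flags must be 0 or 1")
    return records


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Samples censored exactly at an event time count as at risk at that
    time (the standard convention).
    """
    _check_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records[TIME_COL], records[EVENT_COL])
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    times = ev_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        at_risk=ev_rows["at_risk"].to_numpy(dtype=int),
        events=ev_rows["observed"].to_numpy(dtype=int),
        survival=surv,
    )


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int


def logrank_test(groups: Sequence[pd.DataFrame]) -> LogrankResult:
    """Multi-group log-rank test; chi-square with (g - 1) df."""
    if len(groups) < 2:
        raise InputError("log-rank test needs at least two groups")
    for g in groups:
        _check_frame(g)
    times = np.concatenate([g[TIME_COL].to_numpy(float) for g in groups])
    events = np.concatenate([g[EVENT_COL].to_numpy(float) for g in groups])
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        statistic=float(res.test_statistic), p=float(res.p_value), df=len(groups) - 1
    )


@dataclass
class CoxRiskModel:
    """Fitted Cox model: coefficients, HRs, SEs, Wald p-values."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    n: int
    n_events: int
    iterations: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hr": self.hazard_ratios,
                "se": self.se,
                "p": self.p,
            },
            index=self.covariates,
        )

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "p": self.p.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "iterations": self.iterations,
        }


def breslow_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood (used directly by grid oracles)."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_t = (time == t) & (event == 1)
        risk = time >= t
        ll += eta[at_t].sum() - at_t.sum() * np.log(np.exp(eta[risk]).sum())
    return float(ll)


def cox_fit(
    records: pd.DataFrame,
    covariate_names: Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxRiskModel:
    """Newton–Raphson fit of the Breslow partial likelihood.

    Converges when the maximum absolute score component drops below
    ``tol``; raises :class:`FitError` on non-convergence, a singular
    information matrix, or coefficients diverging toward complete
    separation.
    """
    _check_frame(records)
    names = list(covariate_names)
    missing = [c for c in names if c not in records.columns]
    if missing:
        raise InputError(f"missing covariates: {missing}")
    X = records[names].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("covariates must be finite")
    if (X.std(axis=0) == 0).any():
        const = [n for n, s in zip(names, X.std(axis=0)) if s == 0]
        raise InputError(f"constant covariates: {const}")
    time = records[TIME_COL].to_numpy(dtype=float)
    event = records[EVENT_COL].to_numpy(dtype=int)
    if event.sum() < 2:
        raise InputError("Cox fit needs at least 2 events")

    # sort by descending time so risk sets are prefixes
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    n, p = Xs.shape

    # centre covariates for numerical stability; beta is unaffected
    centre = Xs.mean(axis=0)
    Xc = Xs - centre

    uniq_times, first_idx = np.unique(-ts, return_index=True)

    def loglik_score_info(beta: np.ndarray):
        # shifting eta by its max cancels between the event term and
        # log S0, keeping ll invariant while avoiding overflow
        eta = Xc @ beta
        eta = eta - eta.max()
        w = np.exp(eta)
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * Xc, axis=0)
        cwxx = np.cumsum(w[:, None, None] * (Xc[:, :, None] * Xc[:, None, :]), axis=0)
        ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
        for i, t0 in enumerate(uniq_times):
            t = -t0
            start = first_idx[i]
            end = first_idx[i + 1] if i + 1 < len(first_idx) else n
            ev = es[start:end] == 1
            d = int(ev.sum())
            if d == 0:
                continue
            last = end - 1  # risk set = all with time >= t = prefix up to `last`
            S0 = cw[last]
            S1 = cwx[last]
            S2 = cwxx[last]
            xsum = Xc[start:end][ev].sum(axis=0)
            ll += eta[start:end][ev].sum() - d * np.log(S0)
            score += xsum - d * S1 / S0
            info += d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        return ll, score, info

    beta = np.zeros(p)
    ll, score, info = loglik_score_info(beta)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        # step halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = loglik_score_info(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > 50:
            raise FitError("coefficients diverging; possible complete separation")
        # accumulated rounding puts a floor on |score| for large n; a
        # vanishing Newton step means the optimum is resolved to precision
        if np.max(np.abs(factor * step)) < 1e-10:
            break
    else:
        raise FitError(f"no convergence in {max_iter} iterations (|score| = {np.max(np.abs(score)):.3g})")

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxRiskModel(
        covariates=names,
        beta=beta,
        se=se,
        p=pvals,
        loglik=float(ll),
        n=n,
        n_events=int(event.sum()),
        iterations=it,
    )


def univariate_screen(
    features: pd.DataFrame,
    records: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Keep features whose single-covariate Cox Wald p is < alpha (strict).

    ``features`` is feature x sample; sample order must match
    ``records`` rows (or records must carry a matching sample_id
    column indexing the feature columns).
    """
    _check_frame(records)
    if "sample_id" in records.columns:
        ids = records["sample_id"].astype(str).tolist()
        missing = [s for s in ids if s not in features.columns]
        if missing:
            raise InputError(f"features missing for samples: {missing[:5]}")
        feats = features.loc[:, ids]
    else:
        if features.shape[1] != len(records):
            raise InputError("features and records are not aligned")
        feats = features
    selected = []
    for feat in feats.index:
        df = records[[TIME_COL, EVENT_COL]].copy()
        df["_x"] = feats.loc[feat].to_numpy(dtype=float)
        try:
            model = cox_fit(df, ["_x"])
        except (FitError, InputError) as exc:
            warnings.warn(f"univariate Cox fit failed for {feat!r}: {exc}; skipped")
            continue
        if model.p[0] < alpha:
            selected.append(str(feat))
    return selected


@dataclass
class RiskStratification:
    scores: pd.Series  # sample -> f(X) = x'beta
    threshold: float
    group: pd.Series  # sample -> "high" | "low"

    @property
    def high_ids(self) -> list[str]:
        return [str(s) for s in self.group.index[self.group == "high"]]

    @property
    def low_ids(self) -> list[str]:
        return [str(s) for s in self.group.index[self.group == "low"]]


def risk_scores(
    model: CoxRiskModel,
    X: pd.DataFrame,
    threshold: float | None = None,
) -> RiskStratification:
    """Linear risk scores f(X) = x'β and median-split risk groups.

    ``X`` is sample x covariate.  Scores at or above the threshold
    (default: their median) are high risk.  A split that leaves either
    group empty is refused; pass an explicit ``threshold`` to override.
    """
    missing = [c for c in model.covariates if c not in X.columns]
    if missing:
        raise InputError(f"missing covariates: {missing}")
    scores = pd.Series(
        X[model.covariates].to_numpy(dtype=float) @ model.beta,
        index=X.index,
        name="risk_score",
    )
    thr = float(np.median(scores)) if threshold is None else float(threshold)
    group = pd.Series(np.where(scores >= thr, "high", "low"), index=X.index, name="risk")
    if (group == "high").all() or (group == "low").all():
        raise InputError(
            "degenerate risk split (all scores on one side of the threshold); "
            "supply an explicit threshold/tie policy"
        )
    return RiskStratification(scores=scores, threshold=thr, group=group)


@dataclass
class ValidationResult:
    stratification: RiskStratification
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogrankResult


def validate_model(
    model: CoxRiskModel,
    records: pd.DataFrame,
    X: pd.DataFrame,
) -> ValidationResult:
    """Transfer a frozen model to an external cohort.

    Applies the fitted β without refitting, median-splits the external
    scores, and compares high vs low risk with KM + log-rank.
    """
    _check_frame(records)
    if len(records) != len(X):
        raise InputError("records and covariate matrix are not aligned")
    strat = risk_scores(model, X)
    recs = records.set_index(X.index)
    high = recs.loc[strat.group == "high"]
    low = recs.loc[strat.group == "low"]
    return ValidationResult(
        stratification=strat,
        km_high=km_estimate(high),
        km_low=km_estimate(low),
        logrank=logrank_test([high, low]),
    )
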