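"""Binary subtype classifiers from small feature panels.

Random-forest classifiers (500 trees by default) predict membership of
a named subtype (T-high or T-low) from a handful of features — e.g.
the three-miRNA panels, or mean expression of invasion/EMT gene sets.
Evaluation is threshold-free: ROC curves and AUC, where AUC equals the
Mann–Whitney probability that a random positive outscores a random
negative (ties half-counted).

Sample splitting supports the two protocols used in the analysis:
train/test/validation at 60/20/20 and train/test at 70/30, optionally
stratified by class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from ._core import InputError

__all__ = [
    "SplitSpec",
    "split_samples",
    "train_subtype_classifier",
    "SubtypeClassifier",
    "roc_auc",
    "ClassifierEval",
]

DEFAULT_PARTITION_NAMES = ("train", "test", "validation")


@dataclass
class SplitSpec:
    """Disjoint sample partitions whose union is the full id list."""

    partitions: dict[str, list[str]]
    fractions: tuple[float, ...]
    stratified: bool
    seed: int

    def __getitem__(self, name: str) -> list[str]:
        return self.partitions[name]


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to fractions (sums to n)."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    rem = n - sum(base)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base


def split_samples(
    ids: Sequence[str],
    fractions: Sequence[float],
    labels: Mapping[str, int] | pd.Series | None = None,
    stratify: bool = False,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> SplitSpec:
    """Deterministically split ids into disjoint partitions.

    With ``stratify`` the class proportions are preserved within one
    sample per class; every class must then land in every partition.
    """
    fracs = tuple(float(f) for f in fractions)
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    if any(f <= 0 for f in fracs):
        raise InputError("fractions must be positive")
    ids = [str(s) for s in ids]
    if names is None:
        names = list(DEFAULT_PARTITION_NAMES[: len(fracs)])
        while len(names) < len(fracs):
            names.append(f"part{len(names) + 1}")
    rng = np.random.default_rng(seed)

    parts: dict[str, list[str]] = {nm: [] for nm in names}
    if stratify:
        if labels is None:
            raise InputError("stratified split needs labels")
        lab = pd.Series(labels).astype(int)
        strata = [[s for s in ids if lab[s] == c] for c in sorted(lab.loc[ids].unique())]
    else:
        strata = [ids]
    for stratum in strata:
        perm = [stratum[i] for i in rng.permutation(len(stratum))]
        sizes = _allocate(len(stratum), fracs)
        if stratify and any(sz == 0 for sz in sizes):
            raise InputError("a class would be absent from a partition under stratification")
        start = 0
        for nm, sz in zip(names, sizes):
            parts[nm].extend(perm[start : start + sz])
            start += sz
    for nm in parts:
        parts[nm].sort()
    return SplitSpec(partitions=parts, fractions=fracs, stratified=stratify, seed=seed)


@dataclass
class SubtypeClassifier:
    """A trained probabilistic classifier and its feature panel."""

    model: RandomForestClassifier
    feature_panel: list
    positive_label: int = 1

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        """Probability of the positive class; ``features`` is sample x feature."""
        missing = [f for f in self.feature_panel if f not in features.columns]
        if missing:
            raise InputError(f"missing features: {missing}")
        X = features[self.feature_panel].to_numpy(dtype=float)
        pos = list(self.model.classes_).index(self.positive_label)
        return pd.Series(self.model.predict_proba(X)[:, pos], index=features.index)


def train_subtype_classifier(
    features: pd.DataFrame,
    labels: pd.Series | Sequence[int],
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> SubtypeClassifier:
    """Train a random forest on sample x feature data with binary labels."""
    X = features.to_numpy(dtype=float)
    y = np.asarray(pd.Series(labels), dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("training labels contain a single class")
    if min(np.bincount(y)) < 2:
        raise InputError("each class needs at least 2 training samples")
    if not np.isfinite(X).all():
        raise InputError("features must be finite")
    params = {"n_estimators": 500, **(dict(hyperparams) if hyperparams else {})}
    model = RandomForestClassifier(random_state=seed, **params)
    model.fit(X, y)
    return SubtypeClassifier(model=model, feature_panel=list(features.columns))


@dataclass
class ClassifierEval:
    scores: pd.Series
    labels: pd.Series
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    partition: str = ""


def roc_auc(
    scores: pd.Series | Sequence[float],
    labels: pd.Series | Sequence[int],
    partition: str = "",
) -> ClassifierEval:
    """ROC curve and AUC; AUC is the tie-corrected Mann–Whitney probability."""
    s = pd.Series(scores, dtype=float)
    y = pd.Series(labels, dtype=int)
    if len(s) != len(y):
        raise InputError("scores and labels differ in length")
    classes = set(y.unique())
    if classes != {0, 1}:
        raise InputError("labels must contain both classes 0 and 1")
    auc = float(roc_auc_score(y.to_numpy(), s.to_numpy()))
    fpr, tpr, _ = roc_curve(y.to_numpy(), s.to_numpy())
    # guarantee the curve spans (0,0) .. (1,1)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.concatenate([fpr, [1.0]]), np.concatenate([tpr, [1.0]])
    return ClassifierEval(scores=s, labels=y, fpr=fpr, tpr=tpr, auc=auc, partition=partition)
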