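"""Shared containers and exceptions.

The whole toolkit passes data around as two light wrappers over pandas:
:class:`ExpressionMatrix` (feature x sample values plus an optional
normal/tumour role per sample) and :class:`GeneSetCollection` (named,
ordered gene sets).  The same matrix type carries mRNA FPKM, miRNA
expression, immune-infiltration estimates and methylation beta values;
beta matrices additionally satisfy the (0, 1) range restriction, checked
where it matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOUR = "tumour"


class TcdError(Exception):
    """Base class for toolkit errors."""


class InputError(TcdError):
    """Invalid data passed to an operation."""


class ConfigError(TcdError):
    """Invalid configuration value; the message names the field."""


class FitError(TcdError):
    """A model fit failed to converge or was singular."""


@dataclass
class ExpressionMatrix:
    """Nonnegative feature x sample matrix with per-sample roles.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    sample_role
        Optional mapping sample id -> ``"normal"`` or ``"tumour"``.
        Samples without a role are treated as tumour.
    """

    values: pd.DataFrame
    sample_role: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise InputError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise InputError("expression values must be finite")
        if (arr < 0).any():
            raise InputError("expression values must be nonnegative")
        unknown = set(self.sample_role) - set(map(str, cols))
        bad = {r for r in self.sample_role.values() if r not in (NORMAL, TUMOUR)}
        if bad:
            raise InputError(f"unknown sample roles: {sorted(bad)}")
        if unknown:
            raise InputError(f"roles for unknown samples: {sorted(unknown)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def normal_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_role.get(s) == NORMAL]

    @property
    def tumour_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_role.get(s, TUMOUR) == TUMOUR]

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise InputError(f"unknown sample ids: {missing[:5]}")
        role = {s: self.sample_role[s] for s in ids if s in self.sample_role}
        return ExpressionMatrix(self.values.loc[:, list(ids)].copy(), role)

    def require_unit_interval(self) -> None:
        """Assert all values lie in [0, 1] (methylation beta matrices)."""
        arr = self.values.to_numpy()
        if (arr < 0).any() or (arr > 1).any():
            raise InputError("beta values must lie in [0, 1]")


class GeneSetCollection(Mapping[str, list]):
    """Named, ordered gene sets; members unique within a set."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        self._sets: dict[str, list[str]] = {}
        for name, members in sets.items():
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(str(m))
            self._sets[str(name)] = list(seen)

    def __getitem__(self, key: str) -> list[str]:
        return self._sets[key]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Drop members absent from ``universe``, preserving order."""
        uni = set(universe)
        return GeneSetCollection(
            {n: [g for g in gs if g in uni] for n, gs in self._sets.items()}
        )

    def all_members(self) -> list[str]:
        """De-duplicated union over all sets, in first-seen order."""
        seen: dict[str, None] = {}
        for gs in self._sets.values():
            for g in gs:
                seen.setdefault(g)
        return list(seen)
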