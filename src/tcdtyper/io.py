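"""Reading and writing the pipeline's file formats.

Canonical tabular dialect is TSV (UTF-8, no quoting) with features in
rows and a header of sample ids; CSV is accepted on read.  Gene sets
use GMT (set name, description, tab-separated members).  Sample roles
(normal/tumour) come from a two-column sidecar table or a config
mapping.  Models and run reports are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import ExpressionMatrix, GeneSetCollection, InputError
from .synthetic import SyntheticCohort

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "write_cohort",
    "write_json",
]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    dialect: str | None = None,
    sample_role: dict[str, str] | None = None,
    role_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a feature x sample table; first column holds feature ids.

    Roles may come from ``sample_role`` directly or from ``role_path``,
    a two-column table (sample id, role).
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate feature ids {dups[:5]}")
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                # +2: one for the header line, one for 1-based numbering
                line = df.index.get_loc(bad.index[0]) + 2
                raise InputError(
                    f"{path}: non-numeric value {bad.iloc[0]!r} in column "
                    f"{col!r} (line {line})"
                )
        df = df.apply(pd.to_numeric)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    roles = dict(sample_role or {})
    if role_path is not None:
        rp = Path(role_path)
        rt = pd.read_csv(rp, sep=_sep_for(rp, dialect), header=None, comment="#")
        if rt.shape[1] < 2:
            raise InputError(f"{rp}: role table needs two columns")
        roles.update(dict(zip(rt[0].astype(str), rt[1].astype(str))))
    return ExpressionMatrix(df, roles)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            dedup = list(dict.fromkeys(members))
            if len(dedup) < len(members):
                warnings.warn(f"{path}: line {lineno} ({name}) has duplicate members")
            sets[name] = dedup
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets.names:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


CLINICAL_COLUMNS = ["sample_id", "os_time", "os_event", "age", "group"]


def read_clinical(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    missing = [c for c in ("sample_id", "os_time", "os_event") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: clinical table missing columns {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort as the standard pipeline input files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "roles": out / "sample_roles.tsv",
        "mirna": out / "mirna.tsv",
        "beta": out / "beta.tsv",
        "clinical": out / "clinical.tsv",
        "signatures": out / "signatures.gmt",
        "truth": out / "truth.tsv",
    }
    write_expression_table(cohort.expression, paths["expression"])
    pd.Series(
        {s: cohort.expression.sample_role.get(s, "tumour") for s in cohort.expression.sample_ids}
    ).to_csv(paths["roles"], sep="\t", header=False)
    write_expression_table(cohort.mirna, paths["mirna"])
    write_expression_table(cohort.beta, paths["beta"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gmt(cohort.signatures, paths["signatures"])
    cohort.truth.subtype.to_csv(paths["truth"], sep="\t", header=True)
    return paths


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
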