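"""Tabular I/O and cohort eligibility filtering.

Formats
-------
Expression matrix: UTF-8 TSV, first header cell ``gene_id`` followed by
sample ids; one gene per row; values are log2-scale normalized abundances.
The package performs no library-size normalization itself (quantification
is upstream); a ``log2(x+1)`` convenience transform is available behind an
explicit call. Missing values are rejected — the pipeline has no
imputation step.

Clinical table: TSV with mandatory columns ``sample_id``, ``time_months``
(months from surgery, > 0) and ``event`` (1 = radiologically confirmed
recurrence, 0 = censored). An optional ``treatment_flag`` column
(none/chemo/radio/unknown) and any further columns are carried along as
covariates.

Gene sets: standard GMT (name, description, genes...) or a two-column TSV
``gene<TAB>direction`` with direction up/down defining a single signed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

CLINICAL_REQUIRED = ("sample_id", "time_months", "event")

#: months below which a recurrence is attributed to residual disease and excluded
EARLY_RECURRENCE_MONTHS = 2.0
#: recurrences after this horizon are recoded as censored at the horizon
RECURRENCE_HORIZON_MONTHS = 60.0


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named signed gene set (``down_genes`` may be empty)."""

    name: str
    up_genes: tuple = ()
    down_genes: tuple = ()

    def __post_init__(self):
        up = tuple(dict.fromkeys(self.up_genes))
        down = tuple(dict.fromkeys(self.down_genes))
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        if not up and not down:
            raise FormatError(f"gene set {self.name!r} is empty")
        overlap = set(up) & set(down)
        if overlap:
            raise FormatError(
                f"gene set {self.name!r} lists genes in both directions: {sorted(overlap)}"
            )

    @property
    def genes(self) -> tuple:
        return self.up_genes + self.down_genes


def read_gene_sets(path, dialect: str = "gmt") -> list:
    """Parse gene sets from ``path`` under the named *dialect* (gmt | two_column)."""
    path = Path(path)
    if dialect == "gmt":
        sets = []
        seen = set()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                    )
                name, genes = parts[0], [g for g in parts[2:] if g]
                if name in seen:
                    raise FormatError(f"{path}: duplicate gene-set name {name!r}")
                seen.add(name)
                sets.append(GeneSet(name=name, up_genes=tuple(genes)))
        if not sets:
            logger.warning("gene-set file %s is empty", path)
        return sets
    if dialect == "two_column":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "direction"],
                         dtype=str, comment="#")
        if df.empty:
            logger.warning("gene-set file %s is empty", path)
            return []
        bad = ~df["direction"].isin(["up", "down"])
        if bad.any():
            raise FormatError(
                f"{path}: direction column must be up/down, got "
                f"{df.loc[bad, 'direction'].iloc[0]!r}"
            )
        return [GeneSet(
            name=path.stem,
            up_genes=tuple(df.loc[df["direction"] == "up", "gene"]),
            down_genes=tuple(df.loc[df["direction"] == "down", "gene"]),
        )]
    raise FormatError(f"unknown gene-set dialect {dialect!r}")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the genes x samples invariants: unique ids, numeric, finite."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r}")
    for col in expr.columns:
        if not pd.api.types.is_numeric_dtype(expr[col]):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = coerced.isna() & expr[col].notna()
            row = expr.index[bad.to_numpy().argmax()] if bad.any() else expr.index[0]
            raise FormatError(
                f"non-numeric value at gene {row!r}, sample {col!r}"
            )
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite value at gene {expr.index[r]!r}, sample {expr.columns[c]!r}"
        )
    out = expr.astype(float)
    out.index.name = "gene_id"
    return out


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV into a validated float DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr = validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id")


def log2_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Explicit ``log2(x + pseudocount)`` for inputs still on a linear scale."""
    if (expr.to_numpy() + pseudocount <= 0).any():
        raise FormatError("log2 transform needs x + pseudocount > 0 everywhere")
    return np.log2(expr + pseudocount)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical invariants; returns a copy indexed by sample_id."""
    df = clinical.copy()
    if df.index.name == "sample_id":
        df = df.reset_index()
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing mandatory column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["time_months"] = pd.to_numeric(df["time_months"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    bad_event = ~df["event"].isin([0, 1])
    if bad_event.any():
        row = df.loc[bad_event, "sample_id"].iloc[0]
        raise FormatError(f"event must be 0/1; offending sample {row!r}")
    df["event"] = df["event"].astype(int)
    bad_time = ~(df["time_months"] > 0) | ~np.isfinite(df["time_months"])
    if bad_time.any():
        row = df.loc[bad_time, "sample_id"].iloc[0]
        raise FormatError(f"time_months must be > 0; offending sample {row!r}")
    return df.set_index("sample_id")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_clinical(df)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    df = clinical.copy()
    if df.index.name == "sample_id":
        df = df.reset_index()
    df.to_csv(path, sep="\t", index=False)


def apply_cohort_filters(
    clinical: pd.DataFrame,
    exclude_treated_norecurrence: bool = False,
):
    """Apply the cohort eligibility rules; returns (filtered table, report).

    Rules, each logged per row in the report:

    * ``early_recurrence`` — recurrences under 2 months are attributed to
      residual disease at the resection margin and dropped;
    * ``late_recurrence_recode`` — recurrences beyond the 5-year horizon do
      not count as the recurrence phenotype; they are recoded as censored
      at 60 months;
    * ``treated_norecurrence`` — with the flag set, non-recurrence samples
      that received chemo/radiotherapy are dropped (their outcome may
      reflect treatment rather than tumor biology). Treated *recurrence*
      samples are kept, mirroring the cohort definition.

    Idempotent: re-filtering a filtered table is a no-op.
    """
    df = validate_clinical(clinical)
    records = []

    early = (df["event"] == 1) & (df["time_months"] < EARLY_RECURRENCE_MONTHS)
    for sid in df.index[early]:
        records.append({"sample_id": sid, "rule": "early_recurrence",
                        "action": "excluded"})
    df = df.loc[~early].copy()

    late = (df["event"] == 1) & (df["time_months"] > RECURRENCE_HORIZON_MONTHS)
    for sid in df.index[late]:
        records.append({"sample_id": sid, "rule": "late_recurrence_recode",
                        "action": "recoded_censored_at_60"})
    df.loc[late, "event"] = 0
    df.loc[late, "time_months"] = RECURRENCE_HORIZON_MONTHS

    if exclude_treated_norecurrence and "treatment_flag" in df.columns:
        treated = (df["event"] == 0) & df["treatment_flag"].isin(["chemo", "radio"])
        for sid in df.index[treated]:
            records.append({"sample_id": sid, "rule": "treated_norecurrence",
                            "action": "excluded"})
        df = df.loc[~treated].copy()

    report = pd.DataFrame(records, columns=["sample_id", "rule", "action"])
    return df, report
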