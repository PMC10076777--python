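"""Subgroup read-outs: fold changes, single-sample gene-set scores and
Wilcoxon rank-sum group comparisons.

Gene-set scores follow the common single-sample convention: mean z-score
over a set's up-genes minus mean z-score over its down-genes. The immune
read-out ships with a *partial* marker panel (only the marker genes the
literature names explicitly for these cell types); the full 43-marker /
14-cell-type panel and the chemotherapy (FOLFOX) resistance signatures are
consumed as user-supplied gene-set files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .io import GeneSet

logger = logging.getLogger(__name__)

#: Partial tumor-infiltrating immune cell marker panel (incomplete: only the
#: markers explicitly named for these cell types; supply a full panel as a
#: gene-set file for real analyses).
IMMUNE_MARKER_PANEL = (
    GeneSet("neutrophils", up_genes=("FCGR3A",)),
    GeneSet("macrophages", up_genes=("CD68",)),
    GeneSet("t_cells", up_genes=("CD3D", "CD3E")),
    GeneSet("exhausted_cd8", up_genes=("CD244", "LAG3")),
    GeneSet("dcs", up_genes=("HSD11B1",)),
    GeneSet("b_cells", up_genes=("CD19",)),
    GeneSet("cd8_t_cells", up_genes=("CD8A",)),
    GeneSet("cytotoxic_cells", up_genes=("GZMA", "GZMB", "KLRD1", "PRF1")),
)

_EXACT_MAX_N = 10  # exact permutation enumeration bound per group


@dataclass
class GroupComparison:
    name: str
    group_a: str
    group_b: str
    statistic: float  # rank sum of group A
    p_value: float
    method: str  # "exact" | "normal"

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def log2_mean_fold_change(expr, group_a, group_b, genes):
    """Per-gene difference of group means on the log2 matrix, plus their mean.

    Returns ``(per_gene, mean_delta)`` where ``per_gene`` is a Series of
    mean(log2 A) - mean(log2 B) over the stated gene list.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise DataError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise DataError("groups must be disjoint")
    genes = list(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"gene {missing[0]!r} not in expression matrix")
    sub = expr.loc[genes]
    delta = sub[group_a].mean(axis=1) - sub[group_b].mean(axis=1)
    return delta, float(delta.mean())


# ---------------------------------------------------------------------------
# gene-set scores
# ---------------------------------------------------------------------------

def geneset_score(expr_z, sets, min_coverage: float = 0.5):
    """Per-sample score per set: mean z over up-genes minus mean z over down-genes.

    Genes absent from the matrix are dropped; a set whose coverage falls
    below ``min_coverage`` is skipped with a warning. Returns
    ``(scores, coverage)``: samples x sets DataFrame and a per-set Series.
    """
    cols = {}
    coverage = {}
    for gs in sets:
        present_up = [g for g in gs.up_genes if g in expr_z.index]
        present_down = [g for g in gs.down_genes if g in expr_z.index]
        cov = (len(present_up) + len(present_down)) / len(gs.genes)
        if cov < min_coverage:
            logger.warning(
                "gene set %s skipped: coverage %.2f < %.2f", gs.name, cov, min_coverage
            )
            continue
        coverage[gs.name] = cov
        up = expr_z.loc[present_up].mean(axis=0) if present_up else 0.0
        down = expr_z.loc[present_down].mean(axis=0) if present_down else 0.0
        cols[gs.name] = up - down
    scores = pd.DataFrame(cols, index=expr_z.columns)
    scores.index.name = "sample_id"
    return scores, pd.Series(coverage, dtype=float)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _ranksum_p(a, b):
    """Two-sided rank-sum p-value.

    Exact permutation enumeration of the rank-sum statistic (midranks, so
    ties are handled exactly) when both groups have <= 10 values; otherwise
    the normal approximation with tie and continuity corrections. The
    two-sided exact p is ``min(1, 2*min(P(T<=t), P(T>=t)))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("empty group in rank-sum comparison")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    t_obs = ranks[: a.size].sum()
    n1, n2 = a.size, b.size
    n = n1 + n2
    if n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N:
        total = math.comb(n, n1)
        le = ge = 0
        eps = 1e-9
        for idx in combinations(range(n), n1):
            t = ranks[list(idx)].sum()
            if t <= t_obs + eps:
                le += 1
            if t >= t_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return float(t_obs), p, "exact"
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(t_obs), 1.0, "normal"
    z = (abs(t_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return float(t_obs), float(p), "normal"


def compare_groups_wilcoxon(values_by_group, reference_mode: str = "one_vs_rest",
                            reference: str | None = None, name: str = ""):
    """Two-sided rank-sum comparisons across named groups.

    ``one_vs_rest``: each group against the pooled remaining groups.
    ``pairwise_vs_reference``: each group against ``reference`` (default:
    first key).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if any(v.size == 0 for v in groups.values()):
        empty = [k for k, v in groups.items() if v.size == 0][0]
        raise DataError(f"group {empty!r} is empty")
    out = []
    keys = list(groups)
    if reference_mode == "one_vs_rest":
        if len(keys) < 2:
            raise DataError("one_vs_rest needs >= 2 groups")
        for k in keys:
            rest = np.concatenate([groups[j] for j in keys if j != k])
            t, p, method = _ranksum_p(groups[k], rest)
            out.append(GroupComparison(name, k, "rest", t, p, method))
    elif reference_mode == "pairwise_vs_reference":
        ref = reference if reference is not None else keys[0]
        if ref not in groups:
            raise DataError(f"reference group {ref!r} not present")
        for k in keys:
            if k == ref:
                continue
            t, p, method = _ranksum_p(groups[k], groups[ref])
            out.append(GroupComparison(name, k, ref, t, p, method))
    else:
        raise DataError(f"unknown reference_mode {reference_mode!r}")
    return out


# ---------------------------------------------------------------------------
# marker panel read-out
# ---------------------------------------------------------------------------

def marker_panel_readout(expr_z, panel, calls, min_coverage: float = 0.5,
                         reference_group: str = "low_risk"):
    """Score a marker panel per sample and compare scores across risk groups.

    ``calls`` is a risk-call table indexed by sample id with a ``label``
    column. Each cell-type score is compared across the risk groups in
    both conventions: one-vs-rest and pairwise against the low-risk
    reference. Comparisons involving an empty group are skipped with a
    warning. Returns ``(scores, comparisons)``.
    """
    if not panel:
        raise DataError("empty marker panel")
    labels = calls["label"]
    scores, coverage = geneset_score(expr_z, panel, min_coverage=min_coverage)
    scores = scores.loc[labels.index.intersection(scores.index)]
    scores.index.name = "sample_id"
    comparisons = []
    group_names = [g for g in ("low_risk", "high_risk_1", "high_risk_2")
                   if (labels == g).any()]
    skipped = [g for g in ("low_risk", "high_risk_1", "high_risk_2")
               if g not in group_names]
    if skipped:
        logger.warning("risk group(s) %s empty; comparisons skipped", skipped)
    for set_name in scores.columns:
        by_group = {g: scores.loc[labels[labels == g].index, set_name].to_numpy()
                    for g in group_names}
        if len(by_group) >= 2:
            comparisons += compare_groups_wilcoxon(
                by_group, "one_vs_rest", name=set_name)
            if reference_group in by_group:
                comparisons += compare_groups_wilcoxon(
                    by_group, "pairwise_vs_reference",
                    reference=reference_group, name=set_name)
    return scores, comparisons


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame(
        [{"name": c.name, "group_a": c.group_a, "group_b": c.group_b,
          "statistic": c.statistic, "p_value": c.p_value,
          "method": c.method, "stars": c.stars}
         for c in comparisons],
        columns=["name", "group_a", "group_b", "statistic", "p_value",
                 "method", "stars"],
    )
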