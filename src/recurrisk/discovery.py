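"""Subgroup discovery: partition recurrence tumors, prescreen genes by
univariate Cox, and stability-select signature genes by rank frequency
across repeated cross-validation.

The selection logic: in every fold-fit, all candidate genes are ranked by
ascending univariate Cox p-value on the training 9/10 of the working
cohort; a gene scores a hit when it ranks within ``top_k``; its frequency
is hits over all fold-fits, and genes with frequency >= ``freq_threshold``
are stability-selected. The screening p-threshold (``prescreen_alpha``,
no multiple-testing correction — the repeated-CV stage is the guard
against false positives) acts as a candidate filter on top of the full
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .exceptions import ConfigError, DataError, InsufficientEventsError
from .survival import cox_scan

_TIE_EPS = 0.0  # p-value ties are broken by |beta| (descending) then gene id


@dataclass
class DiscoveryConfig:
    """Training-stage knobs; defaults follow the published recipe
    (p < 0.01 screen, 200 rounds of 10-fold CV, top-150 rank, 80% frequency)."""

    prescreen_alpha: float = 0.01
    cv_rounds: int = 200
    cv_folds: int = 10
    top_k: int = 150
    freq_threshold: float = 0.80
    n_branches: int = 2
    n_variance_genes: int = 500
    counting: str = "per_fold_fit"  # or "per_round" (median rank within a round)
    prescreen_filter: bool = True
    seed: int = 0

    def validate(self):
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.cv_rounds < 1 or self.top_k < 1 or self.n_branches < 1:
            raise ConfigError("cv_rounds, top_k and n_branches must be >= 1")
        if not 0 < self.freq_threshold <= 1:
            raise ConfigError("freq_threshold must lie in (0, 1]")
        if self.counting not in ("per_fold_fit", "per_round"):
            raise ConfigError(f"unknown counting mode {self.counting!r}")
        return self


@dataclass
class BranchPartition:
    """Branch (1..n_branches) per recurrence sample plus cohesion diagnostics."""

    labels: pd.Series  # sample_id -> branch
    medoids: list
    silhouette: pd.Series  # per-branch mean silhouette width

    def samples_in(self, branch: int) -> list:
        return list(self.labels.index[self.labels == branch])


@dataclass
class StabilityResult:
    frequency: pd.Series  # per candidate gene, in [0, 1]
    selected_genes: list
    n_fold_fits: int


# ---------------------------------------------------------------------------
# 2-medoid partitioning of recurrence tumors
# ---------------------------------------------------------------------------

def _pam(dist: np.ndarray, k: int):
    """Deterministic PAM (BUILD + SWAP) on a precomputed distance matrix."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - dist[:, j], 0.0).sum() if j not in medoids else -1.0
            for j in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
    assign = np.argmin(dist[:, medoids], axis=1)
    return medoids, assign


def partition_recurrence(expr, clinical, config: DiscoveryConfig,
                         epithelial_markers=None) -> BranchPartition:
    """Cluster recurrence tumors into branches by 2-medoid partitioning on
    1 - Pearson correlation over the most variable genes (z-scored within
    the recurrence set).

    Branches are numbered canonically: ascending mean epithelial-marker
    z-score when a marker list is supplied (branch 1 = marker-low, the
    post-EMT state), else descending size.
    """
    cfg = config.validate()
    clinical = clinical.loc[clinical.index.intersection(expr.columns)]
    rec = list(clinical.index[clinical["event"] == 1])
    if len(rec) < 2 * cfg.n_branches:
        raise InsufficientEventsError(
            f"need >= {2 * cfg.n_branches} recurrence samples, got {len(rec)}"
        )
    sub = expr[rec]
    variances = sub.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[
        : min(cfg.n_variance_genes, (variances > 0).sum())]
    z = sub.loc[top]
    sd = z.std(axis=1, ddof=1)
    z = z.sub(z.mean(axis=1), axis=0).div(sd.replace(0.0, 1.0), axis=0)

    if cfg.n_branches == 1:
        labels = pd.Series(1, index=rec, name="branch")
        return BranchPartition(labels, [rec[0]], pd.Series({1: 0.0}))

    corr = np.corrcoef(z.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    medoid_idx, assign = _pam(dist, cfg.n_branches)

    # canonical branch order
    branch_ids = list(range(cfg.n_branches))
    if epithelial_markers:
        markers = [m for m in epithelial_markers if m in expr.index]
        if not markers:
            raise DataError("none of the epithelial markers are in the matrix")
        mz = expr.loc[markers, rec]
        msd = mz.std(axis=1, ddof=1)
        mz = mz.sub(mz.mean(axis=1), axis=0).div(msd.replace(0.0, 1.0), axis=0)
        means = [mz.to_numpy()[:, assign == b].mean() for b in branch_ids]
        order = list(np.argsort(means, kind="mergesort"))  # ascending: low first
    else:
        sizes = [-(assign == b).sum() for b in branch_ids]
        order = list(np.lexsort((medoid_idx, sizes)))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[a] for a in assign], index=rec, name="branch")

    try:
        sil = silhouette_samples(dist, labels.to_numpy(), metric="precomputed")
        sil_by_branch = pd.Series(sil, index=rec).groupby(labels).mean()
    except ValueError:  # singleton branch etc.
        sil_by_branch = pd.Series({b: float("nan") for b in relabel.values()})
    medoids = [rec[medoid_idx[old]] for old in order]
    return BranchPartition(labels, medoids, sil_by_branch)


# ---------------------------------------------------------------------------
# Cox prescreen
# ---------------------------------------------------------------------------

def prescreen_genes(expr, clinical, alpha: float) -> list:
    """Genes whose univariate Cox p-value is below ``alpha`` (raw, uncorrected).

    Zero-variance genes are skipped. Returns gene ids in matrix order.
    """
    clinical = clinical.loc[clinical.index.intersection(expr.columns)]
    if clinical["event"].sum() < 2:
        raise InsufficientEventsError("prescreen needs >= 2 events")
    res = cox_scan(expr[clinical.index].to_numpy().T,
                   clinical["time_months"].to_numpy(),
                   clinical["event"].to_numpy())
    p = res["p_value"]
    keep = res["valid"] & (p < alpha)
    return list(expr.index[keep])


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

def _stratified_folds(event, n_folds, rng):
    """Fold label per sample, stratified on event status."""
    folds = np.empty(event.size, dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def stability_select(expr, clinical, branch_samples, norecurrence_samples,
                     config: DiscoveryConfig) -> StabilityResult:
    """Rank-frequency stability selection on one branch's working cohort.

    Working cohort = the branch's recurrence samples plus the norecurrence
    samples. Folds are stratified on event status so every training fit
    retains events. Ranking covers every non-degenerate gene in the
    matrix; ties in p are broken by descending |beta| then gene id, so the
    result is invariant to gene order.
    """
    cfg = config.validate()
    branch_samples = list(branch_samples)
    norec = list(norecurrence_samples)
    if not branch_samples or not norec:
        raise DataError("branch and norecurrence sample sets must be non-empty")
    if set(branch_samples) & set(norec):
        raise DataError("branch and norecurrence sample sets must be disjoint")
    cohort = branch_samples + norec
    clin = clinical.loc[cohort]
    n_events = int(clin["event"].sum())
    if n_events * (cfg.cv_folds - 1) / cfg.cv_folds < 2:
        raise ConfigError(
            f"only {n_events} events across {cfg.cv_folds} folds leaves "
            "training fits with < 2 events on average; use fewer folds"
        )

    X = expr[cohort].to_numpy().T  # samples x genes
    time = clin["time_months"].to_numpy()
    event = clin["event"].to_numpy()
    genes = np.asarray(expr.index)
    G = genes.size
    alpha_order = np.argsort(np.argsort(genes, kind="mergesort"), kind="mergesort")

    rng = np.random.default_rng(cfg.seed)
    hits = np.zeros(G)
    n_fits = 0
    round_ranks = np.empty((cfg.cv_folds, G)) if cfg.counting == "per_round" else None
    round_hits = np.zeros(G)
    n_rounds_done = 0

    for _ in range(cfg.cv_rounds):
        folds = _stratified_folds(event, cfg.cv_folds, rng)
        for f in range(cfg.cv_folds):
            train = folds != f
            if event[train].sum() < 2:
                continue
            res = cox_scan(X[train], time[train], event[train])
            p = np.where(np.isfinite(res["p_value"]), res["p_value"], np.inf)
            absb = np.where(np.isfinite(res["beta"]), np.abs(res["beta"]), -np.inf)
            order = np.lexsort((alpha_order, -absb, p))
            ranks = np.empty(G, dtype=int)
            ranks[order] = np.arange(1, G + 1)
            hits += ranks <= cfg.top_k
            if round_ranks is not None:
                round_ranks[f] = ranks
            n_fits += 1
        if round_ranks is not None:
            round_hits += np.median(round_ranks, axis=0) <= cfg.top_k
            n_rounds_done += 1

    if cfg.counting == "per_round":
        freq = round_hits / max(n_rounds_done, 1)
    else:
        freq = hits / max(n_fits, 1)
    frequency = pd.Series(freq, index=expr.index, name="frequency")
    selected = list(expr.index[freq >= cfg.freq_threshold])
    return StabilityResult(frequency, selected, n_fits)


def config_to_dict(cfg: DiscoveryConfig) -> dict:
    return asdict(cfg)
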