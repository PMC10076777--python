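"""Nearest-centroid risk signatures and the combined three-way risk call.

Each signature holds a high-risk and a low-risk centroid (mean z-profiles
of the signature genes over the corresponding training samples) and a
decision cutoff. A sample's signature score is its correlation to the
high-risk centroid minus its correlation to the low-risk centroid; the
default similarity is the *uncentered* correlation (cosine over
z-scores), which retains the coherent up/down shift that carries most of
the signal when a signature's genes move together — centered Pearson is
available via ``metric="pearson"``. The two signatures combine by OR:
a sample is high-risk when either score exceeds its cutoff, and is
assigned to the subgroup with the larger cutoff-centered margin
(ties go to subgroup 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigError, CoverageError, DataError, FormatError
from .preprocessing import StandardizationParams, standardize
from .survival import logrank_test

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
MIN_GENE_COVERAGE = 0.95
RISK_LABELS = ("low_risk", "high_risk_1", "high_risk_2")

#: Published decision cutoffs, installed when a model file carries none.
DEFAULT_CUTOFFS = (-0.0850, -0.0005)


@dataclass
class CentroidSignature:
    name: str
    genes: list
    centroid_high: np.ndarray
    centroid_low: np.ndarray
    cutoff: float | None = None
    standardization: StandardizationParams | None = None
    metric: str = "uncentered"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genes = list(self.genes)
        self.centroid_high = np.asarray(self.centroid_high, dtype=float)
        self.centroid_low = np.asarray(self.centroid_low, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"signature {self.name!r} has duplicate genes")
        if (self.centroid_high.shape != (len(self.genes),)
                or self.centroid_low.shape != (len(self.genes),)):
            raise FormatError(
                f"signature {self.name!r}: centroid length does not match gene list"
            )
        if self.metric not in ("uncentered", "pearson"):
            raise ConfigError(f"unknown centroid metric {self.metric!r}")


def build_signature(expr_z, high_samples, low_samples, genes, name,
                    standardization=None, metric="uncentered") -> CentroidSignature:
    """Centroids = per-gene mean z over each sample set (cutoff left unset)."""
    high, low = list(high_samples), list(low_samples)
    if not high or not low:
        raise DataError("both sample sets must be non-empty")
    if set(high) == set(low):
        warnings.warn(f"signature {name!r}: identical high and low sample sets")
    genes = list(genes)
    missing = [g for g in genes if g not in expr_z.index]
    if missing:
        raise KeyError(f"gene {missing[0]!r} not in matrix")
    sub = expr_z.loc[genes]
    return CentroidSignature(
        name=name,
        genes=genes,
        centroid_high=sub[high].mean(axis=1).to_numpy(),
        centroid_low=sub[low].mean(axis=1).to_numpy(),
        standardization=standardization,
        metric=metric,
        meta={"n_high": len(high), "n_low": len(low)},
    )


def _similarity(Z, centroid, metric):
    """Column-wise similarity of (genes x samples) z-block to a centroid."""
    if metric == "pearson":
        Z = Z - Z.mean(axis=0)
        centroid = centroid - centroid.mean()
    num = Z.T @ centroid
    denom = np.linalg.norm(Z, axis=0) * np.linalg.norm(centroid)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, num / denom, 0.0)
    return sim


def score_samples(sig: CentroidSignature, expr, is_z: bool = False) -> pd.Series:
    """Signature score per sample: similarity(high) - similarity(low).

    ``expr`` is a genes x samples matrix on the raw log2 scale (z-scored
    here with the signature's frozen training parameters) or already
    z-scored when ``is_z``. At least 95% of the signature genes must be
    present; the tolerated few missing are dropped pairwise with a log
    entry.
    """
    present = [g for g in sig.genes if g in expr.index]
    coverage = len(present) / len(sig.genes)
    if coverage < MIN_GENE_COVERAGE:
        missing = [g for g in sig.genes if g not in expr.index]
        raise CoverageError(
            f"signature {sig.name!r}: only {coverage:.0%} of genes present; "
            f"missing {missing}", missing=missing)
    if len(present) < len(sig.genes):
        logger.info("signature %s: %d genes missing, dropped pairwise",
                    sig.name, len(sig.genes) - len(present))
    sub = expr.loc[present]
    if not is_z:
        if sig.standardization is None:
            raise ConfigError(
                f"signature {sig.name!r} has no standardization parameters; "
                "pass a z-scored matrix or attach parameters")
        z, _ = standardize(sub, sig.standardization)
    else:
        z = sub
    keep = [sig.genes.index(gene) for gene in present]
    sim_hi = _similarity(z.to_numpy(), sig.centroid_high[keep], sig.metric)
    sim_lo = _similarity(z.to_numpy(), sig.centroid_low[keep], sig.metric)
    return pd.Series(sim_hi - sim_lo, index=expr.columns, name=f"score_{sig.name}")


def optimize_cutoff(scores, clinical, min_group_frac: float = 0.10) -> float:
    """Cutoff maximizing the training log-rank chi-square.

    Candidate cutoffs are midpoints of adjacent sorted unique scores; each
    side of the split must hold at least ``min_group_frac`` of samples.
    Ties in chi-square break toward the more balanced split, then the
    smaller cutoff.
    """
    scores = pd.Series(scores)
    clin = clinical.loc[scores.index]
    if clin["event"].sum() < 2:
        raise DataError("cutoff optimization needs >= 2 events")
    time = clin["time_months"].to_numpy()
    event = clin["event"].to_numpy()
    s = scores.to_numpy()
    uniq = np.unique(s)
    if uniq.size < 2:
        raise DataError("all scores equal: no admissible cutpoint")
    grid = (uniq[:-1] + uniq[1:]) / 2.0
    n = s.size
    min_side = min_group_frac * n
    best = None  # (chi2, -imbalance, -cutoff)
    best_cut = None
    for c in grid:
        high = s > c
        n_hi = int(high.sum())
        if n_hi < min_side or (n - n_hi) < min_side:
            continue
        chi2 = logrank_test(time, event, high.astype(int)).chi_square
        key = (chi2, -abs(n_hi - (n - n_hi)), -c)
        if best is None or key > best:
            best, best_cut = key, float(c)
    if best_cut is None:
        raise DataError("no admissible cutpoint under the minimum-arm constraint")
    return best_cut


def classify(sig1: CentroidSignature, sig2: CentroidSignature, expr,
             is_z: bool = False) -> pd.DataFrame:
    """Combined three-way risk call per sample.

    Margin = score - cutoff per signature; high-risk when either margin is
    positive, subgroup by the larger margin (tie -> subgroup 1); combined
    score = max margin.
    """
    for sig in (sig1, sig2):
        if sig.cutoff is None:
            raise ConfigError(f"signature {sig.name!r} carries no cutoff")
    s1 = score_samples(sig1, expr, is_z=is_z)
    s2 = score_samples(sig2, expr, is_z=is_z)
    m1 = s1 - sig1.cutoff
    m2 = s2 - sig2.cutoff
    label = np.where(
        (m1 <= 0) & (m2 <= 0), RISK_LABELS[0],
        np.where(m1 >= m2, RISK_LABELS[1], RISK_LABELS[2]),
    )
    out = pd.DataFrame({
        "score1": s1, "score2": s2,
        "margin1": m1, "margin2": m2,
        "combined_score": np.maximum(m1, m2),
        "label": label,
    }, index=expr.columns)
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _sig_to_dict(sig: CentroidSignature) -> dict:
    return {
        "name": sig.name,
        "genes": list(sig.genes),
        "centroid_high": [float(v) for v in sig.centroid_high],
        "centroid_low": [float(v) for v in sig.centroid_low],
        "cutoff": None if sig.cutoff is None else float(sig.cutoff),
        "metric": sig.metric,
        "meta": sig.meta,
    }


def save_model(path, sig1: CentroidSignature, sig2: CentroidSignature,
               config: dict | None = None, seed: int | None = None) -> None:
    """Serialize both signatures plus shared standardization to JSON."""
    std = sig1.standardization or sig2.standardization
    doc = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config": config or {},
        "config_hash": config_hash(config or {}),
        "standardization": std.to_dict() if std is not None else None,
        "signatures": [_sig_to_dict(sig1), _sig_to_dict(sig2)],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path):
    """Restore ``(sig1, sig2, meta)``; validates integrity, warns on version skew."""
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupted model file {path}: {exc}") from exc
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"unsupported model schema {doc.get('schema_version')!r}")
    if doc.get("package_version") != __version__:
        warnings.warn(
            f"model saved with package version {doc.get('package_version')}, "
            f"loading with {__version__}")
    std = (StandardizationParams.from_dict(doc["standardization"])
           if doc.get("standardization") else None)
    sigs = []
    for i, sd in enumerate(doc["signatures"]):
        cutoff = sd.get("cutoff")
        if cutoff is None:
            cutoff = DEFAULT_CUTOFFS[min(i, 1)]
            warnings.warn(
                f"signature {sd['name']!r} carries no cutoff; installing the "
                f"documented default {cutoff}")
        sigs.append(CentroidSignature(
            name=sd["name"],
            genes=sd["genes"],
            centroid_high=sd["centroid_high"],
            centroid_low=sd["centroid_low"],
            cutoff=cutoff,
            standardization=std,
            metric=sd.get("metric", "uncentered"),
            meta=sd.get("meta", {}),
        ))
    if len(sigs) != 2:
        raise FormatError("model file must contain exactly two signatures")
    meta = {k: doc.get(k) for k in
            ("schema_version", "package_version", "seed", "config", "config_hash")}
    return sigs[0], sigs[1], meta
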