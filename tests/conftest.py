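"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each statistic from its definition (explicit
risk-set loops, likelihood grid search, pair enumeration) independently
of the package's vectorized implementations.
"""

import numpy as np
import pandas as pd
import pytest

from recurrisk.model import SubgroupRiskModel
from recurrisk.simulate import SyntheticConfig, simulate_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_logrank_chi2(time, event, group):
    """Hand-summed O-E / hypergeometric variance over event times."""
    time = list(map(float, time))
    o = e = v = 0.0
    for t in sorted({t for t, ev in zip(time, event) if ev == 1}):
        at = [i for i in range(len(time)) if time[i] >= t]
        d = sum(1 for i in at if time[i] == t and event[i] == 1)
        d1 = sum(1 for i in at if time[i] == t and event[i] == 1 and group[i] == 1)
        n = len(at)
        n1 = sum(1 for i in at if group[i] == 1)
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v if v > 0 else 0.0


def oracle_cox_loglik(beta, x, time, event):
    """Partial log-likelihood at scalar beta (tie-free data assumed)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.asarray(x)[risk])))
    return ll


def oracle_cox_beta_grid(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Grid-search maximizer of the partial likelihood (vectorized grid)."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(grid)
    for i in range(time.size):
        if event[i] == 1:
            risk = x[time >= time[i]]
            mat = np.exp(np.outer(risk, grid))
            ll += grid * x[i] - np.log(mat.sum(axis=0))
    return float(grid[np.argmax(ll)])


def oracle_auc(score, label):
    """Exhaustive positive-negative pair enumeration; ties count 1/2."""
    pos = [s for s, l in zip(score, label) if l == 1]
    neg = [s for s, l in zip(score, label) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_tiefree_cohort(rng, n_max=12):
    """Small random survival cohort with distinct times and both groups/events."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        time = rng.uniform(1, 100, size=n)
        if len(np.unique(time)) < n:
            continue
        event = (rng.random(n) < 0.7).astype(int)
        group = (rng.random(n) < 0.5).astype(int)
        if event.sum() >= 2 and 0 < group.sum() < n:
            return time, event, group


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with strong planted programs: every discovery stage is
    identifiable, so mechanics can be tested without borderline power."""
    cfg = SyntheticConfig(n_samples=160, n_genes=400, effect_size=2.5,
                          immune_depletion_high1=-1.5, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_model(strong_cohort):
    """Model fitted on the strong cohort with scaled-down cross-validation."""
    cohort = strong_cohort
    model = SubgroupRiskModel(
        cv_rounds=5, cv_folds=5, random_state=7,
        epithelial_markers=cohort.epithelial_marker_genes())
    model.fit(cohort.expression.T, cohort.clinical)
    return model


@pytest.fixture()
def toy_clinical():
    return pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "time_months": [2.0, 4.0, 6.0, 8.0],
        "event": [1, 1, 0, 1],
    })
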