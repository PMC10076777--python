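"""Survival statistics implemented from first principles.

The package's screening and evaluation layers all reduce to four
primitives, written here directly against their defining formulas so they
can be verified against brute-force oracles:

* product-limit (Kaplan-Meier) survival curves with Greenwood variance and
  log-log confidence intervals,
* the two-group log-rank test (hypergeometric variance summed over event
  times),
* univariate Cox proportional-hazards regression maximizing the Efron
  partial likelihood by safeguarded Newton iteration, vectorized across
  many covariates at once (the gene-screening workhorse),
* the concordance AUC (probability a random positive outscores a random
  negative; tied pairs count 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DataError,
    DegenerateCovariateError,
    InsufficientEventsError,
)

_BETA_CAP = 15.0  # |beta| bound on the unit-variance scale; hitting it flags monotone likelihood


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_time: float  # last observed time (event or censoring)
    _gw_cum: np.ndarray = None  # cumulative Greenwood sum, for log-log CIs


@dataclass
class SurvivalPoint:
    estimate: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    p_value: float
    converged: bool
    n: int
    n_events: int


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray  # events per group (group 0, group 1)
    expected: np.ndarray


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise DataError("time and event must be equal-length 1-d arrays")
    if time.size == 0:
        raise DataError("empty survival data")
    if not np.isfinite(time).all() or (time <= 0).any():
        raise DataError("all times must be finite and > 0")
    if not np.isin(event, [0, 1]).all():
        raise DataError("event indicators must be 0/1")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(time, event) -> KMCurve:
    """Product-limit estimator; ties at a time are one simultaneous event count."""
    time, event = _check_surv(time, event)
    n = time.size
    order = np.argsort(time, kind="mergesort")
    t_s, e_s = time[order], event[order]

    uniq, first = np.unique(t_s, return_index=True)
    counts = np.diff(np.append(first, n))
    d = np.array([e_s[f:f + c].sum() for f, c in zip(first, counts)])
    at_risk = n - first  # sorted ascending: everyone with time >= uniq[j]

    has_event = d > 0
    times_j = uniq[has_event]
    d_j = d[has_event]
    n_j = at_risk[has_event]

    frac = 1.0 - d_j / n_j
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore"):
        term = np.where(n_j > d_j, d_j / (n_j * (n_j - d_j)), np.inf)
    gw_cum = np.cumsum(term)
    with np.errstate(invalid="ignore"):
        greenwood_var = np.where(survival > 0, survival**2 * gw_cum, 0.0)

    return KMCurve(
        event_times=times_j,
        survival=survival,
        greenwood_var=greenwood_var,
        n_at_risk=n_j,
        n_events=d_j,
        max_time=float(t_s[-1]),
        _gw_cum=gw_cum,
    )


def survival_at(curve: KMCurve, t: float, ci_level: float = 0.95) -> SurvivalPoint:
    """Right-continuous step-function evaluation with a log-log Greenwood CI."""
    if t < 0:
        raise DataError("t must be >= 0")
    extrapolated = t > curve.max_time
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return SurvivalPoint(1.0, 1.0, 1.0, extrapolated)
    s = float(curve.survival[idx])
    if s <= 0.0:
        return SurvivalPoint(0.0, 0.0, 0.0, extrapolated)
    if s >= 1.0:
        return SurvivalPoint(1.0, 1.0, 1.0, extrapolated)
    gw = float(curve._gw_cum[idx])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se_cll = np.sqrt(gw) / abs(np.log(s))
    lo = s ** np.exp(z * se_cll)
    hi = s ** np.exp(-z * se_cll)
    return SurvivalPoint(s, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)),
                         extrapolated)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test; chi-square with 1 df.

    At each distinct event time with ``d`` events, ``n`` at risk and ``n1``
    at risk in group 1: E1 = d*n1/n and hypergeometric variance
    V = d*(n1/n)*(1-n1/n)*(n-d)/(n-1).
    """
    time, event = _check_surv(time, event)
    group = np.asarray(group).astype(int)
    if group.shape != time.shape or not np.isin(group, [0, 1]).all():
        raise DataError("group must be a 0/1 label per sample")
    if group.sum() == 0 or group.sum() == group.size:
        raise DataError("both groups must be non-empty")

    order = np.argsort(time, kind="mergesort")
    t_s, e_s, g_s = time[order], event[order], group[order]
    n = t_s.size

    uniq, first = np.unique(t_s, return_index=True)
    counts = np.diff(np.append(first, n))

    # suffix counts give at-risk totals at each distinct time
    at_risk_total = n - first
    g_rev = np.cumsum(g_s[::-1])[::-1]
    at_risk_g1 = g_rev[first]

    o1 = e1 = v = 0.0
    obs = np.zeros(2)
    exp = np.zeros(2)
    for f, c, n_j, n1_j in zip(first, counts, at_risk_total, at_risk_g1):
        d_j = e_s[f:f + c].sum()
        if d_j == 0:
            continue
        d1_j = (e_s[f:f + c] * g_s[f:f + c]).sum()
        p1 = n1_j / n_j
        e1_j = d_j * p1
        o1 += d1_j
        e1 += e1_j
        if n_j > 1:
            v += d_j * p1 * (1 - p1) * (n_j - d_j) / (n_j - 1)
        obs += (d_j - d1_j, d1_j)
        exp += (d_j - e1_j, e1_j)

    if v <= 0:
        chi2 = 0.0
    else:
        chi2 = (o1 - e1) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return LogRankResult(float(chi2), p, obs, exp)


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate, Efron ties)
# ---------------------------------------------------------------------------

def _risk_groups(time, event):
    """Sorted ascending; per event time: risk-set start index + event row indices."""
    order = np.argsort(time, kind="mergesort")
    t_s, e_s = time[order], event[order]
    n = t_s.size
    uniq, first = np.unique(t_s, return_index=True)
    counts = np.diff(np.append(first, n))
    groups = []
    for f, c in zip(first, counts):
        ev = f + np.flatnonzero(e_s[f:f + c] == 1)
        if ev.size:
            groups.append((f, ev))
    return order, groups


def cox_scan(X, time, event, max_iter: int = 60, tol: float = 1e-9) -> dict:
    """Univariate Cox fits for every column of ``X`` simultaneously.

    Maximizes the Efron-corrected partial likelihood per column by Newton
    iteration with step clipping (the univariate partial log-likelihood is
    concave, so clipped Newton from 0 is globally convergent). Columns are
    scaled to unit variance internally; estimates are returned on the
    original scale. A column walking to the |beta| cap (monotone
    likelihood) is clamped there and flagged not converged; constant
    columns come back invalid (NaN).

    Returns arrays ``beta, se, p_value, converged, valid`` of length G.
    """
    time, event = _check_surv(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, G = X.shape
    if n != time.size:
        raise DataError("X rows must match survival data length")
    if event.sum() < 1:
        raise InsufficientEventsError("no events: partial likelihood is flat")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    valid = sd > 0
    Xc = np.zeros_like(X)
    Xc[:, valid] = (X[:, valid] - mu[valid]) / sd[valid]

    order, groups = _risk_groups(time, event)
    Xs = Xc[order]
    Xs2 = Xs * Xs

    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    info = np.full(G, np.nan)
    active = valid.copy()

    for _ in range(max_iter):
        if not active.any():
            break
        eta = Xs * beta  # (n, G); |eta| bounded by cap * max|z|, safe for exp
        theta = np.exp(eta)
        xt = Xs * theta
        x2t = Xs2 * theta
        # suffix sums over the risk sets
        S = np.cumsum(theta[::-1], axis=0)[::-1]
        Sx = np.cumsum(xt[::-1], axis=0)[::-1]
        Sxx = np.cumsum(x2t[::-1], axis=0)[::-1]

        U = np.zeros(G)
        I = np.zeros(G)
        for start, ev in groups:
            d = ev.size
            U += Xs[ev].sum(axis=0)
            S_j, Sx_j, Sxx_j = S[start], Sx[start], Sxx[start]
            if d == 1:
                denom = S_j
                r = Sx_j / denom
                U -= r
                I += Sxx_j / denom - r * r
            else:
                SD = theta[ev].sum(axis=0)
                SxD = xt[ev].sum(axis=0)
                SxxD = x2t[ev].sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = S_j - f * SD
                    r = (Sx_j - f * SxD) / denom
                    U -= r
                    I += (Sxx_j - f * SxxD) / denom - r * r

        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I > 0, U / I, np.sign(U))
        step = np.clip(step, -1.0, 1.0)
        step = np.where(active, step, 0.0)
        beta = np.clip(beta + step, -_BETA_CAP, _BETA_CAP)
        info = np.where(active, I, info)

        newly_done = active & (np.abs(step) < tol)
        converged |= newly_done
        active &= ~newly_done
        capped = active & (np.abs(beta) >= _BETA_CAP)
        active &= ~capped  # stays converged=False

    converged &= np.abs(beta) < _BETA_CAP

    with np.errstate(divide="ignore", invalid="ignore"):
        se_std = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
        z = np.abs(beta) / se_std
    p = 2.0 * stats.norm.sf(z)

    beta_out = np.full(G, np.nan)
    se_out = np.full(G, np.nan)
    p_out = np.full(G, np.nan)
    beta_out[valid] = beta[valid] / sd[valid]
    se_out[valid] = se_std[valid] / sd[valid]
    p_out[valid] = p[valid]
    converged[~valid] = False
    return {
        "beta": beta_out,
        "se": se_out,
        "p_value": p_out,
        "converged": converged,
        "valid": valid,
    }


def fit_cox_univariate(x, time, event) -> CoxResult:
    """Single-covariate Cox PH fit; Wald p-value on the coefficient."""
    time, event = _check_surv(time, event)
    x = np.asarray(x, dtype=float)
    if x.shape != time.shape:
        raise DataError("covariate length must match survival data")
    if event.sum() < 2:
        raise InsufficientEventsError(
            f"need >= 2 events, got {int(event.sum())}"
        )
    if np.ptp(x) == 0:
        raise DegenerateCovariateError("covariate is constant")
    res = cox_scan(x[:, None], time, event)
    beta = float(res["beta"][0])
    return CoxResult(
        beta=beta,
        hr=float(np.exp(beta)),
        se=float(res["se"][0]),
        p_value=float(res["p_value"][0]),
        converged=bool(res["converged"][0]),
        n=int(time.size),
        n_events=int(event.sum()),
    )


def fit_cox_group(time, event, group) -> CoxResult:
    """Cox PH hazard ratio of group 1 (high-risk) vs group 0."""
    group = np.asarray(group).astype(float)
    if len(np.unique(group)) != 2:
        raise DataError("need exactly two non-empty groups")
    return fit_cox_univariate(group, time, event)


# ---------------------------------------------------------------------------
# concordance AUC
# ---------------------------------------------------------------------------

def concordance_auc(score, label) -> float:
    """P(random positive outscores random negative); ties count 1/2."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(int)
    if score.shape != label.shape or score.ndim != 1:
        raise DataError("score and label must be equal-length 1-d arrays")
    if not np.isin(label, [0, 1]).all():
        raise DataError("labels must be 0/1")
    n1 = label.sum()
    n0 = label.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("both label classes must be present")
    ranks = stats.rankdata(score)
    return float((ranks[label == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
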