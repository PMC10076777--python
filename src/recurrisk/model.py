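"""The end-to-end prognostic estimator.

``SubgroupRiskModel`` is an sklearn-style estimator wrapping the full
training workflow: freeze per-gene standardization on the training
cohort, partition recurrence tumors into two branches, screen genes by
univariate Cox within each branch's working cohort, stability-select
signature genes by rank frequency over repeated cross-validation, build
one nearest-centroid signature per branch and optimize its cutoff on the
training log-rank statistic. Prediction produces the combined three-way
risk call (low_risk / high_risk_1 / high_risk_2) and a continuous
combined risk score (the larger cutoff-centered margin).

``X`` is samples x genes (DataFrame preferred; gene names are taken from
the columns). ``y`` is right-censored survival data: a DataFrame with
``time_months`` and ``event`` columns, a structured array with
``time``/``event`` fields, or a ``(time, event)`` pair of arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .centroid import (
    CentroidSignature,
    build_signature,
    classify,
    optimize_cutoff,
    score_samples,
)
from .discovery import (
    DiscoveryConfig,
    partition_recurrence,
    prescreen_genes,
    stability_select,
)
from .exceptions import ConfigError, DataError, InsufficientSignalError
from .preprocessing import standardize
from .survival import concordance_auc, fit_cox_group, logrank_test

RISK_LABELS = ("low_risk", "high_risk_1", "high_risk_2")


def as_clinical(y, sample_ids) -> pd.DataFrame:
    """Coerce survival labels into the package's clinical frame."""
    sample_ids = pd.Index(sample_ids)
    if isinstance(y, pd.DataFrame):
        df = y.copy()
        if df.index.name == "sample_id" or df.index.isin(sample_ids).all():
            df = df.loc[sample_ids]
        else:
            df.index = sample_ids
        cols = {c.lower(): c for c in df.columns}
        tcol = cols.get("time_months") or cols.get("time")
        ecol = cols.get("event")
        if tcol is None or ecol is None:
            raise DataError("y frame needs time(_months) and event columns")
        out = pd.DataFrame({"time_months": df[tcol].astype(float),
                            "event": df[ecol].astype(int)}, index=sample_ids)
    elif isinstance(y, np.ndarray) and y.dtype.names:
        names = {n.lower(): n for n in y.dtype.names}
        tname = names.get("time") or names.get("time_months")
        ename = names.get("event")
        if tname is None or ename is None:
            raise DataError("structured y needs time and event fields")
        out = pd.DataFrame({"time_months": y[tname].astype(float),
                            "event": y[ename].astype(int)}, index=sample_ids)
    elif isinstance(y, (tuple, list)) and len(y) == 2:
        time, event = (np.asarray(a) for a in y)
        out = pd.DataFrame({"time_months": time.astype(float),
                            "event": event.astype(int)}, index=sample_ids)
    else:
        raise DataError("unsupported y type for survival labels")
    out.index.name = "sample_id"
    return out


def _as_expression(X) -> pd.DataFrame:
    """samples x genes input -> genes x samples frame."""
    if isinstance(X, pd.DataFrame):
        return X.T.astype(float)
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X.T, index=[f"g{i}" for i in range(X.shape[1])],
                        columns=[f"s{i}" for i in range(X.shape[0])])


class SubgroupRiskModel(BaseEstimator):
    """Two-signature nearest-centroid recurrence-risk classifier.

    Parameters mirror the published training recipe: a p < ``prescreen_alpha``
    univariate Cox screen, ``cv_rounds`` rounds of ``cv_folds``-fold
    cross-validation ranking genes by Cox p-value, selection of genes in
    the top ``top_k`` ranks in at least ``freq_threshold`` of fits, and a
    cutoff per signature maximizing the training log-rank statistic with a
    ``min_group_frac`` minimum arm size.

    ``epithelial_markers`` (gene ids) fix the subgroup numbering: subgroup 1
    is the branch with the lower mean marker z-score (the marker-loss
    state). Without markers, branches are numbered by descending size.
    """

    def __init__(self, prescreen_alpha=0.01, cv_rounds=200, cv_folds=10,
                 top_k=150, freq_threshold=0.80, n_variance_genes=500,
                 min_group_frac=0.10, counting="per_fold_fit",
                 prescreen_filter=True, score_metric="uncentered",
                 epithelial_markers=None, random_state=0):
        self.prescreen_alpha = prescreen_alpha
        self.cv_rounds = cv_rounds
        self.cv_folds = cv_folds
        self.top_k = top_k
        self.freq_threshold = freq_threshold
        self.n_variance_genes = n_variance_genes
        self.min_group_frac = min_group_frac
        self.counting = counting
        self.prescreen_filter = prescreen_filter
        self.score_metric = score_metric
        self.epithelial_markers = epithelial_markers
        self.random_state = random_state

    # -- config plumbing ----------------------------------------------------

    def _discovery_config(self, seed) -> DiscoveryConfig:
        return DiscoveryConfig(
            prescreen_alpha=self.prescreen_alpha,
            cv_rounds=self.cv_rounds,
            cv_folds=self.cv_folds,
            top_k=self.top_k,
            freq_threshold=self.freq_threshold,
            n_branches=2,
            n_variance_genes=self.n_variance_genes,
            counting=self.counting,
            prescreen_filter=self.prescreen_filter,
            seed=seed,
        ).validate()

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        expr = _as_expression(X)
        clinical = as_clinical(y, expr.columns)
        if self.score_metric not in ("uncentered", "pearson"):
            raise ConfigError(f"unknown score_metric {self.score_metric!r}")
        seed = 0 if self.random_state is None else int(self.random_state)
        branch_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(2)
        ]
        config = self._discovery_config(seed)

        expr_z, params = standardize(expr)
        partition = partition_recurrence(
            expr, clinical, config, epithelial_markers=self.epithelial_markers)
        norec = list(clinical.index[clinical["event"] == 0])
        if not norec:
            raise DataError("no norecurrence samples in the training cohort")

        signatures = []
        stability_results = {}
        prescreen_sets = {}
        for branch in (1, 2):
            branch_samples = partition.samples_in(branch)
            cohort = branch_samples + norec
            branch_clin = clinical.loc[cohort]
            screened = prescreen_genes(expr[cohort], branch_clin,
                                       self.prescreen_alpha)
            prescreen_sets[branch] = screened
            branch_cfg = self._discovery_config(branch_seeds[branch - 1])
            stab = stability_select(expr, clinical, branch_samples, norec,
                                    branch_cfg)
            stability_results[branch] = stab
            selected = stab.selected_genes
            if self.prescreen_filter:
                screened_set = set(screened)
                selected = [g for g in selected if g in screened_set]
            if not selected:
                raise InsufficientSignalError(
                    f"branch {branch}: no gene is both stability-selected and "
                    f"below the p < {self.prescreen_alpha} screen"
                )
            sig = build_signature(
                expr_z, branch_samples, norec, selected,
                name=f"subgroup{branch}", standardization=params,
                metric=self.score_metric)
            scores = score_samples(sig, expr_z, is_z=True)
            sig.cutoff = optimize_cutoff(scores, clinical,
                                         min_group_frac=self.min_group_frac)
            sig.meta.update({"n_genes": len(selected), "seed": seed})
            signatures.append(sig)

        self.standardization_ = params
        self.partition_ = partition
        self.prescreen_ = prescreen_sets
        self.stability_ = stability_results
        self.signature1_, self.signature2_ = signatures
        self.classes_ = np.asarray(RISK_LABELS, dtype=object)
        self.feature_names_in_ = np.asarray(expr.index, dtype=object)
        self.n_features_in_ = expr.shape[0]
        self.training_report_ = self._evaluate(expr, clinical)
        return self

    # -- prediction ---------------------------------------------------------

    def risk_table(self, X) -> pd.DataFrame:
        """Full per-sample call table: scores, margins, combined score, label."""
        check_is_fitted(self, "signature1_")
        expr = _as_expression(X)
        return classify(self.signature1_, self.signature2_, expr)

    def predict(self, X) -> np.ndarray:
        return self.risk_table(X)["label"].to_numpy(dtype=object)

    def decision_function(self, X) -> np.ndarray:
        """Continuous combined risk score (max cutoff-centered margin)."""
        return self.risk_table(X)["combined_score"].to_numpy(dtype=float)

    # -- evaluation ---------------------------------------------------------

    def _evaluate(self, expr, clinical) -> dict:
        calls = classify(self.signature1_, self.signature2_, expr, is_z=False)
        return evaluate_calls(calls, clinical)

    def evaluate(self, X, y) -> dict:
        """High-risk fraction, per-group 3-year RFS, log-rank p, HR and AUC."""
        check_is_fitted(self, "signature1_")
        expr = _as_expression(X)
        clinical = as_clinical(y, expr.columns)
        return evaluate_calls(self.risk_table(X), clinical)


def evaluate_calls(calls: pd.DataFrame, clinical: pd.DataFrame,
                   horizon_months: float = 36.0) -> dict:
    """Survival evaluation of a risk-call table against follow-up data."""
    from .survival import km_estimate, survival_at  # local: avoid cycle at import

    common = calls.index.intersection(clinical.index)
    if len(common) == 0:
        raise DataError("calls and clinical tables share no sample ids")
    calls = calls.loc[common]
    clin = clinical.loc[common]
    high = (calls["label"] != "low_risk").to_numpy().astype(int)
    time = clin["time_months"].to_numpy()
    event = clin["event"].to_numpy()
    report = {
        "n": int(len(common)),
        "n_events": int(event.sum()),
        "high_risk_fraction": float(high.mean()),
        "n_high_risk_1": int((calls["label"] == "high_risk_1").sum()),
        "n_high_risk_2": int((calls["label"] == "high_risk_2").sum()),
    }
    for label, mask in (("low", high == 0), ("high", high == 1)):
        if mask.sum() == 0:
            report[f"rfs36_{label}"] = None
            continue
        point = survival_at(km_estimate(time[mask], event[mask]), horizon_months)
        report[f"rfs36_{label}"] = point.estimate
        report[f"rfs36_{label}_ci"] = (point.ci_low, point.ci_high)
    if 0 < high.sum() < high.size:
        report["logrank_p"] = logrank_test(time, event, high).p_value
        cox = fit_cox_group(time, event, high)
        report["hr_high_vs_low"] = cox.hr
        report["hr_p"] = cox.p_value
    else:
        report["logrank_p"] = None
        report["hr_high_vs_low"] = None
        report["hr_p"] = None
    score = calls["combined_score"].to_numpy()
    if 0 < event.sum() < event.size:
        report["auc"] = concordance_auc(score, event)
    else:
        report["auc"] = None
    return report
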