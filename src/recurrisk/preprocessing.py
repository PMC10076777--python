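"""Per-gene standardization with frozen training parameters.

Centroid scoring operates on z-scores; a validation cohort must be scaled
with the *training* cohort's per-gene mean and standard deviation, so the
parameters are an explicit, serializable object. Zero-variance genes are
z-scored to 0 (not dropped) so downstream gene lists keep their length;
they are recorded so the trainer can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import FormatError


@dataclass
class StandardizationParams:
    """Frozen per-gene (mean, sd) pairs estimated on a training cohort."""

    mean: pd.Series
    sd: pd.Series
    zero_variance_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.mean = pd.Series(self.mean, dtype=float)
        self.sd = pd.Series(self.sd, dtype=float)
        if not self.mean.index.equals(self.sd.index):
            raise FormatError("standardization mean/sd gene lists differ")
        if (self.sd < 0).any():
            raise FormatError("standard deviations must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.mean.index

    def to_dict(self) -> dict:
        return {
            "genes": list(self.mean.index),
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
            "zero_variance_genes": list(self.zero_variance_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        genes = d["genes"]
        if not (len(genes) == len(d["mean"]) == len(d["sd"])):
            raise FormatError("standardization arrays have inconsistent lengths")
        return cls(
            mean=pd.Series(d["mean"], index=genes),
            sd=pd.Series(d["sd"], index=genes),
            zero_variance_genes=list(d.get("zero_variance_genes", [])),
        )


def standardize(expr: pd.DataFrame, params: StandardizationParams | None = None):
    """z-score a genes x samples matrix; returns ``(z, params)``.

    With ``params`` given, the frozen training mean/sd are applied (every
    gene in ``expr`` must be covered). Otherwise parameters are estimated
    on ``expr`` itself (sample sd, ddof=1). Zero-variance genes map to 0.
    """
    if params is None:
        mean = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1).fillna(0.0)
        zero_var = list(expr.index[sd == 0])
        params = StandardizationParams(mean=mean, sd=sd, zero_variance_genes=zero_var)
    else:
        missing = expr.index.difference(params.genes)
        if len(missing):
            raise KeyError(
                f"gene {missing[0]!r} absent from standardization parameters"
            )
    mean = params.mean.reindex(expr.index)
    sd = params.sd.reindex(expr.index)
    safe_sd = sd.replace(0.0, 1.0)
    z = expr.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[sd == 0] = 0.0
    return z, params


class GeneStandardizer(TransformerMixin, BaseEstimator):
    """sklearn transformer over samples x genes matrices.

    Thin estimator facade over :func:`standardize`; ``fit`` freezes per-gene
    mean/sd, ``transform`` applies them to any cohort.
    """

    def fit(self, X, y=None):
        X = self._to_frame(X)
        _, params = standardize(X.T)
        self.params_ = params
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        X = self._to_frame(X)
        z, _ = standardize(X.T, self.params_)
        return z.T

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])
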