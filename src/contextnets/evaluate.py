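"""Expression-MSE scoring, relative errors, and hold-out-group CV.

Goodness-of-fit of any per-sample network set is measured against observed
(standardized) expression through the class's own predictive form, so the
number reported here equals the penalty-free training loss on the same rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import UnseenGroupError
from .networks import MASKED_CLASSES, NetworkClass, SampleNetworks

__all__ = [
    "EvaluationReport",
    "expression_mse",
    "relative_mse",
    "error_reduction",
    "holdout_group_cv",
    "bootstrap_summary",
]


def expression_mse(networks: SampleNetworks, X: np.ndarray) -> np.ndarray:
    """Per-sample mean squared residual under the network class's form.

    neighborhood/markov: residual of ``x - x @ theta`` averaged over the p
    genes; correlation: residuals of all p*p ordered-pair univariate
    regressions (the diagonal self-regression contributes 0 at theta_ii=1).
    ``X`` must already be on the scale the networks were fitted to.
    """
    X = np.asarray(X, dtype=float)
    theta = networks.values
    if X.shape[0] != theta.shape[0]:
        raise ValueError(f"networks have {theta.shape[0]} samples, X has {X.shape[0]}")
    if X.shape[1] != theta.shape[1]:
        raise ValueError(f"networks have p={theta.shape[1]}, X has p={X.shape[1]}")
    if networks.network_class is NetworkClass.CORRELATION:
        resid = X[:, None, :] - X[:, :, None] * theta
        return np.mean(resid**2, axis=(1, 2))
    if networks.network_class is NetworkClass.MARKOV:
        theta = theta + np.swapaxes(theta, -1, -2)
    resid = X - np.einsum("ni,nij->nj", X, theta)
    return np.mean(resid**2, axis=1)


@dataclass
class EvaluationReport:
    """Per-sample MSEs with optional group structure and bootstrap spread."""

    per_sample_mse: np.ndarray
    groups: np.ndarray | None = None
    model: str = ""
    bootstrap_sd: float | None = None

    def __post_init__(self) -> None:
        self.per_sample_mse = np.asarray(self.per_sample_mse, dtype=float)
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != len(self.per_sample_mse):
                raise ValueError("groups and per-sample MSEs must align")

    @property
    def mean(self) -> float:
        """Population-averaged MSE."""
        return float(np.mean(self.per_sample_mse))

    def group_means(self) -> pd.Series:
        if self.groups is None:
            return pd.Series({"all": self.mean})
        return (
            pd.Series(self.per_sample_mse)
            .groupby(pd.Series(self.groups))
            .mean()
            .rename(self.model or "mse")
        )

    def to_frame(self) -> pd.DataFrame:
        gm = self.group_means()
        return pd.DataFrame(
            {"group": gm.index, "model": self.model, "mse": gm.values}
        )


def relative_mse(report: EvaluationReport, baseline: EvaluationReport) -> pd.Series:
    """Group-mean MSE ratios, baseline in the denominator.

    A zero baseline MSE yields NaN (flagged), never infinity; the baseline
    against itself is exactly 1 everywhere.
    """
    num = report.group_means()
    den = baseline.group_means()
    if not num.index.equals(den.index):
        raise ValueError("reports have different groupings")
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"baseline MSE is zero for groups {list(den.index[zero])}; "
            "relative MSE undefined there"
        )
    out = num / den.where(~zero)
    return out.rename(f"{report.model}_vs_{baseline.model}")


def error_reduction(ratios: pd.Series) -> float:
    """Headline summary ``1 - mean(relative MSE)`` as a fraction."""
    return float(1.0 - np.nanmean(np.asarray(ratios, dtype=float)))


def holdout_group_cv(contexts, expression, group_labels, fitters: dict) -> pd.DataFrame:
    """Hold out each group entirely, fit on the rest, score on the held-out rows.

    ``fitters`` maps a model name to ``fit(contexts_tr, X_tr, labels_tr)``
    returning ``score(contexts_te, X_te, labels_te) -> per-sample MSEs``.
    A scorer raising :class:`UnseenGroupError` is reported as not applicable
    (NaN MSE, ``applicable=False``) -- the structural limitation of
    group-specific inference on unseen groups.
    """
    contexts_df = _as_frame(contexts)
    X = np.asarray(expression, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("hold-out-group CV needs at least 2 groups")
    rows = []
    for g in groups:
        te = labels == g
        tr = ~te
        if te.sum() == 1:
            warnings.warn(f"group {g!r} is a singleton; evaluating anyway")
        for name, fit_fn in fitters.items():
            scorer = fit_fn(contexts_df[tr], X[tr], labels[tr])
            try:
                mses = scorer(contexts_df[te], X[te], labels[te])
                rows.append(dict(group=g, model=name, mse=float(np.mean(mses)),
                                 applicable=True))
            except UnseenGroupError:
                rows.append(dict(group=g, model=name, mse=np.nan, applicable=False))
    return pd.DataFrame(rows)


def bootstrap_summary(ensemble, contexts, expression) -> dict:
    """Population-averaged MSE of the averaged networks, SD over members.

    The point estimate scores the bootstrap-averaged networks; the SD is
    taken over the per-member population-averaged MSEs.
    """
    mse = float(np.mean(ensemble.measure_mse(contexts, expression)))
    member_means = ensemble.member_mses(contexts, expression)
    return {"mse": mse, "sd": float(np.std(member_means)), "B": ensemble.B}


def _as_frame(contexts) -> pd.DataFrame:
    if isinstance(contexts, pd.DataFrame):
        return contexts.reset_index(drop=True)
    arr = np.asarray(contexts)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
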