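"""Network-parameter subtype discovery and survival stratification.

Samples are clustered by Ward-linkage hierarchical clustering on their
flattened network parameters; the number of clusters is either matched to a
reference subtyping or chosen by the best mean silhouette over k = 2..10.
Discovered subtypes are then characterized by per-feature Welch t-tests
(subtype vs. rest, minimum p over subtypes) and by multivariate and
pairwise log-rank tests against a survival table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind
from sklearn.metrics import silhouette_score

from .networks import NetworkClass, SampleNetworks

__all__ = [
    "SubtypeReport",
    "SurvivalTable",
    "flatten_networks",
    "cluster_networks",
    "select_k_silhouette",
    "feature_association",
    "logrank_tests",
    "subtype_pipeline",
]


@dataclass
class SurvivalTable:
    """Right-censored survival data: time-to-event and event indicator."""

    time: np.ndarray
    event: np.ndarray
    sample_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.time) != len(self.event):
            raise ValueError("time and event must align")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("times must be finite and nonnegative")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicators must be 0/1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalTable":
        cols = {c.lower(): c for c in df.columns}
        return cls(
            time=df[cols.get("time", df.columns[1])].to_numpy(),
            event=df[cols.get("event", df.columns[2])].to_numpy(),
            sample_id=df[cols.get("sample", df.columns[0])].to_numpy(),
        )


@dataclass
class SubtypeReport:
    labels: np.ndarray
    k: int
    silhouette_by_k: dict = field(default_factory=dict)
    feature_pvalues: pd.Series | None = None
    logrank_multivariate_p: float | None = None
    logrank_pairwise_p: np.ndarray | None = None
    min_pairwise_p: float | None = None


def flatten_networks(networks: SampleNetworks) -> np.ndarray:
    """Vectorize each sample's network for clustering.

    Neighborhood networks keep all off-diagonal entries (the matrix is
    asymmetric); markov and correlation networks keep the upper triangle
    only, to avoid double-weighting symmetric entries.
    """
    vals = networks.values
    p = networks.p
    if networks.network_class is NetworkClass.NEIGHBORHOOD:
        mask = ~np.eye(p, dtype=bool)
    else:
        mask = np.triu(np.ones((p, p), dtype=bool), k=1)
        if networks.network_class is NetworkClass.MARKOV:
            # cluster on the symmetric coefficients, not the raw gamma
            vals = vals + np.swapaxes(vals, -1, -2)
    return vals[:, mask]


def _ward_labels(flat: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(flat, method="ward")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def cluster_networks(networks: SampleNetworks | np.ndarray, k: int) -> SubtypeReport:
    """Ward-linkage agglomerative clustering on flattened network parameters."""
    flat = flatten_networks(networks) if isinstance(networks, SampleNetworks) else np.asarray(networks, dtype=float)
    n = flat.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    labels = _ward_labels(flat, k)
    sil = _safe_silhouette(flat, labels)
    if k >= 2 and (sil is None or sil <= 0):
        warnings.warn(
            f"degenerate split at k={k}: "
            + ("clustering collapsed" if sil is None else f"silhouette {sil:.3f} <= 0")
        )
    return SubtypeReport(labels=labels, k=int(len(np.unique(labels))),
                         silhouette_by_k={k: sil})


def _safe_silhouette(flat: np.ndarray, labels: np.ndarray) -> float | None:
    if len(np.unique(labels)) < 2:
        return None
    try:
        return float(silhouette_score(flat, labels))
    except ValueError:
        return None


def select_k_silhouette(
    networks: SampleNetworks | np.ndarray, k_range=range(2, 11)
) -> tuple[int, dict]:
    """Pick k maximizing the mean silhouette of the Ward labels; ties -> smallest k.

    Degenerate inputs (all points identical) fall back to the smallest k with
    a warning.
    """
    flat = flatten_networks(networks) if isinstance(networks, SampleNetworks) else np.asarray(networks, dtype=float)
    n = flat.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 samples to select k")
    scores: dict[int, float | None] = {}
    for k in k_range:
        if k > n:
            break
        scores[k] = _safe_silhouette(flat, _ward_labels(flat, k))
    valid = {k: s for k, s in scores.items() if s is not None and np.isfinite(s)}
    if not valid or max(valid.values()) <= 0 and np.allclose(flat, flat[0]):
        warnings.warn("silhouette undefined (identical samples); falling back to k=2")
        return min(scores), scores
    best = max(valid.values())
    k_best = min(k for k, s in valid.items() if s == best)
    return k_best, scores


def feature_association(
    context_features: pd.DataFrame | np.ndarray, labels: np.ndarray
) -> pd.Series:
    """Per-feature minimum two-sided Welch-t p-value over subtype-vs-rest splits.

    Features with zero variance on both sides of every split get p = 1
    (flagged). Result is sorted ascending (most subtype-associated first).
    """
    df = context_features if isinstance(context_features, pd.DataFrame) else pd.DataFrame(
        np.atleast_2d(np.asarray(context_features, dtype=float)),
        columns=[f"c{i}" for i in range(np.atleast_2d(np.asarray(context_features)).shape[1])],
    )
    labels = np.asarray(labels)
    pvals = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        best = 1.0
        for g in np.unique(labels):
            a, b = x[labels == g], x[labels != g]
            if len(a) < 2 or len(b) < 2:
                continue
            if np.var(a) == 0 and np.var(b) == 0:
                if a[0] != b[0]:  # perfectly separating constant feature
                    best = 0.0
                continue  # identical on both sides: contributes p = 1
            res = ttest_ind(a, b, equal_var=False)
            p = float(res.pvalue)
            if np.isfinite(p):
                best = min(best, p)
        pvals[col] = best
    return pd.Series(pvals, name="min_p").sort_values()


def logrank_tests(
    labels: np.ndarray, survival: SurvivalTable
) -> tuple[float, pd.DataFrame, float]:
    """Multivariate and all-pairs log-rank tests across subtype labels.

    Returns ``(multivariate_p, pairwise_p_frame, min_pairwise_p)``. Groups
    with no observations are excluded with a warning. -log10 transforms for
    reporting are left to the caller (see :func:`subtype_pipeline`).
    """
    labels = np.asarray(labels)
    if len(labels) != len(survival.time):
        raise ValueError("labels and survival table must align")
    groups = [g for g in np.unique(labels) if np.sum(labels == g) > 0]
    if len(groups) < 2:
        raise ValueError("log-rank tests need at least 2 groups")
    if survival.event.sum() == 0:
        raise ValueError("log-rank tests need at least one event")
    mv = multivariate_logrank_test(survival.time, labels, survival.event)
    pairwise = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    min_p = 1.0
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            mi, mj = labels == gi, labels == gj
            res = logrank_test(
                survival.time[mi], survival.time[mj],
                event_observed_A=survival.event[mi],
                event_observed_B=survival.event[mj],
            )
            p = float(res.p_value)
            pairwise.loc[gi, gj] = pairwise.loc[gj, gi] = p
            min_p = min(min_p, p)
    return float(mv.p_value), pairwise, min_p


def subtype_pipeline(
    networks: SampleNetworks,
    context_features=None,
    survival: SurvivalTable | None = None,
    k: int | None = None,
    reference_labels: np.ndarray | None = None,
) -> SubtypeReport:
    """Cluster -> associate -> stratify, the full subtype discovery recipe.

    ``k`` is forced to the reference subtyping's cluster count when
    ``reference_labels`` is given, otherwise chosen by silhouette unless
    passed explicitly.
    """
    flat = flatten_networks(networks)
    sil_trace: dict = {}
    if reference_labels is not None:
        k = int(len(np.unique(np.asarray(reference_labels))))
    if k is None:
        k, sil_trace = select_k_silhouette(flat)
    report = cluster_networks(flat, k)
    report.silhouette_by_k = {**sil_trace, **report.silhouette_by_k}
    if context_features is not None:
        report.feature_pvalues = feature_association(context_features, report.labels)
    if survival is not None:
        mv_p, pairwise, min_p = logrank_tests(report.labels, survival)
        report.logrank_multivariate_p = mv_p
        report.logrank_pairwise_p = pairwise.to_numpy()
        report.min_pairwise_p = min_p
    return report
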