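"""Partition-based baseline estimators fitted under the same class losses.

Three granularities bracket the contextualized model:

* ``population`` -- one network for every sample;
* ``labels`` -- one network per known cohort (e.g. disease type);
* ``context_clusters`` -- k-means on the encoded context matrix, then one
  network per cluster.

With no L1 penalty the neighborhood and correlation fits are exact least
squares; the symmetric Markov fit is solved exactly from its stationarity
conditions (a linear system in the p(p-1)/2 free entries). With a penalty,
a small Adam loop on the shared parameter matrix is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .encoder import ContextSchema
from .networks import NetworkClass, SampleNetworks, loss_and_grad
from .train import _Adam, _context_frame

__all__ = ["GroupingScheme", "GroupedNetworks", "UnseenGroupError", "fit_grouped",
           "fit_single_network"]


class UnseenGroupError(KeyError):
    """Raised when a label-based baseline is asked about a group it never saw."""


@dataclass
class GroupingScheme:
    kind: str  # population | labels | context_clusters
    labels: np.ndarray | None = None
    n_clusters: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("population", "labels", "context_clusters"):
            raise ValueError(f"unknown grouping kind {self.kind!r}")
        if (self.kind == "labels") != (self.labels is not None):
            raise ValueError("labels must be given exactly when kind='labels'")
        if self.kind != "context_clusters" and self.n_clusters is not None:
            raise ValueError("n_clusters only applies to kind='context_clusters'")


# ---------------------------------------------------------------------------
# single-network fits
# ---------------------------------------------------------------------------

def fit_single_network(
    X: np.ndarray,
    network_class: NetworkClass | str,
    lambda_l1: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Fit one network to i.i.d. rows; returns the regression-form matrix.

    For the markov class the returned matrix is gamma' (half the symmetric
    coefficient matrix) so that downstream reconstruction conventions match
    the contextualized model.
    """
    network_class = NetworkClass.coerce(network_class)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p:
        warnings.warn(f"degenerate fit: n={n} < p={p}; coefficients are high-variance")
    if network_class is NetworkClass.CORRELATION:
        # separable univariate OLS per ordered pair; lambda does not apply
        sq = np.einsum("ni,ni->i", X, X)
        cross = X.T @ X
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(sq[:, None] > 0, cross / sq[:, None], 0.0)
        return theta
    if lambda_l1 == 0.0:
        if network_class is NetworkClass.NEIGHBORHOOD:
            theta = np.zeros((p, p))
            for j in range(p):
                others = [i for i in range(p) if i != j]
                coef, *_ = np.linalg.lstsq(X[:, others], X[:, j], rcond=None)
                theta[others, j] = coef
            return theta
        return _fit_markov_exact(X)
    return _fit_single_gradient(X, network_class, lambda_l1, seed)


def _fit_markov_exact(X: np.ndarray) -> np.ndarray:
    """Exact symmetric zero-diagonal fit of ``min ||X - X(gamma+gamma.T)||^2``.

    Stationarity requires offdiag(sym(S - S theta)) = 0 with S = X.T X and
    theta symmetric, zero-diagonal; solved as a linear system over the
    upper-triangle entries. Returns gamma' = theta / 2.
    """
    p = X.shape[1]
    S = X.T @ X
    pairs = [(a, b) for a in range(p) for b in range(a + 1, p)]
    npairs = len(pairs)
    M = np.zeros((npairs, npairs))
    rhs = np.array([S[a, b] for a, b in pairs])
    for r, (a, b) in enumerate(pairs):
        # sym(S theta)_ab = 0.5 * (sum_i S_ai theta_ib + sum_i S_bi theta_ia)
        for c, (k, l) in enumerate(pairs):
            val = 0.0
            # theta_kl = theta_lk appears in column b via i=k or i=l, etc.
            if l == b:
                val += 0.5 * S[a, k]
            if k == b:
                val += 0.5 * S[a, l]
            if l == a:
                val += 0.5 * S[b, k]
            if k == a:
                val += 0.5 * S[b, l]
            M[r, c] = val
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    theta = np.zeros((p, p))
    for c, (k, l) in enumerate(pairs):
        theta[k, l] = theta[l, k] = sol[c]
    return theta / 2.0


def _fit_single_gradient(
    X: np.ndarray, network_class: NetworkClass, lambda_l1: float, seed: int,
    max_iter: int = 2000, tol: float = 1e-10,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    theta = rng.normal(0.0, 1e-3, size=(p, p))
    opt = _Adam([theta], 1e-2)
    prev = np.inf
    for _ in range(max_iter):
        loss, grad = loss_and_grad(theta, X, network_class, lambda_l1)
        theta = opt.step([theta], [grad.sum(axis=0)])[0]
        if abs(prev - loss) < tol:
            break
        prev = loss
    return theta * (1.0 - np.eye(p))


# ---------------------------------------------------------------------------
# grouped estimators
# ---------------------------------------------------------------------------

class GroupedNetworks:
    """A fitted partition-based baseline (one network per group)."""

    def __init__(self, scheme: GroupingScheme, network_class: NetworkClass,
                 lambda_l1: float = 0.0, standardize: bool = True, seed: int = 0):
        self.scheme = scheme
        self.network_class = NetworkClass.coerce(network_class)
        self.lambda_l1 = lambda_l1
        self.standardize_flag = standardize
        self.seed = seed
        self.networks: dict = {}
        self.expr_mean: np.ndarray | None = None
        self.expr_std: np.ndarray | None = None
        self.schema: ContextSchema | None = None
        self.kmeans: KMeans | None = None

    def standardize(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.expr_mean is None:
            return X
        return (X - self.expr_mean) / self.expr_std

    # -- fitting -------------------------------------------------------------
    def fit(self, contexts, expression) -> "GroupedNetworks":
        X = np.asarray(expression, dtype=float)
        n, p = X.shape
        if self.standardize_flag:
            self.expr_mean = X.mean(axis=0)
            sd = X.std(axis=0)
            self.expr_std = np.where(sd > 0, sd, 1.0)
        else:
            self.expr_mean = np.zeros(p)
            self.expr_std = np.ones(p)
        Xs = self.standardize(X)
        assignments = self._fit_assignments(contexts, n)
        for g in np.unique(assignments):
            rows = Xs[assignments == g]
            if len(rows) == 0:
                raise ValueError(f"group {g!r} is empty")
            self.networks[g] = fit_single_network(
                rows, self.network_class, self.lambda_l1, self.seed
            )
        return self

    def _fit_assignments(self, contexts, n: int) -> np.ndarray:
        if self.scheme.kind == "population":
            return np.zeros(n, dtype=object)
        if self.scheme.kind == "labels":
            labels = np.asarray(self.scheme.labels)
            if len(labels) != n:
                raise ValueError("labels length does not match expression rows")
            return labels
        Cdf = _context_frame(contexts)
        self.schema = ContextSchema.fit(Cdf)
        C = self.schema.transform(Cdf)
        k = self.scheme.n_clusters or self._silhouette_k(C)
        self.kmeans = KMeans(n_clusters=k, n_init=10, random_state=self.seed).fit(C)
        return self.kmeans.labels_.astype(object)

    @staticmethod
    def _silhouette_k(C: np.ndarray, k_range=range(2, 11)) -> int:
        best_k, best_s = 2, -np.inf
        for k in k_range:
            if k >= len(C):
                break
            lab = KMeans(n_clusters=k, n_init=10, random_state=0).fit(C).labels_
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(C, lab)
            if s > best_s + 1e-12:
                best_k, best_s = k, s
        return best_k

    # -- prediction ----------------------------------------------------------
    def assign_groups(self, contexts=None, labels=None, n: int | None = None) -> np.ndarray:
        if self.scheme.kind == "population":
            if n is None:
                if contexts is not None:
                    n = len(_context_frame(contexts))
                elif labels is not None:
                    n = len(np.atleast_1d(labels))
                else:
                    raise ValueError("population prediction needs contexts, labels, or n")
            return np.zeros(n, dtype=object)
        if self.scheme.kind == "labels":
            if labels is None:
                raise ValueError("labels mode requires labels at prediction time")
            labels = np.asarray(labels)
            unseen = [l for l in np.unique(labels) if l not in self.networks]
            if unseen:
                raise UnseenGroupError(
                    f"no fitted network for group(s) {unseen}; "
                    "group-specific inference cannot be applied to unseen groups"
                )
            return labels
        C = self.schema.transform(_context_frame(contexts))
        return self.kmeans.predict(C).astype(object)

    def predict_networks(self, contexts=None, labels=None, n: int | None = None) -> SampleNetworks:
        assignments = self.assign_groups(contexts, labels, n)
        p = next(iter(self.networks.values())).shape[0]
        theta = np.stack([self.networks[g] for g in assignments]) if len(assignments) else np.empty((0, p, p))
        return SampleNetworks(theta, self.network_class)

    def measure_mse(self, expression, contexts=None, labels=None) -> np.ndarray:
        from .evaluate import expression_mse

        nets = self.predict_networks(contexts, labels, n=len(np.asarray(expression)))
        return expression_mse(nets, self.standardize(expression))


def fit_grouped(
    contexts,
    expression,
    scheme: GroupingScheme,
    network_class: NetworkClass | str = NetworkClass.MARKOV,
    lambda_l1: float = 0.0,
    standardize: bool = True,
    seed: int = 0,
) -> GroupedNetworks:
    """Fit one network per group under the requested scheme; see class docs."""
    return GroupedNetworks(scheme, network_class, lambda_l1, standardize, seed).fit(
        contexts, expression
    )
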