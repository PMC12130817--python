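"""Unified linear parameterizations of the three network classes.

Three classical views of a gene-gene network are expressed as square matrices
of linear-regression coefficients, which makes their fitting objectives
differentiable and mutually comparable:

* **neighborhood** -- each gene is regressed on all others; ``theta[i, j]`` is
  the coefficient of gene *i* in the prediction of gene *j*, with a zero
  diagonal (no self-regression).
* **markov** -- a Gaussian graphical model under the unit-diagonal precision
  convention; the regression matrix is the symmetrization ``gamma + gamma.T``
  of a zero-diagonal matrix, and the precision estimate is
  ``Omega = -(gamma + gamma.T)`` off the diagonal with ones on it.
* **correlation** -- every ordered pair (i, j) is a separate univariate
  regression of gene j on gene i; products ``theta[i, j] * theta[j, i]``
  recover squared Pearson correlations.

All losses use a *mean* reduction over residual terms so values are
comparable across sample and gene counts; the L1 penalty is
``lambda * sum(|offdiag|)`` per network, averaged over samples when networks
are sample-specific.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkClass",
    "NetworkParams",
    "SampleNetworks",
    "mask_diagonal",
    "neighborhood_loss",
    "markov_loss",
    "correlation_loss",
    "loss_and_grad",
    "reconstruct_precision",
    "partial_correlation",
    "reconstruct_correlation",
]


class NetworkClass(str, enum.Enum):
    """Which network family a parameter matrix belongs to."""

    NEIGHBORHOOD = "neighborhood"
    MARKOV = "markov"
    CORRELATION = "correlation"

    @classmethod
    def coerce(cls, value: "NetworkClass | str") -> "NetworkClass":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


#: classes whose regression matrix has a masked (zero) diagonal
MASKED_CLASSES = (NetworkClass.NEIGHBORHOOD, NetworkClass.MARKOV)


@dataclass
class NetworkParams:
    """A single p x p network parameter matrix with its class tag."""

    values: np.ndarray
    network_class: NetworkClass
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.network_class = NetworkClass.coerce(self.network_class)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"expected square matrix, got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("networks need at least 2 genes")
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[0])]

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class SampleNetworks:
    """Per-sample network parameters: an (n, p, p) tensor plus a class tag.

    ``values`` holds the *regression-form* parameters (masked theta for
    neighborhood, masked gamma for markov, dense theta for correlation);
    use :func:`reconstruct_precision` / :func:`reconstruct_correlation`
    to obtain the interpretable network matrices.
    """

    values: np.ndarray
    network_class: NetworkClass
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.network_class = NetworkClass.coerce(self.network_class)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(f"expected (n, p, p) tensor, got {self.values.shape}")
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[1])]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# masking and losses
# ---------------------------------------------------------------------------

def mask_diagonal(theta: np.ndarray) -> np.ndarray:
    """Zero the diagonal: ``(1 - I) * theta`` elementwise.

    Accepts a single p x p matrix or an (n, p, p) stack; off-diagonal
    entries are unchanged.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim not in (2, 3) or theta.shape[-1] != theta.shape[-2]:
        raise ValueError(f"expected square matrix or stack, got shape {theta.shape}")
    p = theta.shape[-1]
    return theta * (1.0 - np.eye(p))


def _as_stack(theta: np.ndarray, n: int) -> np.ndarray:
    """Broadcast a shared p x p matrix to an (n, p, p) stack if needed."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 2:
        return np.broadcast_to(theta, (n,) + theta.shape)
    if theta.ndim == 3:
        if theta.shape[0] != n:
            raise ValueError(f"theta stack has {theta.shape[0]} samples, X has {n}")
        return theta
    raise ValueError(f"theta must be 2- or 3-dimensional, got ndim={theta.ndim}")


def _check_shapes(theta: np.ndarray, X: np.ndarray) -> None:
    if theta.shape[-1] != theta.shape[-2]:
        raise ValueError(f"theta is not square: {theta.shape}")
    if X.ndim != 2:
        raise ValueError(f"X must be 2-dimensional, got {X.shape}")
    if theta.shape[-1] != X.shape[1]:
        raise ValueError(f"theta has p={theta.shape[-1]} but X has p={X.shape[1]}")


def _l1_penalty(theta_masked: np.ndarray, lambda_l1: float) -> float:
    """lambda * sum |offdiag|, averaged over the sample axis if present."""
    if lambda_l1 == 0.0:
        return 0.0
    if theta_masked.ndim == 3:
        return lambda_l1 * float(np.abs(theta_masked).sum()) / theta_masked.shape[0]
    return lambda_l1 * float(np.abs(theta_masked).sum())


def neighborhood_loss(
    theta_masked: np.ndarray, X: np.ndarray, lambda_l1: float = 0.0
) -> float:
    """Mean squared residual of ``X - X @ theta'`` plus the L1 penalty.

    ``theta_masked`` may be shared (p x p) or per-sample (n x p x p); its
    diagonal must already be zero.
    """
    X = np.asarray(X, dtype=float)
    _check_shapes(np.asarray(theta_masked), X)
    th = _as_stack(theta_masked, X.shape[0])
    resid = X - np.einsum("ni,nij->nj", X, th)
    return float(np.mean(resid**2)) + _l1_penalty(np.asarray(theta_masked), lambda_l1)


def markov_loss(
    gamma_masked: np.ndarray, X: np.ndarray, lambda_l1: float = 0.0
) -> float:
    """Neighborhood loss evaluated at the symmetrized ``gamma' + gamma'.T``.

    The penalty is taken on ``gamma'`` itself, mirroring the training
    objective.
    """
    X = np.asarray(X, dtype=float)
    _check_shapes(np.asarray(gamma_masked), X)
    g = _as_stack(gamma_masked, X.shape[0])
    theta = g + np.swapaxes(g, -1, -2)
    resid = X - np.einsum("ni,nij->nj", X, theta)
    return float(np.mean(resid**2)) + _l1_penalty(np.asarray(gamma_masked), lambda_l1)


def correlation_loss(theta: np.ndarray, X: np.ndarray) -> float:
    """Mean squared residual over all ordered gene pairs.

    For pair (i, j), gene j is predicted from gene i alone with coefficient
    ``theta[i, j]``; the diagonal self-regression is included (zero residual
    at ``theta[i, i] = 1``). Reduction: mean over n * p * p terms.
    """
    X = np.asarray(X, dtype=float)
    _check_shapes(np.asarray(theta), X)
    th = _as_stack(theta, X.shape[0])
    # resid[n, i, j] = X[n, j] - X[n, i] * theta[n, i, j]
    resid = X[:, None, :] - X[:, :, None] * th
    return float(np.mean(resid**2))


def loss_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    network_class: NetworkClass | str,
    lambda_l1: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Class loss and its gradient w.r.t. the (pre-masking) parameter stack.

    ``theta`` is the raw mixed parameter tensor (n, p, p); masking for the
    neighborhood/markov classes is applied internally, and the returned
    gradient is already masked (zero diagonal) for those classes so the
    chain rule through the mask is included. The L1 term contributes its
    subgradient ``lambda * sign`` on off-diagonal entries.
    """
    network_class = NetworkClass.coerce(network_class)
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _check_shapes(theta, X)
    n, p = X.shape
    th = _as_stack(theta, n)

    if network_class is NetworkClass.CORRELATION:
        resid = X[:, None, :] - X[:, :, None] * th
        loss = float(np.mean(resid**2))
        grad = -2.0 / (n * p * p) * X[:, :, None] * resid
        return loss, grad

    mask = 1.0 - np.eye(p)
    thm = th * mask
    if network_class is NetworkClass.MARKOV:
        pred_theta = thm + np.swapaxes(thm, -1, -2)
    else:
        pred_theta = thm
    resid = X - np.einsum("ni,nij->nj", X, pred_theta)
    loss = float(np.mean(resid**2))
    g = -2.0 / (n * p) * np.einsum("ni,nj->nij", X, resid)
    if network_class is NetworkClass.MARKOV:
        g = g + np.swapaxes(g, -1, -2)
    g = g * mask
    if lambda_l1 > 0.0:
        loss += lambda_l1 * float(np.abs(thm).sum()) / n
        g = g + (lambda_l1 / n) * np.sign(thm) * mask
    return loss, g


# ---------------------------------------------------------------------------
# reconstruction maps between parameterizations
# ---------------------------------------------------------------------------

def reconstruct_precision(gamma_masked: np.ndarray) -> np.ndarray:
    """Precision estimate ``Omega = -(gamma' + gamma'.T)`` with unit diagonal.

    Works on a single matrix or an (n, p, p) stack. The result is exactly
    symmetric by construction.
    """
    g = np.asarray(gamma_masked, dtype=float)
    if g.shape[-1] != g.shape[-2]:
        raise ValueError(f"gamma must be square, got {g.shape}")
    omega = -(g + np.swapaxes(g, -1, -2))
    p = g.shape[-1]
    idx = np.arange(p)
    omega[..., idx, idx] = 1.0
    return omega


def partial_correlation(omega: np.ndarray) -> np.ndarray:
    """Partial correlations ``rho_ij = -omega_ij / sqrt(omega_ii omega_jj)``.

    The diagonal of the result is set to 1; the zero pattern of ``omega``
    is preserved. Raises on non-positive diagonal entries.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape[-1] != omega.shape[-2]:
        raise ValueError(f"omega must be square, got {omega.shape}")
    p = omega.shape[-1]
    idx = np.arange(p)
    d = omega[..., idx, idx]
    if np.any(d <= 0):
        raise ValueError("precision matrix diagonal must be strictly positive")
    scale = np.sqrt(d)
    rho = -omega / (scale[..., :, None] * scale[..., None, :])
    rho[..., idx, idx] = 1.0
    return rho


def reconstruct_correlation(
    theta: np.ndarray, signed: bool = False, clip: bool = True
) -> np.ndarray:
    """Squared correlations ``rho2_ij = theta_ij * theta_ji`` (diagonal 1).

    With ``signed=True`` returns ``sign(theta_ij) * sqrt(max(rho2, 0))``
    instead. Values outside [0, 1] arise from an inconsistent fit and are
    clipped (with a warning) unless ``clip=False``.
    """
    th = np.asarray(theta, dtype=float)
    if th.shape[-1] != th.shape[-2]:
        raise ValueError(f"theta must be square, got {th.shape}")
    rho2 = th * np.swapaxes(th, -1, -2)
    p = th.shape[-1]
    idx = np.arange(p)
    if clip and (np.any(rho2 > 1.0 + 1e-12) or np.any(rho2 < -1e-12)):
        warnings.warn(
            "squared-correlation estimates outside [0, 1] were clipped",
            stacklevel=2,
        )
        rho2 = np.clip(rho2, 0.0, 1.0)
    if signed:
        out = np.sign(th) * np.sqrt(np.maximum(rho2, 0.0))
    else:
        out = rho2
    out[..., idx, idx] = 1.0
    return out
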