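"""Context encoder: metadata -> subtype weights -> archetype mixture.

A sample's context vector C (clinical covariates, mutation indicators,
immune fractions, ...) is mapped by a small multilayer perceptron f to a
K-vector of subtype weights Z = f(C); the sample-specific network parameter
matrix is the mixture ``theta = sum_k Z_k A_k`` over K learnable p x p
archetype matrices. Two mixing modes are supported:

* ``linear`` (default): Z unconstrained, theta lies in span(A_1..A_K);
* ``simplex``: Z passed through a softmax, theta is a convex combination.

The encoder is plain NumPy with explicit forward/backward passes; the
training loop lives in :mod:`contextnets.train`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContextSchema",
    "EncoderConfig",
    "ArchetypeSet",
    "SubtypeWeights",
    "ContextEncoder",
    "mix_archetypes",
]

MAX_ARCHETYPES = 256

_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0.0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class SubtypeWeights:
    """Per-sample archetype-mixing weights Z (one row per sample)."""

    values: np.ndarray
    mode: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.mode not in ("linear", "simplex"):
            raise ValueError(f"unknown mixing mode {self.mode!r}")
        if self.mode == "simplex":
            s = self.values.sum(axis=1)
            if np.any(self.values < -1e-9) or np.any(np.abs(s - 1.0) > 1e-6):
                raise ValueError("simplex weights must be nonnegative and sum to 1")


@dataclass
class EncoderConfig:
    """Architecture and initialization choices for the context encoder."""

    K: int = 16
    hidden_widths: tuple[int, ...] = (64, 64)
    activation: str = "relu"
    mode: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be >= 1")
        if not 1 <= self.K <= MAX_ARCHETYPES:
            raise ValueError(f"K must be in [1, {MAX_ARCHETYPES}]")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.mode not in ("linear", "simplex"):
            raise ValueError(f"unknown mixing mode {self.mode!r}")


class ArchetypeSet:
    """K learnable p x p matrices whose mixtures contain every emitted network."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[1] != values.shape[2]:
            raise ValueError(f"expected (K, p, p) tensor, got {values.shape}")
        if values.shape[0] > MAX_ARCHETYPES:
            raise ValueError(f"K exceeds the configured maximum {MAX_ARCHETYPES}")
        self.values = values

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def init_random(cls, K: int, p: int, rng: np.random.Generator, scale: float = 1e-2):
        """Near-zero random init so initial networks are approximately zero."""
        return cls(rng.normal(0.0, scale, size=(K, p, p)))


def mix_archetypes(Z: np.ndarray | SubtypeWeights, A: ArchetypeSet) -> np.ndarray:
    """Weighted sum of archetypes: ``theta_n = sum_k Z[n, k] A_k``.

    Accepts a single K-vector (returns p x p) or an (n, K) matrix
    (returns n x p x p). Linear in both arguments.
    """
    if isinstance(Z, SubtypeWeights):
        Z = Z.values
    Z = np.asarray(Z, dtype=float)
    single = Z.ndim == 1
    Z2 = np.atleast_2d(Z)
    if Z2.shape[1] != A.K:
        raise ValueError(f"Z has {Z2.shape[1]} weights but archetype set has K={A.K}")
    theta = np.einsum("nk,kij->nij", Z2, A.values)
    return theta[0] if single else theta


class ContextEncoder:
    """MLP mapping encoded context vectors to K subtype weights.

    Parameters are stored as a flat list of (W, b) layer tuples; `forward`
    caches pre-activations so `backward` can push the loss gradient on Z
    down to every weight.
    """

    def __init__(self, d_in: int, config: EncoderConfig):
        self.config = config
        self.d_in = int(d_in)
        rng = np.random.default_rng(config.seed)
        widths = [self.d_in, *config.hidden_widths, config.K]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(len(widths) - 1):
            fan_in = widths[i]
            # He-style init for hidden layers; small final layer so that
            # initial subtype weights (and hence networks) start near zero
            scale = np.sqrt(2.0 / fan_in) if i < len(widths) - 2 else 0.01
            self.weights.append(rng.normal(0.0, scale, size=(widths[i], widths[i + 1])))
            self.biases.append(np.zeros(widths[i + 1]))
        self._cache: list[np.ndarray] | None = None

    # -- forward / backward -------------------------------------------------
    def forward(self, C: np.ndarray, cache: bool = False) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        single = C.ndim == 1
        H = np.atleast_2d(C)
        if H.shape[1] != self.d_in:
            raise ValueError(f"context has {H.shape[1]} features, encoder expects {self.d_in}")
        if not np.all(np.isfinite(H)):
            raise ValueError("context contains non-finite values")
        act, _ = _ACTIVATIONS[self.config.activation]
        pre_acts = []
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            Hpre = H @ W + b
            pre_acts.append((H, Hpre))
            H = act(Hpre) if i < len(self.weights) - 1 else Hpre
        if self.config.mode == "simplex":
            # stable softmax over the K outputs
            e = np.exp(H - H.max(axis=1, keepdims=True))
            H = e / e.sum(axis=1, keepdims=True)
        if cache:
            self._cache = pre_acts
        return H[0] if single else H

    def encode(self, C: np.ndarray) -> SubtypeWeights:
        return SubtypeWeights(self.forward(C), mode=self.config.mode)

    def backward(self, dZ: np.ndarray, Z: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of the loss w.r.t. every weight/bias given dL/dZ."""
        if self._cache is None:
            raise RuntimeError("forward(cache=True) must be called before backward")
        if self.config.mode == "simplex":
            # softmax Jacobian: dpre = Z * (dZ - sum(dZ * Z))
            dot = np.sum(dZ * Z, axis=1, keepdims=True)
            delta = Z * (dZ - dot)
        else:
            delta = dZ
        _, dact = _ACTIVATIONS[self.config.activation]
        dWs = [np.empty(0)] * len(self.weights)
        dbs = [np.empty(0)] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            H_in, H_pre = self._cache[i]
            dWs[i] = H_in.T @ delta
            dbs[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * dact(self._cache[i - 1][1])
        return dWs, dbs

    # -- parameter plumbing --------------------------------------------------
    def get_params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def set_params(self, params: list[np.ndarray]) -> None:
        nw = len(self.weights)
        self.weights = [np.asarray(p, dtype=float) for p in params[:nw]]
        self.biases = [np.asarray(p, dtype=float) for p in params[nw:]]


# ---------------------------------------------------------------------------
# context feature encoding
# ---------------------------------------------------------------------------

@dataclass
class ContextSchema:
    """Fixed fit-time encoding of raw context features.

    Continuous columns are z-scored with training-split statistics (missing
    values mean-imputed with a companion missingness-indicator column);
    categorical columns are one-hot encoded with an explicit NA level. The
    schema is frozen at fit time and reapplied verbatim at predict time.
    """

    continuous: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    categorical: dict[str, list] = field(default_factory=dict)
    column_order: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, context: "pd.DataFrame | np.ndarray") -> "ContextSchema":
        df = _to_frame(context)
        schema = cls(column_order=list(df.columns))
        for col in df.columns:
            s = df[col]
            if pd.api.types.is_numeric_dtype(s):
                vals = s.to_numpy(dtype=float)
                finite = vals[np.isfinite(vals)]
                mu = float(finite.mean()) if finite.size else 0.0
                sd = float(finite.std())
                sd = sd if sd > 0 else 1.0
                has_na = bool(np.any(~np.isfinite(vals)))
                schema.continuous[col] = (mu, sd, has_na)
                schema.feature_ids.append(str(col))
                if has_na:
                    schema.feature_ids.append(f"{col}__missing")
            else:
                levels = sorted(s.dropna().astype(str).unique().tolist())
                if s.isna().any():
                    levels.append("__NA__")
                schema.categorical[col] = levels
                schema.feature_ids.extend(f"{col}={lv}" for lv in levels)
        return schema

    def transform(self, context: "pd.DataFrame | np.ndarray") -> np.ndarray:
        df = _to_frame(context)
        missing = [c for c in self.column_order if c not in df.columns]
        if missing:
            raise ValueError(f"context is missing fit-time features: {missing}")
        cols: list[np.ndarray] = []
        for col in self.column_order:
            if col in self.continuous:
                mu, sd, has_na = self.continuous[col]
                vals = df[col].to_numpy(dtype=float)
                na = ~np.isfinite(vals)
                if na.any() and not has_na:
                    raise ValueError(
                        f"context feature {col!r} has missing values but had "
                        "none when the schema was fitted"
                    )
                vals = np.where(na, mu, vals)
                cols.append((vals - mu) / sd)
                if has_na:
                    cols.append(na.astype(float))
            else:
                levels = self.categorical[col]
                raw = df[col].astype(object)
                labels = np.where(raw.isna(), "__NA__", raw.astype(str))
                for lv in levels:
                    cols.append((labels == lv).astype(float))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    @property
    def width(self) -> int:
        return len(self.feature_ids)

    def to_dict(self) -> dict:
        return {
            "continuous": {k: list(v) for k, v in self.continuous.items()},
            "categorical": {str(k): v for k, v in self.categorical.items()},
            "column_order": [str(c) for c in self.column_order],
            "feature_ids": self.feature_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContextSchema":
        return cls(
            continuous={k: tuple(v) for k, v in d["continuous"].items()},
            categorical=dict(d["categorical"]),
            column_order=list(d["column_order"]),
            feature_ids=list(d["feature_ids"]),
        )


def _to_frame(context) -> pd.DataFrame:
    if isinstance(context, pd.DataFrame):
        return context
    arr = np.asarray(context)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
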