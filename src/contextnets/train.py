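"""End-to-end fitting of the context encoder and archetypes.

The objective is the class-specific network loss summed over training
samples; encoder weights and archetype matrices are learned jointly with
Adam (the whole map context -> Z -> theta is differentiable, and the loss
is quadratic in theta, so all gradients are analytic and the backward pass
is written out explicitly in NumPy).

Seed plumbing: one master seed (``FitConfig.seed``) derives all randomness
through ``np.random.SeedSequence([seed, role])`` with documented roles:
0 = train/validation split, 1 = encoder init, 2 = archetype init,
3 = minibatch shuffling, 100+b = bootstrap resample b.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .encoder import ArchetypeSet, ContextEncoder, ContextSchema, EncoderConfig, mix_archetypes
from .networks import (
    MASKED_CLASSES,
    NetworkClass,
    SampleNetworks,
    loss_and_grad,
    mask_diagonal,
)

__all__ = [
    "FitConfig",
    "ContextualizedNetworks",
    "BootstrapEnsemble",
    "bootstrap_fit",
]


@dataclass
class FitConfig:
    """Hyperparameters for a single contextualized-network fit."""

    network_class: NetworkClass | str = NetworkClass.MARKOV
    K: int = 16
    lambda_l1: float = 1e-3
    learning_rate: float = 1e-2
    max_epochs: int = 500
    early_stop_patience: int = 25
    batch_size: int = 256
    val_fraction: float = 0.2
    hidden_widths: tuple[int, ...] = (64, 64)
    activation: str = "relu"
    mode: str = "linear"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.network_class = NetworkClass.coerce(self.network_class)
        if not 0.0 <= self.val_fraction <= 0.5:
            raise ValueError("val_fraction must lie in [0, 0.5]")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be positive")


def _role_rng(seed: int, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(role)]))


def _role_int(seed: int, role: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(role)]).generate_state(1)[0] % (2**31))


class _Adam:
    """Minimal Adam over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


class ContextualizedNetworks:
    """A fitted (or initialized) contextualized network model.

    Use :meth:`fit` then :meth:`predict_networks`; the model can be saved
    to a single-file bundle and reloaded bit-for-bit.
    """

    def __init__(self, config: FitConfig):
        self.config = config
        self.schema: ContextSchema | None = None
        self.encoder: ContextEncoder | None = None
        self.archetypes: ArchetypeSet | None = None
        self.gene_ids: list[str] = []
        self.expr_mean: np.ndarray | None = None
        self.expr_std: np.ndarray | None = None
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- data plumbing -------------------------------------------------------
    def standardize(self, X) -> np.ndarray:
        """Apply the train-split per-gene z-scoring to an expression matrix."""
        X = np.asarray(X, dtype=float)
        if self.expr_mean is None:
            return X
        return (X - self.expr_mean) / self.expr_std

    def encode_context(self, contexts) -> np.ndarray:
        if self.schema is None:
            raise RuntimeError("model is not fitted")
        return self.schema.transform(_context_frame(contexts))

    # -- fitting -------------------------------------------------------------
    def fit(self, contexts, expression, log_file=None) -> "ContextualizedNetworks":
        cfg = self.config
        Cdf = _context_frame(contexts)
        X = np.asarray(expression, dtype=float)
        if isinstance(expression, pd.DataFrame):
            self.gene_ids = [str(c) for c in expression.columns]
        else:
            self.gene_ids = [f"g{i}" for i in range(X.shape[1])]
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if len(Cdf) != n:
            raise ValueError(f"contexts have {len(Cdf)} rows but expression has {n}")

        # train/validation split (role 0)
        idx = _role_rng(cfg.seed, 0).permutation(n)
        n_val = int(round(cfg.val_fraction * n))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        Xtr, Xval = X[tr_idx], X[val_idx]
        Ctr_df, Cval_df = Cdf.iloc[tr_idx], Cdf.iloc[val_idx]

        if cfg.standardize:
            self.expr_mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            self.expr_std = np.where(sd > 0, sd, 1.0)
        else:
            self.expr_mean = np.zeros(p)
            self.expr_std = np.ones(p)
        Xtr = self.standardize(Xtr)
        Xval = self.standardize(Xval)

        # context schema frozen on the training split only
        self.schema = ContextSchema.fit(Ctr_df)
        Ctr = self.schema.transform(Ctr_df)
        Cval = self.schema.transform(Cval_df)

        enc_cfg = EncoderConfig(
            K=cfg.K,
            hidden_widths=cfg.hidden_widths,
            activation=cfg.activation,
            mode=cfg.mode,
            seed=_role_int(cfg.seed, 1),
        )
        self.encoder = ContextEncoder(max(self.schema.width, 1), enc_cfg)
        self.archetypes = ArchetypeSet.init_random(cfg.K, p, _role_rng(cfg.seed, 2))
        self._const_context = self.schema.width == 0
        if self._const_context:  # empty context collapses to a single zero feature
            Ctr = np.zeros((len(Xtr), 1))
            Cval = np.zeros((len(Xval), 1))

        params = [*self.encoder.get_params(), self.archetypes.values]
        opt = _Adam(params, cfg.learning_rate)
        shuffle_rng = _role_rng(cfg.seed, 3)
        full_batch = len(Xtr) <= 1024 or cfg.batch_size >= len(Xtr)

        best_val = np.inf
        best_params = [q.copy() for q in params]
        patience = 0
        self.history = {"train_loss": [], "val_loss": []}

        for epoch in range(cfg.max_epochs):
            if full_batch:
                batches = [np.arange(len(Xtr))]
            else:
                order = shuffle_rng.permutation(len(Xtr))
                batches = np.array_split(order, int(np.ceil(len(Xtr) / cfg.batch_size)))
            epoch_loss = 0.0
            for b in batches:
                loss, grads = self._loss_grads(params, Ctr[b], Xtr[b])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate or check the inputs"
                    )
                params = opt.step(params, grads)
                epoch_loss += loss * len(b)
            epoch_loss /= len(Xtr)
            self._set_params(params)
            if len(Xval):
                val_loss = self._eval_loss(Cval, Xval)
            else:
                val_loss = epoch_loss
            self.history["train_loss"].append(epoch_loss)
            self.history["val_loss"].append(float(val_loss))
            if log_file is not None:
                log_file.write(f"epoch={epoch}\ttrain_loss={epoch_loss:.6g}\tval_loss={val_loss:.6g}\n")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = [q.copy() for q in params]
                patience = 0
            else:
                patience += 1
                if patience >= cfg.early_stop_patience:
                    break
        self._set_params(best_params)
        return self

    def _loss_grads(self, params, C, X):
        self._set_params(params)
        Z = self.encoder.forward(C, cache=True)
        theta = mix_archetypes(Z, self.archetypes)
        loss, g_theta = loss_and_grad(theta, X, self.config.network_class, self.config.lambda_l1)
        dA = np.einsum("nk,nij->kij", Z, g_theta)
        dZ = np.einsum("nij,kij->nk", g_theta, self.archetypes.values)
        dWs, dbs = self.encoder.backward(dZ, np.atleast_2d(Z))
        return loss, [*dWs, *dbs, dA]

    def _set_params(self, params: list[np.ndarray]) -> None:
        self.encoder.set_params(params[:-1])
        self.archetypes = ArchetypeSet(params[-1])

    def _eval_loss(self, C_enc: np.ndarray, X_std: np.ndarray) -> float:
        """Penalty-free loss on already-encoded/standardized rows."""
        Z = self.encoder.forward(C_enc)
        theta = mix_archetypes(np.atleast_2d(Z), self.archetypes)
        loss, _ = loss_and_grad(theta, X_std, self.config.network_class, 0.0)
        return loss

    # -- prediction ----------------------------------------------------------
    def predict_subtype_weights(self, contexts) -> np.ndarray:
        C = self._encode_for_predict(contexts)
        return np.atleast_2d(self.encoder.forward(C))

    def predict_networks(self, contexts, sample_ids=None) -> SampleNetworks:
        """One network per context row; unseen contexts are handled zero-shot."""
        Z = self.predict_subtype_weights(contexts)
        theta = mix_archetypes(Z, self.archetypes)
        if self.config.network_class in MASKED_CLASSES:
            theta = mask_diagonal(theta)
        return SampleNetworks(
            theta,
            self.config.network_class,
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids) if sample_ids is not None else [],
        )

    def _encode_for_predict(self, contexts) -> np.ndarray:
        if self.schema is None:
            raise RuntimeError("model is not fitted")
        C = self.schema.transform(_context_frame(contexts))
        if self._const_context:
            C = np.zeros((C.shape[0], 1))
        return C

    def measure_mse(self, contexts, expression) -> np.ndarray:
        """Per-sample penalty-free expression MSE under this model's networks."""
        from .evaluate import expression_mse

        nets = self.predict_networks(contexts)
        return expression_mse(nets, self.standardize(expression))

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["network_class"] = self.config.network_class.value
        meta = {
            "format_version": 1,
            "config": cfg,
            "schema": self.schema.to_dict() if self.schema else None,
            "gene_ids": self.gene_ids,
            "const_context": bool(getattr(self, "_const_context", False)),
            "history": self.history,
        }
        arrays = {"archetypes": self.archetypes.values,
                  "expr_mean": self.expr_mean, "expr_std": self.expr_std}
        for i, W in enumerate(self.encoder.weights):
            arrays[f"W{i}"] = W
        for i, b in enumerate(self.encoder.biases):
            arrays[f"b{i}"] = b
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr(zipfile.ZipInfo("meta.json"), json.dumps(meta, sort_keys=True))
            zf.writestr(zipfile.ZipInfo("arrays.npz"), buf.getvalue())

    @classmethod
    def load(cls, path) -> "ContextualizedNetworks":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("arrays.npz"))) as npz:
                arrays = {k: npz[k] for k in npz.files}
        cfgd = meta["config"]
        cfgd["hidden_widths"] = tuple(cfgd["hidden_widths"])
        model = cls(FitConfig(**cfgd))
        model.schema = ContextSchema.from_dict(meta["schema"]) if meta["schema"] else None
        model.gene_ids = list(meta["gene_ids"])
        model._const_context = bool(meta["const_context"])
        model.history = meta["history"]
        model.expr_mean = arrays["expr_mean"]
        model.expr_std = arrays["expr_std"]
        model.archetypes = ArchetypeSet(arrays["archetypes"])
        d_in = arrays["W0"].shape[0]
        enc_cfg = EncoderConfig(
            K=model.config.K,
            hidden_widths=model.config.hidden_widths,
            activation=model.config.activation,
            mode=model.config.mode,
            seed=_role_int(model.config.seed, 1),
        )
        model.encoder = ContextEncoder(d_in, enc_cfg)
        nw = sum(1 for k in arrays if k.startswith("W"))
        model.encoder.set_params(
            [arrays[f"W{i}"] for i in range(nw)] + [arrays[f"b{i}"] for i in range(nw)]
        )
        return model


# ---------------------------------------------------------------------------
# bootstrap ensembling
# ---------------------------------------------------------------------------

@dataclass
class BootstrapEnsemble:
    """B independently initialized fits on with-replacement resamples.

    Predictions are the entrywise mean of member networks; the spread
    across members gives the per-edge SD used as a confidence band.
    """

    members: list[ContextualizedNetworks]
    config: FitConfig

    @property
    def B(self) -> int:
        return len(self.members)

    def predict_networks(self, contexts) -> SampleNetworks:
        stack = np.stack([m.predict_networks(contexts).values for m in self.members])
        first = self.members[0]
        return SampleNetworks(
            stack.mean(axis=0), self.config.network_class, gene_ids=list(first.gene_ids)
        )

    def predict_sd(self, contexts) -> np.ndarray:
        stack = np.stack([m.predict_networks(contexts).values for m in self.members])
        return stack.std(axis=0)

    def member_mses(self, contexts, expression) -> list[float]:
        return [float(np.mean(m.measure_mse(contexts, expression))) for m in self.members]

    def measure_mse(self, contexts, expression) -> np.ndarray:
        """Per-sample MSE of the bootstrap-averaged networks."""
        from .evaluate import expression_mse

        nets = self.predict_networks(contexts)
        return expression_mse(nets, self.members[0].standardize(expression))


def bootstrap_fit(contexts, expression, config: FitConfig, B: int) -> BootstrapEnsemble:
    """Fit ``B`` members on bootstrap resamples with seeds ``seed + b``."""
    if B < 1:
        raise ValueError("B must be >= 1")
    Cdf = _context_frame(contexts)
    X = np.asarray(expression, dtype=float)
    n = len(Cdf)
    members: list[ContextualizedNetworks] = []
    for b in range(B):
        rows = np.arange(n) if B == 1 else _role_rng(config.seed, 100 + b).integers(0, n, size=n)
        cfg_b = FitConfig(**{**asdict(config), "network_class": config.network_class,
                             "seed": config.seed + b})
        try:
            m = ContextualizedNetworks(cfg_b).fit(Cdf.iloc[rows], X[rows])
            members.append(m)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"bootstrap member {b} failed: {exc}")
    if len(members) < max(1, B // 2):
        raise RuntimeError(f"only {len(members)}/{B} bootstrap members succeeded")
    return BootstrapEnsemble(members, config)


def _context_frame(contexts) -> pd.DataFrame:
    if isinstance(contexts, pd.DataFrame):
        return contexts
    arr = np.asarray(contexts)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
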