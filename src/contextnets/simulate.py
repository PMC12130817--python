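"""Context-varying Gaussian benchmark and the scaling-grid experiment.

The generative model draws a scalar context ``C ~ Unif[-1, 1]`` and a
2-gene observation ``X ~ N(0, [[1, C], [C, 1]])``, so the ground-truth
precision matrix at context C is ``(1 / (1 - C^2)) [[1, -C], [-C, 1]]``.
Sweeping the number of distinct contexts ("horizontal" scaling) against
the number of replicates per context ("vertical" scaling) contrasts the
contextualized estimator with population and per-context grouped fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import NetworkClass, reconstruct_precision

__all__ = [
    "ContextVaryingGaussianSpec",
    "ScalingGridResult",
    "sample_dataset",
    "true_precision",
    "unit_diagonal_normalize",
    "parameter_mse",
    "run_scaling_grid",
    "default_estimators",
]


@dataclass
class ContextVaryingGaussianSpec:
    n_contexts: int = 100
    samples_per_context: int = 1
    context_low: float = -1.0
    context_high: float = 1.0
    context_eps: float = 0.01  # keeps Sigma(C) well-conditioned
    seed: int = 0


def sample_dataset(
    spec: ContextVaryingGaussianSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the benchmark dataset.

    Returns ``(contexts, expression, true_precisions)`` with
    ``n = n_contexts * samples_per_context`` rows; rows within a context are
    i.i.d. draws from ``N(0, Sigma(C))``. Contexts beyond the positive-
    definiteness guard ``|C| <= 1 - eps`` are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    bound = 1.0 - spec.context_eps
    ctx = rng.uniform(spec.context_low, spec.context_high, size=spec.n_contexts)
    bad = np.abs(ctx) > bound
    while np.any(bad):
        ctx[bad] = rng.uniform(spec.context_low, spec.context_high, size=bad.sum())
        bad = np.abs(ctx) > bound
    contexts = np.repeat(ctx, spec.samples_per_context)[:, None]
    n = contexts.shape[0]
    # X = L z with L the Cholesky factor of [[1, C], [C, 1]]
    z = rng.standard_normal((n, 2))
    c = contexts[:, 0]
    x1 = z[:, 0]
    x2 = c * z[:, 0] + np.sqrt(1.0 - c**2) * z[:, 1]
    X = np.column_stack([x1, x2])
    truths = np.stack([true_precision(ci) for ci in c])
    return contexts, X, truths


def true_precision(C: float) -> np.ndarray:
    """Closed-form inverse of ``[[1, C], [C, 1]]``."""
    C = float(C)
    if abs(C) >= 1.0:
        raise ValueError(f"|C| must be < 1, got {C}")
    scale = 1.0 / (1.0 - C**2)
    return scale * np.array([[1.0, -C], [-C, 1.0]])


def unit_diagonal_normalize(omega: np.ndarray) -> np.ndarray:
    """Rescale ``D^{-1/2} Omega D^{-1/2}`` so the diagonal is exactly 1."""
    omega = np.asarray(omega, dtype=float)
    p = omega.shape[-1]
    idx = np.arange(p)
    d = omega[..., idx, idx]
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive to normalize")
    s = 1.0 / np.sqrt(d)
    return omega * s[..., :, None] * s[..., None, :]


def parameter_mse(
    estimated: np.ndarray, truth: np.ndarray, normalize: bool = True
) -> float:
    """Mean squared entrywise error between precision stacks.

    By default both sides are rescaled to a unit diagonal first, so the
    comparison is on the partial-correlation scale and independent of each
    side's diagonal convention.
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError(f"shape mismatch: {estimated.shape} vs {truth.shape}")
    if normalize:
        estimated = unit_diagonal_normalize(estimated)
        truth = unit_diagonal_normalize(truth)
    return float(np.mean((estimated - truth) ** 2))


# ---------------------------------------------------------------------------
# estimator registry for the grid
# ---------------------------------------------------------------------------

def _population_estimator(contexts, X, seed):
    from .baselines import GroupingScheme, fit_grouped

    m = fit_grouped(contexts, X, GroupingScheme("population"),
                    NetworkClass.MARKOV, seed=seed)
    return reconstruct_precision(m.predict_networks(contexts).values)


def _grouped_estimator(contexts, X, seed):
    """One Markov network per distinct context value."""
    from .baselines import GroupingScheme, fit_grouped

    labels = np.asarray(contexts).reshape(len(X), -1)[:, 0]
    m = fit_grouped(contexts, X, GroupingScheme("labels", labels=labels),
                    NetworkClass.MARKOV, seed=seed)
    return reconstruct_precision(m.predict_networks(labels=labels).values)


def make_contextualized_estimator(**overrides):
    """Build a grid estimator running the full contextualized fit."""
    from .train import ContextualizedNetworks, FitConfig

    def _estimator(contexts, X, seed):
        cfg = FitConfig(network_class=NetworkClass.MARKOV,
                        K=overrides.get("K", 4),
                        hidden_widths=overrides.get("hidden_widths", (32,)),
                        lambda_l1=overrides.get("lambda_l1", 0.0),
                        max_epochs=overrides.get("max_epochs", 300),
                        learning_rate=overrides.get("learning_rate", 1e-2),
                        early_stop_patience=overrides.get("early_stop_patience", 20),
                        seed=seed)
        model = ContextualizedNetworks(cfg).fit(contexts, X)
        return reconstruct_precision(model.predict_networks(contexts).values)

    return _estimator


def default_estimators() -> dict:
    return {
        "population": _population_estimator,
        "grouped": _grouped_estimator,
        "contextualized": make_contextualized_estimator(),
    }


@dataclass
class ScalingGridResult:
    """Long-format parameter-MSE table over the scaling grid."""

    table: pd.DataFrame
    replicates: int = 5

    def mean_table(self) -> pd.DataFrame:
        return (
            self.table.groupby(["estimator", "n_contexts", "samples_per_context"])[
                "parameter_mse"
            ]
            .mean()
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot_contours(self, path) -> None:  # pragma: no cover - optional output
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mt = self.mean_table()
        estimators = mt["estimator"].unique()
        fig, axes = plt.subplots(1, len(estimators), figsize=(4 * len(estimators), 3.2))
        for ax, est in zip(np.atleast_1d(axes), estimators):
            sub = mt[mt["estimator"] == est].pivot(
                index="samples_per_context", columns="n_contexts", values="parameter_mse"
            )
            im = ax.imshow(np.log10(sub.values), origin="lower", aspect="auto")
            ax.set_xticks(range(len(sub.columns)), sub.columns)
            ax.set_yticks(range(len(sub.index)), sub.index)
            ax.set_xlabel("contexts")
            ax.set_ylabel("samples per context")
            ax.set_title(est)
            fig.colorbar(im, ax=ax, label="log10 parameter MSE")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def run_scaling_grid(
    n_contexts_list=(1, 10, 100, 1000),
    samples_per_context_list=(1, 10, 100),
    estimators: dict | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> ScalingGridResult:
    """Evaluate every estimator on every (contexts, samples/context) cell.

    Each cell/replicate gets its own derived seed; failures are recorded as
    missing (NaN) and the sweep continues.
    """
    if estimators is None:
        estimators = default_estimators()
    rows = []
    for ci, n_contexts in enumerate(n_contexts_list):
        for si, spc in enumerate(samples_per_context_list):
            for rep in range(replicates):
                cell_seed = int(
                    np.random.SeedSequence([seed, ci, si, rep]).generate_state(1)[0]
                    % (2**31)
                )
                spec = ContextVaryingGaussianSpec(
                    n_contexts=n_contexts, samples_per_context=spc, seed=cell_seed
                )
                contexts, X, truths = sample_dataset(spec)
                for name, fn in estimators.items():
                    try:
                        est = fn(contexts, X, cell_seed)
                        mse = parameter_mse(est, truths)
                    except Exception:
                        mse = np.nan
                    rows.append(
                        dict(
                            estimator=name,
                            n_contexts=n_contexts,
                            samples_per_context=spc,
                            replicate=rep,
                            parameter_mse=mse,
                        )
                    )
    return ScalingGridResult(pd.DataFrame(rows), replicates=replicates)
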