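"""Synthetic cohorts exercising the full pipeline without any downloads.

Two generators cover every test surface:

* the 2-gene context-varying Gaussian (re-exported from
  :mod:`contextnets.simulate`) for parameter-recovery experiments;
* a *planted cohort*: subtypes sit at distinct points along a latent axis,
  each subtype's precision matrix is a point on a linear archetype path
  (SPD-repaired), expression is drawn from the implied Gaussian, context
  features carry the latent coordinate (plus pure-noise features), and
  survival times are exponential with subtype-specific hazards under
  independent exponential censoring.

Because the subtype -> network map is linear in the shared latent
coordinate, a contextualized model trained with one subtype held out can
still emit a sensible network for it -- the zero-shot mechanism the
hold-out-group evaluation probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import (  # re-exported benchmark generator  # noqa: F401
    ContextVaryingGaussianSpec,
    sample_dataset,
    true_precision,
)
from .subtype import SurvivalTable

__all__ = [
    "PlantedCohortSpec",
    "PlantedCohort",
    "generate_planted_cohort",
    "ContextVaryingGaussianSpec",
    "sample_dataset",
    "true_precision",
]


@dataclass
class PlantedCohortSpec:
    n_subtypes: int = 3
    p: int = 5
    n_per_subtype: tuple[int, ...] | int = 100
    n_context_features: int = 4
    context_informativeness: float = 1.0  # fraction of informative features
    noise_sd: float = 0.05  # jitter on informative context features
    effect_size: float = 0.8  # largest |off-diagonal| precision entry at |c|=1
    latent_geometry: str = "line"  # line | simplex placement of subtype centers
    centers: tuple[float, ...] | None = None  # explicit line coordinates
    hazard_rates: tuple[float, ...] | None = None  # default: 4x ratio ladder
    censoring_fraction: float = 0.2
    max_condition: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_subtype, int):
            self.n_per_subtype = (self.n_per_subtype,) * self.n_subtypes
        if len(self.n_per_subtype) != self.n_subtypes:
            raise ValueError("n_per_subtype must have one entry per subtype")
        if self.hazard_rates is None:
            self.hazard_rates = tuple(2.0 * 0.25**s for s in range(self.n_subtypes))
        if any(r <= 0 for r in self.hazard_rates):
            raise ValueError("hazard rates must be positive")
        if not 0.0 <= self.context_informativeness <= 1.0:
            raise ValueError("context_informativeness must lie in [0, 1]")
        if self.latent_geometry not in ("line", "simplex"):
            raise ValueError(f"unknown latent_geometry {self.latent_geometry!r}")


@dataclass
class PlantedCohort:
    contexts: pd.DataFrame
    expression: np.ndarray
    true_precisions: np.ndarray
    labels: np.ndarray
    survival: SurvivalTable
    subtype_precisions: np.ndarray
    subtype_centers: np.ndarray
    informative_features: list[str] = field(default_factory=list)


def _spd_repair(A: np.ndarray, max_condition: float) -> np.ndarray:
    """Symmetrize and diagonally load to condition number <= max_condition."""
    S = 0.5 * (A + A.T)
    lam = np.linalg.eigvalsh(S)
    lo, hi = lam[0], lam[-1]
    if hi <= 0:
        S = S + (1e-2 - lo) * np.eye(len(S))
        lam = np.linalg.eigvalsh(S)
        lo, hi = lam[0], lam[-1]
    if lo <= 0 or hi / lo > max_condition:
        delta = (hi - max_condition * lo) / (max_condition - 1.0)
        S = S + delta * np.eye(len(S))
        warnings.warn(f"planted precision diagonally loaded by {delta:.3g} for SPD")
    return S


def generate_planted_cohort(spec: PlantedCohortSpec) -> PlantedCohort:
    """Draw a full synthetic cohort; see the module docstring for the design."""
    rng = np.random.default_rng(spec.seed)
    p, S = spec.p, spec.n_subtypes
    # linear archetype path: Omega(c) = I + sum_d c_d * D_d, SPD-repaired;
    # directions are rescaled so the planted contrast is seed-independent.
    # "line" places subtype centers on a shared 1-D axis (interpolable,
    # suited to hold-out experiments); "simplex" puts them at equidistant
    # corners of a centered simplex (well-separated clusters).
    if spec.latent_geometry == "line":
        latent_dim = 1
        if spec.centers is not None:
            if len(spec.centers) != S:
                raise ValueError("centers must have one coordinate per subtype")
            centers = np.asarray(spec.centers, dtype=float)[:, None]
        else:
            centers = (np.linspace(-0.8, 0.8, S) if S > 1 else np.zeros(1))[:, None]
    else:
        latent_dim = max(S, 2)
        centers = 0.8 * (np.eye(S, latent_dim) - 1.0 / S)
    directions = []
    for _ in range(latent_dim):
        D = rng.normal(size=(p, p))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        directions.append(D * spec.effect_size / np.abs(D).max())
    directions = np.stack(directions)
    subtype_precisions = np.stack([
        _spd_repair(np.eye(p) + np.einsum("d,dij->ij", centers[s], directions),
                    spec.max_condition)
        for s in range(S)
    ])

    keep = [s for s in range(S) if spec.n_per_subtype[s] > 0]
    for s in range(S):
        if spec.n_per_subtype[s] == 0:
            warnings.warn(f"subtype {s} has n=0 and is omitted")

    labels, X_rows, truth_rows = [], [], []
    for s in keep:
        n_s = spec.n_per_subtype[s]
        cov = np.linalg.inv(subtype_precisions[s])
        L = np.linalg.cholesky(cov)
        X_rows.append(rng.standard_normal((n_s, p)) @ L.T)
        truth_rows.append(np.broadcast_to(subtype_precisions[s], (n_s, p, p)))
        labels.extend([s] * n_s)
    labels = np.asarray(labels)
    X = np.vstack(X_rows)
    truths = np.concatenate(truth_rows)
    n = len(labels)

    d = spec.n_context_features
    n_inf = int(round(spec.context_informativeness * d))
    cols = {}
    informative = []
    for j in range(d):
        if j < n_inf:
            name = f"ctx_signal_{j}"
            cols[name] = (
                centers[labels, j % latent_dim]
                + spec.noise_sd * rng.standard_normal(n)
            )
            informative.append(name)
        else:
            cols[f"ctx_noise_{j - n_inf}"] = rng.standard_normal(n)
    contexts = pd.DataFrame(cols)

    rates = np.array([spec.hazard_rates[s] for s in labels])
    event_times = rng.exponential(1.0 / rates)
    if spec.censoring_fraction > 0:
        # exponential censoring with rate c = f/(1-f) * hazard keeps the
        # censored fraction at f within every subtype
        cens_rates = rates * spec.censoring_fraction / (1.0 - spec.censoring_fraction)
        cens_times = rng.exponential(1.0 / cens_rates)
        time = np.minimum(event_times, cens_times)
        event = (event_times <= cens_times).astype(int)
    else:
        time, event = event_times, np.ones(n, dtype=int)
    survival = SurvivalTable(time=time, event=event,
                             sample_id=np.array([f"s{i}" for i in range(n)]))

    return PlantedCohort(
        contexts=contexts,
        expression=X,
        true_precisions=truths,
        labels=labels,
        survival=survival,
        subtype_precisions=subtype_precisions,
        subtype_centers=centers,
        informative_features=informative,
    )
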