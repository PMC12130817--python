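"""Readers/writers and expression preprocessing.

Expression matrices are delimited text with a header row of gene ids and a
first column of sample ids. Preprocessing follows the standard recipe for
bulk TPM panels: ``log(x + 1e-3)`` (natural log by default, configurable)
followed by compression into *metagenes* -- principal components fitted on
the training split only and applied identically to every split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .networks import MASKED_CLASSES, SampleNetworks

__all__ = [
    "log_transform",
    "MetagenePCAState",
    "fit_metagenes",
    "apply_metagenes",
    "inverse_metagenes",
    "load_matrix",
    "write_matrix",
    "write_networks",
    "load_networks_long",
    "load_survival",
]


def log_transform(X, pseudocount: float = 1e-3, base: float | None = None):
    """Elementwise ``log(x + pseudocount)``; natural log unless a base is given.

    Negative entries are rejected (TPM-style inputs are nonnegative), and
    the offending cell is named in the error.
    """
    arr = np.asarray(X, dtype=float)
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative expression value at row {i}, column {j}")
    out = np.log(arr + pseudocount)
    if base is not None:
        out = out / np.log(base)
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


@dataclass
class MetagenePCAState:
    """Frozen PCA projection: loadings, centering, captured variance."""

    components: np.ndarray  # (m, p_original), orthonormal rows
    mean: np.ndarray
    m: int
    variance_captured: float

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_captured <= 1.0 + 1e-9:
            raise ValueError("variance_captured must lie in (0, 1]")


def fit_metagenes(X_train, m: int = 50) -> MetagenePCAState:
    """Fit an m-component PCA on the training rows only."""
    X = np.asarray(X_train, dtype=float)
    if m > min(X.shape):
        raise ValueError(f"m={m} exceeds min(n, p) = {min(X.shape)}")
    pca = PCA(n_components=m, svd_solver="full").fit(X)
    return MetagenePCAState(
        components=pca.components_,
        mean=pca.mean_,
        m=m,
        variance_captured=float(min(pca.explained_variance_ratio_.sum(), 1.0)),
    )


def apply_metagenes(state: MetagenePCAState, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - state.mean) @ state.components.T


def inverse_metagenes(state: MetagenePCAState, scores: np.ndarray) -> np.ndarray:
    return np.asarray(scores, dtype=float) @ state.components + state.mean


# ---------------------------------------------------------------------------
# delimited-text matrices
# ---------------------------------------------------------------------------

def load_matrix(path, sep: str = "\t", allow_na: bool = False) -> pd.DataFrame:
    """Load a samples x features table; first column = sample ids.

    Duplicate sample ids and (by default) missing values are errors, and
    ragged rows are rejected by the parser with a line number.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate sample id(s): {dup}")
    if not allow_na and df.select_dtypes(include=[np.number]).isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in column(s): {bad}")
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=True)


def load_survival(path, sep: str = "\t") -> pd.DataFrame:
    """Load a (sample, time, event) table."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("survival table needs sample, time, event columns")
    return df


# ---------------------------------------------------------------------------
# network tensors
# ---------------------------------------------------------------------------

def write_networks(networks: SampleNetworks, path, sep: str = "\t") -> None:
    """Write per-sample networks as long-format text.

    Columns: sample_id, gene_i, gene_j, value, network_class. The diagonal
    is omitted for diagonal-masked classes (neighborhood, markov).
    """
    p = networks.p
    masked = networks.network_class in MASKED_CLASSES
    rows = []
    for s, sid in enumerate(networks.sample_ids):
        for i in range(p):
            for j in range(p):
                if masked and i == j:
                    continue
                rows.append(
                    (sid, networks.gene_ids[i], networks.gene_ids[j],
                     networks.values[s, i, j], networks.network_class.value)
                )
    pd.DataFrame(
        rows, columns=["sample_id", "gene_i", "gene_j", "value", "network_class"]
    ).to_csv(path, sep=sep, index=False)


def load_networks_long(path, sep: str = "\t") -> SampleNetworks:
    df = pd.read_csv(path, sep=sep)
    classes = df["network_class"].unique()
    if len(classes) != 1:
        raise ValueError(f"mixed network classes in file: {classes}")
    sample_ids = list(pd.unique(df["sample_id"]))
    gene_ids = list(pd.unique(pd.concat([df["gene_i"], df["gene_j"]])))
    gidx = {g: i for i, g in enumerate(gene_ids)}
    sidx = {s: i for i, s in enumerate(sample_ids)}
    vals = np.zeros((len(sample_ids), len(gene_ids), len(gene_ids)))
    vals[df["sample_id"].map(sidx), df["gene_i"].map(gidx), df["gene_j"].map(gidx)] = df["value"]
    return SampleNetworks(vals, classes[0], gene_ids=[str(g) for g in gene_ids],
                          sample_ids=[str(s) for s in sample_ids])
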