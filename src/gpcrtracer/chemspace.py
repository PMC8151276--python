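"""Two-dimensional manifold embedding of the MACCS block.

Uses UMAP with a Jaccard metric on the binary structural keys; a neighbor
sweep supports model selection via silhouette on family labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from gpcrtracer.errors import ConfigurationError


@dataclass(frozen=True)
class EmbeddingConfig:
    n_neighbors: int = 50
    n_components: int = 2
    min_dist: float = 0.1
    metric: str = "jaccard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ConfigurationError("n_neighbors must be >= 2")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")


def embed(maccs_matrix, config: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Embed the binary key matrix; returns one coordinate row per compound."""
    import umap  # deferred: heavy import

    X = np.asarray(maccs_matrix, dtype=float)
    if X.shape[0] <= config.n_neighbors:
        raise ConfigurationError(
            f"need more than n_neighbors={config.n_neighbors} rows, got {X.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        reducer = umap.UMAP(
            n_neighbors=config.n_neighbors,
            n_components=config.n_components,
            min_dist=config.min_dist,
            metric=config.metric,
            random_state=config.seed,
        )
        coords = reducer.fit_transform(X)
    return np.asarray(coords)


def neighbor_sweep(
    maccs_matrix, neighbor_values: list[int], seed: int = 0
) -> dict[int, np.ndarray]:
    """One embedding per neighbor setting, sharing the seed."""
    out: dict[int, np.ndarray] = {}
    for n in neighbor_values:
        config = EmbeddingConfig(n_neighbors=int(n), seed=seed)
        out[int(n)] = embed(maccs_matrix, config)
    return out


def cluster_silhouette(coords: np.ndarray, labels) -> float:
    """Mean silhouette of the given labels on embedded coordinates."""
    return float(silhouette_score(np.asarray(coords), np.asarray(labels)))


def coordinates_table(coords: np.ndarray, compound_ids, families) -> pd.DataFrame:
    """CSV-ready table {compound_id, umap1, umap2, family}."""
    coords = np.asarray(coords)
    return pd.DataFrame(
        {
            "compound_id": list(compound_ids),
            "umap1": coords[:, 0],
            "umap2": coords[:, 1],
            "family": list(families),
        }
    )
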