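"""The 2-D sleep landscape: standardize, embed, cluster, validate.

Period feature vectors are z-scored, embedded with UMAP (15 neighbours,
min_dist 0.1, 2 components) and clustered with DBSCAN in embedding space.
DBSCAN noise points are assigned to the nearest cluster centroid so every
period receives a phenotype.  Because DBSCAN's integer labels are arbitrary,
:func:`characterize_clusters` maps each cluster to a semantic high-level
cluster (0-4) through the modal rule-based composition label of its members;
the rule-based classifier is also available directly as a deterministic
fallback that avoids embedding nondeterminism.

Cross-platform bit-identity of UMAP coordinates is not promised; for a fixed
seed on one machine the fit is reproducible, and tests assert partition
agreement rather than coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError
from .periods import PERIOD_FEATURE_NAMES


@dataclass
class UmapParams:
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    # Spectral initialization is nondeterministic on disconnected
    # neighbourhood graphs (threaded eigensolver), and well-separated
    # phenotype islands disconnect the graph by construction; random init
    # keeps seeded fits reproducible without affecting the partition.
    init: str = "random"


@dataclass
class DbscanParams:
    # Not reported in the source analysis; the clusters are widely separated
    # in embedding space so the exact values are not critical.
    eps: float = 0.5
    min_samples: int = 15


@dataclass
class LandscapeModel:
    """Fitted standardization + embedding + clustering of sleep periods."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    kept_columns: np.ndarray  # boolean mask of non-constant columns
    embedding: np.ndarray  # (n, 2)
    raw_labels: np.ndarray  # DBSCAN output, -1 = noise
    cluster_id: np.ndarray  # after noise assignment, all >= 0
    umap_params: UmapParams
    dbscan_params: DbscanParams
    seed: int
    semantic_map: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.cluster_id).size)

    def semantic_labels(self) -> np.ndarray:
        if not self.semantic_map:
            raise DataError("semantic map not set; run characterize_clusters first")
        return np.array([self.semantic_map[int(c)] for c in self.cluster_id])


def standardize(
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns; constant columns are dropped with a warning.

    Returns ``(z, means, sds, kept_mask)`` where ``z`` holds only the kept
    columns.
    """
    x = np.asarray(x, dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    kept = sds > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} all-constant feature column(s)",
            stacklevel=2,
        )
    z = (x[:, kept] - means[kept]) / sds[kept]
    return z, means, sds, kept


def fit_landscape(
    features,
    *,
    umap_params: UmapParams | None = None,
    dbscan_params: DbscanParams | None = None,
    seed: int = 0,
    min_periods: int = 500,
    assign_noise: bool = True,
) -> LandscapeModel:
    """Standardize, embed with UMAP and cluster with DBSCAN.

    ``features`` is an (n, 18) array or a period DataFrame carrying the
    :data:`~sleepscape.periods.PERIOD_FEATURE_NAMES` columns.  Deterministic
    for a fixed ``seed`` (UMAP runs single-threaded when seeded).
    """
    umap_params = umap_params or UmapParams()
    dbscan_params = dbscan_params or DbscanParams()
    if isinstance(features, pd.DataFrame):
        names = tuple(PERIOD_FEATURE_NAMES)
        x = features.loc[:, list(names)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = tuple(f"f{i}" for i in range(x.shape[1]))
    if x.shape[0] < min_periods:
        raise DataError(
            f"{x.shape[0]} periods < minimum {min_periods}; lower min_periods "
            "explicitly for small inputs"
        )

    z, means, sds, kept = standardize(x)

    import umap  # deferred: numba-backed import is slow

    reducer = umap.UMAP(
        n_neighbors=umap_params.n_neighbors,
        min_dist=umap_params.min_dist,
        n_components=umap_params.n_components,
        init=umap_params.init,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism
        warnings.filterwarnings("ignore", category=UserWarning, module="umap")
        embedding = np.asarray(reducer.fit_transform(z), dtype=float)

    from sklearn.cluster import DBSCAN

    raw = DBSCAN(eps=dbscan_params.eps, min_samples=dbscan_params.min_samples).fit_predict(
        embedding
    )
    labels = raw.copy()
    if assign_noise and np.any(labels == -1):
        labels = _assign_noise_to_nearest(embedding, labels)
    return LandscapeModel(
        feature_names=names,
        means=means,
        sds=sds,
        kept_columns=kept,
        embedding=embedding,
        raw_labels=raw,
        cluster_id=labels,
        umap_params=umap_params,
        dbscan_params=dbscan_params,
        seed=seed,
    )


def _assign_noise_to_nearest(embedding: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    cluster_ids = np.unique(labels[labels >= 0])
    if cluster_ids.size == 0:
        raise DataError("DBSCAN labelled every point noise; adjust eps/min_samples")
    centroids = np.stack([embedding[labels == c].mean(axis=0) for c in cluster_ids])
    noise = np.flatnonzero(labels == -1)
    d = np.linalg.norm(embedding[noise, None, :] - centroids[None, :, :], axis=2)
    out[noise] = cluster_ids[np.argmin(d, axis=1)]
    return out


def silhouette_by_cluster(embedding: np.ndarray, labels: np.ndarray) -> pd.Series:
    """Mean silhouette score, (b - a) / max(a, b), per cluster.

    Computed on embedding coordinates with Euclidean distances; requires at
    least two clusters.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DataError("silhouette is undefined for a single cluster")
    from sklearn.metrics import silhouette_samples

    scores = silhouette_samples(np.asarray(embedding, float), labels)
    return pd.Series(scores).groupby(labels).mean().rename("silhouette")


# ---------------------------------------------------------------------------
# rule-based semantic classification


def rule_based_cluster(periods: pd.DataFrame) -> np.ndarray:
    """High-level cluster (0-4) from per-period night composition.

    Precedence: every night short-only -> 4; any short-only night -> 1; any
    long+short night -> 2; any multi-long night -> 3; otherwise 0 (every
    night exactly one long window).  Deterministic alternative to the
    embedding route, and the basis of ground-truth recovery checks.
    """
    labels = np.zeros(len(periods), dtype=np.int64)
    labels[periods["any_multi_long_night"].to_numpy(bool)] = 3
    labels[periods["any_long_short_night"].to_numpy(bool)] = 2
    labels[periods["any_short_only_night"].to_numpy(bool)] = 1
    labels[periods["all_short_only"].to_numpy(bool)] = 4
    return labels


def characterize_clusters(
    labels: np.ndarray,
    periods: pd.DataFrame,
    *,
    on_duplicate: str = "merge",
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Describe each cluster and map it onto the semantic clusters 0-4.

    Per cluster: size, feature means/sds, and the modal rule-based
    composition label of its members, which becomes the semantic identity.
    Several DBSCAN clusters may legitimately share one identity (mixed
    archetypes occupy several embedding islands); ``on_duplicate="merge"``
    (default) accepts that, ``"error"`` raises for manual override.

    Returns ``(summary, semantic_map)``.
    """
    if on_duplicate not in ("merge", "error"):
        raise ConfigError("on_duplicate must be 'merge' or 'error'")
    labels = np.asarray(labels)
    rule = rule_based_cluster(periods)
    feature_cols = [c for c in PERIOD_FEATURE_NAMES if c in periods.columns]
    rows = []
    semantic_map: dict[int, int] = {}
    seen: dict[int, int] = {}
    for c in np.unique(labels):
        members = labels == c
        modal = int(np.bincount(rule[members]).argmax())
        if modal in seen and on_duplicate == "error":
            raise DataError(
                f"clusters {seen[modal]} and {int(c)} share signature {modal}; "
                "override the mapping manually"
            )
        seen.setdefault(modal, int(c))
        semantic_map[int(c)] = modal
        row = {"cluster_id": int(c), "n": int(members.sum()), "semantic_cluster": modal}
        if feature_cols:
            sub = periods.loc[members, feature_cols]
            row.update({f"{col}": sub[col].mean() for col in feature_cols})
        rows.append(row)
    return pd.DataFrame(rows), semantic_map
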