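"""Feature scaling, kNN-graph Leiden clustering, per-cluster enrichment
against a positive reference set, and random-forest cluster prediction
with category annotation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .errors import FusionScopeError

logger = logging.getLogger(__name__)

DEFAULT_KNN_K = 50
DEFAULT_RESOLUTION = 3.0
DEFAULT_MAX_PER_CLUSTER = 300
DEFAULT_TRAIN_FRAC = 2.0 / 3.0
FOREST_TREES = 500


def scale_features(matrix: np.ndarray) -> np.ndarray:
    """Z-score, truncate to [-2, 2], then rescale to fill [-2, 2].

    Per column: z = (x - mean) / sd (sample sd), clamped to [-2, 2],
    then linearly mapped so the column min lands on -2 and the max on 2.
    Constant columns become all zeros.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FusionScopeError("scaling needs a 2-D matrix with >= 2 rows")
    out = np.zeros_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        z = np.clip((col - col.mean()) / sd, -2.0, 2.0)
        lo, hi = z.min(), z.max()
        if hi == lo:
            continue
        out[:, j] = -2.0 + 4.0 * (z - lo) / (hi - lo)
    return out


def leiden_cluster(
    matrix: np.ndarray,
    k: int = DEFAULT_KNN_K,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> np.ndarray:
    """Leiden communities on the undirected union Euclidean kNN graph."""
    if k < 1:
        raise FusionScopeError(f"k must be >= 1, got {k}")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n <= k:
        logger.warning("k=%d >= n=%d rows; reducing k to %d", k, n, n - 1)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            if i != j:
                edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


@dataclass
class EnrichmentResult:
    cluster: int
    in_positive: int
    in_other: int
    out_positive: int
    out_other: int
    p_value: float
    q_value: float = float("nan")


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher's exact p for table [[a,b],[c,d]]."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def cosmic_enrichment(
    labels: np.ndarray, flags: np.ndarray
) -> list[EnrichmentResult]:
    """Per-cluster one-sided Fisher's exact test for flagged variants,
    with Benjamini-Hochberg q-values across clusters."""
    labels = np.asarray(labels)
    flags = np.asarray(flags, dtype=bool)
    if labels.shape != flags.shape:
        raise FusionScopeError("labels and flags must align")
    results = []
    for cluster in sorted(set(labels.tolist())):
        inside = labels == cluster
        a = int((inside & flags).sum())
        b = int((inside & ~flags).sum())
        c = int((~inside & flags).sum())
        d = int((~inside & ~flags).sum())
        results.append(
            EnrichmentResult(
                cluster=int(cluster),
                in_positive=a,
                in_other=b,
                out_positive=c,
                out_other=d,
                p_value=fisher_one_sided(a, b, c, d),
            )
        )
    if results:
        qs = stats.false_discovery_control([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


@dataclass
class ClusterModel:
    """Fitted clustering + classifier + cluster->category annotation."""

    knn_k: int
    resolution: float
    seed: int
    labels: np.ndarray
    forest: RandomForestClassifier
    annotation_map: dict[int, str] = field(default_factory=dict)
    heldout_accuracy: float = float("nan")
    n_features: int = 9


def train_cluster_classifier(
    matrix: np.ndarray,
    labels: np.ndarray,
    max_per_cluster: int = DEFAULT_MAX_PER_CLUSTER,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 0,
    annotation_map: dict[int, str] | None = None,
    knn_k: int = DEFAULT_KNN_K,
    resolution: float = DEFAULT_RESOLUTION,
) -> ClusterModel:
    """Random forest over cluster labels with per-cluster downsampling
    to ``max_per_cluster`` and a stratified 2/3-1/3 split."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    clusters, counts = np.unique(y, return_counts=True)
    if len(clusters) < 2:
        raise FusionScopeError("need at least 2 clusters to train")
    if counts.min() < 3:
        raise FusionScopeError("every cluster needs >= 3 members")

    rng = np.random.default_rng(seed)
    keep = []
    for cluster in clusters:
        members = np.flatnonzero(y == cluster)
        if len(members) > max_per_cluster:
            members = rng.choice(members, size=max_per_cluster, replace=False)
        keep.extend(members.tolist())
    keep = np.array(sorted(keep))

    X_sub, y_sub = X[keep], y[keep]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X_sub,
        y_sub,
        train_size=train_frac,
        stratify=y_sub,
        random_state=seed,
    )
    forest = RandomForestClassifier(
        n_estimators=FOREST_TREES, random_state=seed, n_jobs=1
    )
    forest.fit(X_tr, y_tr)
    accuracy = float((forest.predict(X_te) == y_te).mean())
    return ClusterModel(
        knn_k=knn_k,
        resolution=resolution,
        seed=seed,
        labels=y,
        forest=forest,
        annotation_map=dict(annotation_map or {}),
        heldout_accuracy=accuracy,
        n_features=X.shape[1],
    )


def predict_category(
    model: ClusterModel, matrix: np.ndarray
) -> list[tuple[int, str]]:
    """Predicted (cluster label, category) per row; labels without an
    annotation fall back to "other"."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise FusionScopeError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {model.n_features}"
        )
    predicted = model.forest.predict(X)
    return [
        (int(label), model.annotation_map.get(int(label), "other"))
        for label in predicted
    ]


def tumor_enrichment(
    n_tumor_with: int, n_tumor: int, n_normal_with: int, n_normal: int
) -> float:
    """((tumor_with + 1)/tumor_total) / ((normal_with + 1)/normal_total)."""
    if n_tumor <= 0 or n_normal <= 0:
        raise FusionScopeError("sample totals must be positive")
    return ((n_tumor_with + 1) / n_tumor) / ((n_normal_with + 1) / n_normal)


def cluster_medians(matrix: np.ndarray, labels: np.ndarray, names=None) -> pd.DataFrame:
    """Per-cluster medians of each attribute (report convenience)."""
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=names)
    df["cluster"] = np.asarray(labels)
    return df.groupby("cluster").median()
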