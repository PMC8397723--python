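"""Distance-based profile typing: PAM clustering and CH-index model selection.

The typing procedure follows the enterotyping tradition: a sqrt-JSD distance
matrix is clustered with partitioning around medoids (PAM) for each candidate
number of clusters, and the Calinski-Harabasz (CH) index — computed on the
PCoA embedding of the distance matrix, where the classic between/within sum of
squares formulation is well defined — picks the number of clusters.

``PAMClusterer`` and ``JSDTyper`` are scikit-learn-style estimators (``fit``,
``labels_``, ``get_params``); the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score

from .distance import DistanceMatrix, Ordination, distance_matrix, normalize_profile, pcoa


@dataclass
class ClusterModel:
    """A fitted PAM partition at one value of k."""

    k: int
    medoids: np.ndarray  # sorted sample indices
    labels: np.ndarray  # sample -> cluster (index into medoids)
    cost: float  # sum of within-cluster distances to medoids
    ch: float | None = None


def _as_matrix(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.values
    return np.asarray(d, dtype=float)


class PAMClusterer(ClusterMixin, BaseEstimator):
    """Deterministic partitioning around medoids on a precomputed distance matrix.

    BUILD seeds medoids greedily (each new medoid maximises the cost
    reduction, ties to the lowest sample index); SWAP performs steepest-descent
    single medoid/non-medoid swaps until no swap lowers the total cost, so the
    result is locally optimal under single swaps.

    Parameters
    ----------
    n_clusters : int
        Number of medoids, 2 <= k <= n-1.
    max_iter : int
        Safety cap on SWAP iterations.

    Attributes
    ----------
    medoid_indices_ : ndarray of sorted medoid sample indices
    labels_ : ndarray, cluster index of each sample (nearest medoid, ties to
        the lowest medoid index)
    inertia_ : float, total within-cluster distance to medoids
    n_iter_ : int, SWAP iterations performed
    """

    def __init__(self, n_clusters: int = 3, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.max_iter = max_iter

    def fit(self, X, y=None):
        D = _as_matrix(X)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square (precomputed) distance matrix")
        n = D.shape[0]
        k = int(self.n_clusters)
        if not 2 <= k <= n - 1:
            raise ValueError(f"n_clusters must be in [2, n-1]; got {k} for n={n}")

        medoids = self._build(D, k)
        medoids, n_iter = self._swap(D, medoids)
        medoids = np.sort(medoids)
        labels = np.argmin(D[:, medoids], axis=1)
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = float(D[np.arange(n), medoids[labels]].sum())
        self.n_iter_ = n_iter
        return self

    @staticmethod
    def _build(D: np.ndarray, k: int) -> np.ndarray:
        n = D.shape[0]
        first = int(np.argmin(D.sum(axis=0)))  # argmin keeps lowest index on ties
        medoids = [first]
        nearest = D[:, first].copy()
        while len(medoids) < k:
            gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
            gains[medoids] = -np.inf
            c = int(np.argmax(gains))
            medoids.append(c)
            nearest = np.minimum(nearest, D[:, c])
        return np.asarray(medoids)

    def _swap(self, D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, int]:
        n = D.shape[0]
        medoids = np.array(medoids)
        for it in range(self.max_iter):
            Dm = D[:, medoids]  # n x k
            order = np.argsort(Dm, axis=1, kind="stable")
            d1 = Dm[np.arange(n), order[:, 0]]
            d2 = Dm[np.arange(n), order[:, 1]]
            nearest = order[:, 0]
            total = d1.sum()
            # delta[i, h]: change in cost when medoid i is replaced by point h
            delta = np.empty((len(medoids), n))
            for i in range(len(medoids)):
                base = np.where(nearest == i, d2, d1)  # loss if medoid i removed
                delta[i] = np.minimum(D, base[:, None]).sum(axis=0) - total
            delta[:, medoids] = np.inf
            flat = int(np.argmin(delta))  # row-major: lowest medoid slot, then h
            i, h = divmod(flat, n)
            if delta[i, h] >= -1e-12:
                return medoids, it
            medoids = medoids.copy()
            medoids[i] = h
        return medoids, self.max_iter

    def to_model(self, d=None) -> ClusterModel:
        return ClusterModel(
            k=int(self.n_clusters),
            medoids=self.medoid_indices_,
            labels=self.labels_,
            cost=self.inertia_,
        )


def pam(d, k: int) -> ClusterModel:
    """Cluster a distance matrix with PAM at a fixed k."""
    est = PAMClusterer(n_clusters=k).fit(_as_matrix(d))
    return est.to_model()


def ch_index(d, labels, embedding: Ordination | None = None, method: str = "pcoa") -> float:
    """Calinski-Harabasz index of a labelling of a distance matrix.

    With ``method='pcoa'`` (default) the samples are embedded with classical
    scaling on the positive axes and the classic CH ratio
    [B/(k-1)] / [W/(n-k)] is computed there; ``method='medoid'`` uses squared
    distances to cluster medoids and the overall medoid instead, staying in
    distance space.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("CH index needs at least two non-empty clusters")
    D = _as_matrix(d)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("label count does not match distance matrix")
    if method == "pcoa":
        if embedding is None:
            embedding = pcoa(d if isinstance(d, DistanceMatrix) else DistanceMatrix(list(range(n)), D))
        return float(calinski_harabasz_score(embedding.coordinates, labels))
    if method == "medoid":
        k = len(uniq)
        W = 0.0
        cluster_medoids = []
        for lab in uniq:
            idx = np.flatnonzero(labels == lab)
            sub = D[np.ix_(idx, idx)]
            m = idx[int(np.argmin(sub.sum(axis=0)))]
            cluster_medoids.append((m, idx))
            W += float((D[idx, m] ** 2).sum())
        g = int(np.argmin(D.sum(axis=0)))  # overall medoid
        B = float(sum(len(idx) * D[m, g] ** 2 for m, idx in cluster_medoids))
        if W == 0:
            return np.inf
        return (B / (k - 1)) / (W / (n - k))
    raise ValueError(f"unknown method {method!r}")


def select_k(d, k_range=range(2, 9), method: str = "pcoa") -> tuple[int, dict[int, ClusterModel]]:
    """PAM at each k in ``k_range``; pick the k maximising the CH index.

    Ties go to the smaller k.  Returns (k*, {k: ClusterModel with .ch set}).
    """
    D = _as_matrix(d)
    dm = d if isinstance(d, DistanceMatrix) else DistanceMatrix(list(range(D.shape[0])), D)
    embedding = pcoa(dm) if method == "pcoa" else None
    models: dict[int, ClusterModel] = {}
    for k in k_range:
        model = pam(D, k)
        model.ch = ch_index(dm, model.labels, embedding=embedding, method=method)
        models[k] = model
    best = max(sorted(models), key=lambda k: (models[k].ch, -k))
    return best, models


class JSDTyper(ClusterMixin, BaseEstimator):
    """End-to-end profile typing: normalise, sqrt-JSD, PAM, CH selection of k.

    Parameters
    ----------
    k_min, k_max : candidate cluster numbers (inclusive).
    pseudocount : added to every feature before renormalising.
    proportion : if True (default), rows are renormalised to proportions; set
        False to type raw values that are already probability vectors.
    ch_method : 'pcoa' or 'medoid' dispersion for the CH index.

    Attributes
    ----------
    k_ : selected number of clusters
    labels_ : cluster label per sample
    models_ : {k: ClusterModel} for every candidate k
    ch_scores_ : {k: CH index}
    distance_ : DistanceMatrix used
    ordination_ : PCoA embedding of the distance matrix
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 8,
        pseudocount: float = 1e-9,
        proportion: bool = True,
        ch_method: str = "pcoa",
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.pseudocount = pseudocount
        self.proportion = proportion
        self.ch_method = ch_method

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            labels = list(X.index)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            labels = list(range(values.shape[0]))
        if self.proportion:
            values = np.vstack(
                [normalize_profile(row, self.pseudocount) for row in values]
            )
        self.distance_ = distance_matrix(values, labels=labels)
        self.ordination_ = pcoa(self.distance_)
        k_range = range(self.k_min, min(self.k_max, len(labels) - 1) + 1)
        self.k_, self.models_ = select_k(
            self.distance_, k_range=k_range, method=self.ch_method
        )
        self.ch_scores_ = {k: m.ch for k, m in self.models_.items()}
        self.labels_ = self.models_[self.k_].labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def characterize_clusters(labels, features, ranking: str = "mean") -> pd.DataFrame:
    """Per-cluster feature means, ranked; the top feature is the main contributor.

    With ``ranking='mean'`` features are ranked by their within-cluster mean
    (natural for compositions, where the dominant taxon defines the cluster).
    With ``ranking='enrichment'`` they are ranked by cluster mean divided by
    global mean — appropriate for concentration profiles where one analyte
    (e.g. acetate) is largest in every cluster and clusters are distinguished
    by what is *elevated* relative to the cohort.

    Returns a tidy frame with one row per (cluster, feature) carrying the
    cluster mean, the enrichment ratio and the rank (rank 1 = main
    contributor under the chosen ranking).
    """
    if ranking not in ("mean", "enrichment"):
        raise ValueError("ranking must be 'mean' or 'enrichment'")
    features = pd.DataFrame(features)
    if features.shape[1] == 0 or features.shape[0] == 0:
        raise ValueError("empty feature table")
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("label count does not match feature table")
    global_mean = features.mean(axis=0)
    rows = []
    for lab in np.unique(labels):
        means = features.loc[labels == lab].mean(axis=0)
        enrichment = means / global_mean.where(global_mean > 0, np.nan)
        key = means if ranking == "mean" else enrichment
        for rank, feat in enumerate(key.sort_values(ascending=False).index, start=1):
            rows.append({
                "cluster": lab, "feature": feat, "mean": float(means[feat]),
                "enrichment": float(enrichment[feat]) if np.isfinite(enrichment[feat]) else np.nan,
                "rank": rank,
            })
    return pd.DataFrame(rows)


def main_contributors(labels, features, ranking: str = "mean") -> dict:
    """Map each cluster label to its top feature under the chosen ranking."""
    table = characterize_clusters(labels, features, ranking=ranking)
    top = table[table["rank"] == 1]
    return dict(zip(top["cluster"], top["feature"]))
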