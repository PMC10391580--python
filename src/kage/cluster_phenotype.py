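"""Semi-supervised clustering of phenotype feature tables.

The procedure exploits one a-priori known group (the control animals):
many (algorithm, hyperparameter) combinations are sampled, and only
clusterings that place every known control in a single cluster are
retained; candidates are ranked by mean Silhouette, with agglomerative
ward/Euclidean pinned as the documented default among passing models.
Stability is quantified by leave-one-animal-out re-clustering (mean
Silhouette and adjusted Rand index against the original partition) and
compared with chance thresholds from feature-shuffled surrogate tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import (
    OPTICS,
    AffinityPropagation,
    AgglomerativeClustering,
    KMeans,
    SpectralClustering,
)
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.mixture import BayesianGaussianMixture

__all__ = [
    "ClusteringModel",
    "StabilityReport",
    "zscore_features",
    "silhouette",
    "adjusted_rand",
    "cluster_search",
    "gap_statistic_k",
    "select_final",
    "loo_stability",
    "shuffle_null_stability",
    "score_confusion",
    "assign_new",
]

ALGORITHMS = ("kmeans", "bayes_gmm", "agglomerative", "optics",
              "spectral", "affinity_propagation")


@dataclass
class ClusteringModel:
    algorithm: str
    hyperparameters: dict
    labels: np.ndarray
    mouse_ids: list
    control_pure: bool
    mean_silhouette: float

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class StabilityReport:
    silhouette_mean: float
    silhouette_sd: float
    ari_mean: float
    ari_sd: float
    silhouette_threshold: float | None = None
    ari_threshold: float | None = None
    n_sims: int = 0
    n_shuffles: int = 0
    seed: int = 0


def zscore_features(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization; constant columns map to 0."""
    X = table.to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant columns {list(table.columns[const])} set to 0")
        sd = np.where(const, 1.0, sd)
    return pd.DataFrame((X - mu) / sd, index=table.index,
                        columns=table.columns)


def silhouette(table, labels):
    """Per-sample Silhouette values and their mean (Euclidean distance).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)); singleton clusters score 0.
    """
    X = np.asarray(table, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    vals = silhouette_samples(X, labels, metric="euclidean")
    return vals, float(vals.mean())


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index between two partitions."""
    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------------------------
# Model search

def _sample_params(alg: str, n: int, rng) -> dict:
    k = int(rng.integers(2, min(9, n)))
    if alg == "kmeans":
        return {"n_clusters": k, "n_init": 10}
    if alg == "bayes_gmm":
        return {"n_components": k,
                "covariance_type": str(rng.choice(
                    ["full", "diag", "spherical", "tied"]))}
    if alg == "agglomerative":
        linkage = str(rng.choice(["ward", "complete", "average", "single"]))
        metric = "euclidean" if linkage == "ward" else str(
            rng.choice(["euclidean", "manhattan", "cosine"]))
        return {"n_clusters": k, "linkage": linkage, "metric": metric}
    if alg == "optics":
        return {"min_samples": int(rng.integers(2, 6)),
                "xi": float(rng.uniform(0.02, 0.3))}
    if alg == "spectral":
        return {"n_clusters": k,
                "n_neighbors": int(rng.integers(3, max(4, n // 2)))}
    if alg == "affinity_propagation":
        return {"damping": float(rng.uniform(0.5, 0.95))}
    raise ValueError(alg)


def _fit_labels(alg: str, params: dict, X: np.ndarray, seed: int):
    if alg == "kmeans":
        return KMeans(random_state=seed, **params).fit_predict(X)
    if alg == "bayes_gmm":
        return BayesianGaussianMixture(
            random_state=seed, max_iter=200, **params).fit_predict(X)
    if alg == "agglomerative":
        return AgglomerativeClustering(**params).fit_predict(X)
    if alg == "optics":
        return OPTICS(**params).fit_predict(X)
    if alg == "spectral":
        return SpectralClustering(
            random_state=seed, affinity="nearest_neighbors",
            assign_labels="discretize", **params).fit_predict(X)
    if alg == "affinity_propagation":
        return AffinityPropagation(
            random_state=seed, **params).fit_predict(X)
    raise ValueError(alg)


def _controls_together(labels, mouse_ids, control_ids) -> bool:
    idx = [i for i, m in enumerate(mouse_ids) if m in control_ids]
    lab = np.asarray(labels)[idx]
    return len(set(lab.tolist())) == 1 and lab[0] != -1


def cluster_search(table: pd.DataFrame, known_control_ids, n_sims: int = 25_000,
                   seed: int = 0, standardized: bool = False):
    """Sample clustering models; keep those grouping all known controls.

    ``table`` is z-scored internally unless ``standardized``.  Returns the
    retained :class:`ClusteringModel` candidates sorted by decreasing mean
    Silhouette; the first agglomerative ward/Euclidean candidate, when one
    passes, is moved to the front as the default final model.  An empty
    list means no sampled model kept the controls together.
    """
    control_ids = set(known_control_ids)
    if not control_ids or not control_ids <= set(table.index):
        raise ValueError("known_control_ids must be a non-empty subset of "
                         "the table's mice")
    Z = table if standardized else zscore_features(table)
    X = Z.to_numpy(float)
    ids = list(table.index)
    rng = np.random.default_rng(seed)
    seen = set()
    candidates = []
    for i in range(n_sims):
        alg = str(rng.choice(ALGORITHMS))
        params = _sample_params(alg, len(ids), rng)
        key = (alg, tuple(sorted(params.items())))
        fit_seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                labels = np.asarray(_fit_labels(alg, params, X, fit_seed))
            except Exception:
                continue
        if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= len(ids):
            continue
        if not _controls_together(labels, ids, control_ids):
            continue
        lab_key = key + (tuple(labels.tolist()),)
        if lab_key in seen:
            continue
        seen.add(lab_key)
        _, mean_s = silhouette(X, labels)
        candidates.append(ClusteringModel(
            alg, params, labels, ids, True, mean_s))
    candidates.sort(key=lambda m: -m.mean_silhouette)
    ward = [m for m in candidates
            if m.algorithm == "agglomerative"
            and m.hyperparameters.get("linkage") == "ward"]
    if ward:
        candidates.remove(ward[0])
        candidates.insert(0, ward[0])
    return candidates


def _log_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    W = 0.0
    for c in np.unique(labels):
        x = X[labels == c]
        W += float(((x - x.mean(axis=0)) ** 2).sum())
    return np.log(max(W, 1e-12))


def gap_statistic_k(table: pd.DataFrame, k_range=range(2, 9),
                    n_ref: int = 30, seed: int = 0,
                    standardized: bool = False) -> dict:
    """Cluster count for ward/Euclidean clustering by the gap statistic.

    Gap(k) compares the log within-cluster dispersion of the data with its
    expectation under column-permuted surrogates; the selected k is the
    smallest with Gap(k) >= Gap(k+1) - SE(k+1) (the one-standard-error
    rule), which resists the under-clustering that raw silhouette ranking
    favors when one group lies much farther out than the rest.
    """
    Z = table if standardized else zscore_features(table)
    X = Z.to_numpy(float)
    rng = np.random.default_rng(seed)
    ks = [k for k in k_range if k < len(X)]
    refs = []
    for _ in range(n_ref):
        Xs = np.empty_like(X)
        for j in range(X.shape[1]):
            Xs[:, j] = X[rng.permutation(len(X)), j]
        refs.append(Xs)
    gap, se = {}, {}
    for k in ks:
        lab = AgglomerativeClustering(n_clusters=k).fit_predict(X)
        null = [_log_within_dispersion(
            Xs, AgglomerativeClustering(n_clusters=k).fit_predict(Xs))
            for Xs in refs]
        gap[k] = float(np.mean(null) - _log_within_dispersion(X, lab))
        se[k] = float(np.std(null) * np.sqrt(1.0 + 1.0 / n_ref))
    chosen = None
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - se[ks[i + 1]]:
            chosen = k
            break
    if chosen is None and len(ks) >= 3:
        # no plateau: fall back to the elbow of the gap curve (largest
        # drop in marginal gain)
        curv = {k: (gap[k] - gap[ks[i - 1]]) - (gap[ks[i + 1]] - gap[k])
                for i, k in enumerate(ks) if 0 < i < len(ks) - 1}
        chosen = max(curv, key=curv.get)
    if chosen is None:
        chosen = ks[-1]
    return {"k": chosen, "gap": gap, "se": se}


def select_final(table: pd.DataFrame, known_control_ids,
                 candidates=None, seed: int = 0,
                 standardized: bool = False) -> ClusteringModel | None:
    """Pick the final clustering model.

    The default final model is agglomerative ward/Euclidean with its
    cluster count set by :func:`gap_statistic_k`, provided that model
    keeps all known controls in one cluster; otherwise the next k in gap
    preference order is tried, and as a last resort the top-Silhouette
    sampled candidate is returned (None when nothing passes).
    """
    control_ids = set(known_control_ids)
    Z = table if standardized else zscore_features(table)
    X = Z.to_numpy(float)
    ids = list(table.index)
    res = gap_statistic_k(table, seed=seed, standardized=True) if \
        standardized else gap_statistic_k(table, seed=seed)
    # when the chosen k violates the control constraint, first try sampled
    # candidates at the same cluster count, then nearby counts
    order = sorted(res["gap"], key=lambda k: (abs(k - res["k"]), -k))
    for k in order:
        params = {"n_clusters": k, "linkage": "ward", "metric": "euclidean"}
        labels = AgglomerativeClustering(**params).fit_predict(X)
        if len(np.unique(labels)) >= 2 and \
                _controls_together(labels, ids, control_ids):
            _, mean_s = silhouette(X, labels)
            return ClusteringModel("agglomerative", params,
                                   np.asarray(labels), ids, True, mean_s)
        same_k = [m for m in (candidates or []) if m.n_clusters == k]
        if same_k:
            return max(same_k, key=lambda m: m.mean_silhouette)
    if candidates:
        return candidates[0]
    return None


def refit(model: ClusteringModel, X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Re-fit the model's algorithm/hyperparameters on new data."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(_fit_labels(
            model.algorithm, model.hyperparameters, X, seed))


# ---------------------------------------------------------------------------
# Stability

def loo_stability(table: pd.DataFrame, model: ClusteringModel,
                  n_sims: int = 10_000, seed: int = 0,
                  standardized: bool = False) -> StabilityReport:
    """Leave-one-animal-out stability of a fitted clustering.

    Each simulation removes one uniformly chosen mouse (with replacement
    across simulations), re-fits the same algorithm and hyperparameters,
    and records the re-fit's mean Silhouette plus the adjusted Rand index
    against the original labels restricted to the retained mice.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 mice")
    Z = table if standardized else zscore_features(table)
    X = Z.to_numpy(float)
    rng = np.random.default_rng(seed)
    sils, aris = [], []
    orig = np.asarray(model.labels)
    for _ in range(n_sims):
        drop = int(rng.integers(0, len(table)))
        keep = np.ones(len(table), bool)
        keep[drop] = False
        labels = refit(model, X[keep], seed=int(rng.integers(0, 2**31 - 1)))
        if len(np.unique(labels)) >= 2:
            _, s = silhouette(X[keep], labels)
        else:
            s = 0.0
        sils.append(s)
        aris.append(adjusted_rand(orig[keep], labels))
    return StabilityReport(
        float(np.mean(sils)), float(np.std(sils)),
        float(np.mean(aris)), float(np.std(aris)),
        n_sims=n_sims, seed=seed)


def shuffle_null_stability(table: pd.DataFrame, model: ClusteringModel,
                           n_shuffles: int = 10_000, q: float = 0.95,
                           seed: int = 0, standardized: bool = False):
    """Chance thresholds for Silhouette and ARI from shuffled surrogates.

    Each surrogate permutes every feature column across mice independently
    (feature type preserved); the model is re-fit on the surrogate and its
    mean Silhouette recorded, along with the ARI between the surrogate fit
    and the original labels.  Thresholds are the q-quantiles.
    """
    Z = table if standardized else zscore_features(table)
    X = Z.to_numpy(float)
    rng = np.random.default_rng(seed)
    orig = np.asarray(model.labels)
    sils, aris = [], []
    for _ in range(n_shuffles):
        Xs = np.empty_like(X)
        for j in range(X.shape[1]):
            Xs[:, j] = X[rng.permutation(len(X)), j]
        labels = refit(model, Xs, seed=int(rng.integers(0, 2**31 - 1)))
        if len(np.unique(labels)) >= 2:
            _, s = silhouette(Xs, labels)
        else:
            s = 0.0
        sils.append(s)
        aris.append(adjusted_rand(orig, labels))
    return {
        "silhouette_threshold": float(np.quantile(sils, q)),
        "ari_threshold": float(np.quantile(aris, q)),
        "silhouette_null": np.asarray(sils),
        "ari_null": np.asarray(aris),
    }


# ---------------------------------------------------------------------------
# Scoring and assignment

def score_confusion(labels, truth_groups):
    """Confusion matrix under the accuracy-maximizing cluster-group map.

    Clusters are matched one-to-one to truth groups by optimal bipartite
    assignment; a truth group without a matched cluster scores 0% and is
    flagged.  Returns a dict with the matrix (groups x clusters, counts),
    per-group accuracy (%), overall accuracy (%), the mapping, and any
    unmatched groups.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth_groups)
    groups = list(dict.fromkeys(truth.tolist()))
    clusters = list(np.unique(labels))
    cont = np.zeros((len(groups), len(clusters)), int)
    for g_i, g in enumerate(groups):
        for c_i, c in enumerate(clusters):
            cont[g_i, c_i] = int(np.sum((truth == g) & (labels == c)))
    row, col = linear_sum_assignment(-cont)
    mapping = {clusters[c]: groups[r] for r, c in zip(row, col)}
    per_group = {}
    correct = 0
    matched_rows = set(row.tolist())
    for g_i, g in enumerate(groups):
        size = int(np.sum(truth == g))
        if g_i in matched_rows:
            c_i = col[list(row).index(g_i)]
            hits = cont[g_i, c_i]
        else:
            hits = 0
        per_group[g] = 100.0 * hits / size if size else float("nan")
        correct += hits
    return {
        "matrix": pd.DataFrame(cont, index=groups, columns=clusters),
        "mapping": mapping,
        "per_group_accuracy": per_group,
        "overall_accuracy": 100.0 * correct / len(truth),
        "unmatched_groups": [g for i, g in enumerate(groups)
                             if i not in matched_rows],
    }


def assign_new(table_ref: pd.DataFrame, labels_ref, table_new: pd.DataFrame,
               group_names: dict | None = None) -> pd.DataFrame:
    """Nearest-group assignment of new mice in the reference feature space.

    New rows are standardized with the REFERENCE table's means/SDs; the
    distance to a group is the mean Euclidean distance to its member rows.
    Returns a frame with one distance column per group plus ``nearest``.
    """
    mu = table_ref.mean(axis=0)
    sd = table_ref.std(axis=0, ddof=0).replace(0.0, 1.0)
    Zr = ((table_ref - mu) / sd).to_numpy(float)
    Zn = ((table_new[table_ref.columns] - mu) / sd).to_numpy(float)
    labels_ref = np.asarray(labels_ref)
    groups = list(np.unique(labels_ref))
    out = {}
    for g in groups:
        members = Zr[labels_ref == g]
        d = np.linalg.norm(Zn[:, None, :] - members[None, :, :], axis=2)
        name = group_names.get(g, g) if group_names else g
        out[name] = d.mean(axis=1)
    df = pd.DataFrame(out, index=table_new.index)
    df["nearest"] = df.idxmin(axis=1)
    return df
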