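"""Co-expression clustering of temporal profiles and term enrichment.

DEG profiles (z-scored log2 mean FPKM over the time points) are
partitioned by K-means with many random starts; the number of clusters
is chosen by the gap statistic against a uniform reference distribution
drawn in the PCA-aligned bounding box of the data. Smaller gene families
can be organized by average-linkage hierarchical clustering, and
clusters are tested for term over-representation with a one-sided
hypergeometric test, BH-corrected across all (cluster, term) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from ._rng import child_seed, substream


def profile_matrix(
    fpkm: pd.DataFrame, design: pd.DataFrame, zscore: bool = True,
) -> pd.DataFrame:
    """Per-gene temporal profile: z-scored log2(mean FPKM + 1) per DAP."""
    design = design.loc[fpkm.columns]
    means = fpkm.T.groupby(design["dap"].to_numpy()).mean().T
    prof = np.log2(means + 1.0)
    if zscore:
        mu = prof.mean(axis=1)
        sd = prof.std(axis=1, ddof=0).replace(0.0, 1.0)
        prof = prof.sub(mu, axis=0).div(sd, axis=0)
    return prof


@dataclass
class ClusteringResult:
    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    k: int
    seed: int


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int,
    n_start: int = 100,
    max_iter: int = 25,
    seed: int = 0,
) -> ClusteringResult:
    """K-means on profile rows; best of `n_start` runs, seeded."""
    if k < 1 or k > len(profiles):
        raise ValueError(f"k={k} outside [1, {len(profiles)}]")
    km = KMeans(
        n_clusters=k, n_init=n_start, max_iter=max_iter,
        random_state=child_seed(seed, "kmeans"), algorithm="lloyd",
    ).fit(profiles.to_numpy())
    labels = pd.Series(km.labels_, index=profiles.index, name="cluster")
    return ClusteringResult(labels, km.cluster_centers_, float(km.inertia_), k, seed)


def within_ss(profiles: pd.DataFrame, labels: pd.Series) -> float:
    """Total within-cluster sum of squares of an assignment."""
    x = profiles.to_numpy()
    lab = labels.to_numpy()
    total = 0.0
    for c in np.unique(lab):
        sub = x[lab == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def gap_statistic(
    profiles: pd.DataFrame,
    k_range: range | list[int] = range(1, 9),
    B: int = 50,
    seed: int = 0,
    n_start: int = 10,
    max_iter: int = 50,
) -> tuple[int, pd.DataFrame]:
    """Choose k by the gap statistic.

    Gap(k) = E*[log W_k] - log W_k over `B` uniform reference draws in
    the PCA-aligned bounding box of the data; the chosen k is the
    smallest with Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    if B < 2:
        raise ValueError("need at least 2 reference datasets")
    ks = list(k_range)
    X = profiles.to_numpy(dtype=float)
    rng = substream(seed, "gap-reference")

    def log_wk(data: np.ndarray, k: int, state: int) -> float:
        km = KMeans(n_clusters=k, n_init=n_start, max_iter=max_iter,
                    random_state=state, algorithm="lloyd").fit(data)
        return float(np.log(max(km.inertia_, 1e-300)))

    # PCA-aligned box (Tibshirani variant b)
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    obs = np.array([log_wk(X, k, child_seed(seed, f"gap-obs-{k}")) for k in ks])
    ref = np.empty((B, len(ks)))
    for b in range(B):
        Z = rng.uniform(lo, hi, size=Xp.shape) @ Vt + mu
        for j, k in enumerate(ks):
            ref[b, j] = log_wk(Z, k, child_seed(seed, f"gap-ref-{b}-{k}"))
    gap = ref.mean(axis=0) - obs
    s = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    curve = pd.DataFrame({"k": ks, "log_wk": obs, "e_log_wk": ref.mean(axis=0),
                          "gap": gap, "s_k": s})
    chosen = ks[-1]
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            chosen = ks[j]
            break
    return chosen, curve


def hierarchical_cluster(
    profiles: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, pd.Series | None]:
    """Average-linkage hierarchical clustering of a gene subset.

    Returns the scipy linkage matrix and, if `n_clusters` or `height`
    is given, the cut assignments.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    Z = linkage(profiles.to_numpy(), method=method, metric=metric)
    labels = None
    if n_clusters is not None:
        labels = pd.Series(fcluster(Z, t=n_clusters, criterion="maxclust"),
                           index=profiles.index, name="cluster")
    elif height is not None:
        labels = pd.Series(fcluster(Z, t=height, criterion="distance"),
                           index=profiles.index, name="cluster")
    return Z, labels


def hypergeometric_enrichment(
    cluster_labels: pd.Series,
    term_map: dict[str, set[str]],
    background: set[str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of terms in clusters.

    For each (cluster, term): the upper-tail probability of drawing at
    least the observed overlap when sampling the cluster from the
    background. BH correction is applied across all pairs.
    """
    if background is None:
        background = set(cluster_labels.index)
    clustered = set(cluster_labels.index)
    if not clustered <= background:
        raise ValueError("background must contain every clustered gene")
    M = len(background)
    rows = []
    for term, genes in term_map.items():
        genes_bg = set(genes) & background
        if not genes_bg:
            warnings.warn(f"term {term!r} has no genes in the background; skipped")
            continue
        K = len(genes_bg)
        for cluster, members in cluster_labels.groupby(cluster_labels):
            cluster_genes = set(members.index)
            n = len(cluster_genes)
            overlap = len(cluster_genes & genes_bg)
            p = float(hypergeom.sf(overlap - 1, M, K, n)) if overlap > 0 else 1.0
            rows.append({"cluster": cluster, "term": term, "overlap": overlap,
                         "cluster_size": n, "term_size": K, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = np.maximum(q, out["p"])
    return out


def jaccard_collapse(term_map: dict[str, set[str]], threshold: float = 0.7) -> dict[str, set[str]]:
    """Greedy merge of term gene-sets with Jaccard similarity >= threshold.

    A light stand-in for semantic redundancy filtering: terms are
    scanned in name order and each is merged into the first retained
    term it resembles.
    """
    kept: dict[str, set[str]] = {}
    for term in sorted(term_map):
        genes = set(term_map[term])
        target = None
        for other, og in kept.items():
            j = len(genes & og) / len(genes | og) if genes | og else 0.0
            if j >= threshold:
                target = other
                break
        if target is None:
            kept[term] = set(genes)
        else:
            kept[target] |= genes
    return kept
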