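"""Comparative proteome analysis: scaling, PCA, elbow-selected K-means.

Protein property vectors from two (or more) organisms are z-scaled column-
wise, projected with PCA, and clustered with K-means; the number of clusters
is chosen by an explained-within-cluster-variance elbow rule. The cluster
report gives per-cluster mean scaled feature values and the organism
composition of each cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

ELBOW_EXPLAINED = 0.75   # smallest k reaching this explained fraction ...
ELBOW_MIN_GAIN = 0.05    # ... whose next step adds less than this
KMEANS_RESTARTS = 50
KMEANS_MAX_ITER = 300


@dataclass
class ClusterReport:
    k: int
    assignments: pd.Series               # protein -> cluster index
    feature_means: pd.DataFrame          # cluster x feature (scaled units)
    organism_fractions: pd.DataFrame     # cluster x organism (rows sum to 1)
    organism_distribution: pd.DataFrame  # organism x cluster (rows sum to 1)
    explained_variance: np.ndarray       # PCA fractions, sum 1


def zscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score (ddof=1); constant columns are dropped with a warning.

    Missing cells are imputed with the column mean before scaling.
    """
    filled = matrix.apply(lambda col: col.fillna(col.mean()))
    sd = filled.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant):
        warnings.warn(f"dropping constant columns: {list(constant)}")
        filled = filled.drop(columns=constant)
        sd = sd.drop(constant)
    return (filled - filled.mean()) / sd


def pca(scaled: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the scaled matrix.

    Returns (components, explained variance fractions); components are sign-
    fixed so each one's largest-magnitude loading is positive, and the
    fractions sum to 1 over all components.
    """
    n_comp = min(scaled.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    model.fit(scaled.to_numpy(dtype=float))
    comps = model.components_
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps, model.explained_variance_ratio_


def kmeans(scaled: pd.DataFrame, k: int, seed: int = 0
           ) -> tuple[pd.Series, np.ndarray, float]:
    """K-means (k-means++ init, 50 restarts, best WCSS) -> assignments, centroids, WCSS."""
    if k > len(scaled):
        raise ValueError("k exceeds number of rows")
    X = scaled.to_numpy(dtype=float)
    model = KMeans(n_clusters=k, init="k-means++", n_init=KMEANS_RESTARTS,
                   max_iter=KMEANS_MAX_ITER, random_state=seed)
    labels = model.fit_predict(X)
    return pd.Series(labels, index=scaled.index), model.cluster_centers_, float(model.inertia_)


def choose_k_elbow(scaled: pd.DataFrame, k_max: int = 10, seed: int = 0,
                   explained_threshold: float = ELBOW_EXPLAINED,
                   min_gain: float = ELBOW_MIN_GAIN) -> int:
    """Elbow rule on explained within-cluster variance.

    explained(k) = 1 - WCSS(k)/WCSS(1); pick the smallest k that reaches the
    explained threshold and whose next step gains less than min_gain. Falls
    back to 1 when no k in range qualifies (single-blob data).
    """
    k_max = min(k_max, len(scaled))
    wcss = {k: kmeans(scaled, k, seed)[2] for k in range(1, min(k_max + 1, len(scaled)) + 1)}
    total = wcss[1]
    if total == 0:
        return 1
    explained = {k: 1.0 - wcss[k] / total for k in wcss}
    for k in range(1, k_max + 1):
        gain = explained.get(k + 1, 1.0) - explained[k]
        if explained[k] >= explained_threshold and gain < min_gain:
            return k
    # No k explains enough: treat the data as unstructured (one cluster).
    return 1


def cluster_profile(assignments: pd.Series, scaled: pd.DataFrame,
                    organisms: pd.Series, explained_variance: np.ndarray | None = None
                    ) -> ClusterReport:
    """Per-cluster mean scaled features and organism composition."""
    if not assignments.index.equals(scaled.index):
        assignments = assignments.reindex(scaled.index)
        if assignments.isna().any():
            raise ValueError("assignments do not cover all rows")
    organisms = organisms.reindex(scaled.index)
    df = scaled.copy()
    df["_cluster"] = assignments
    means = df.groupby("_cluster").mean()
    means.index.name = "cluster"
    counts = pd.crosstab(assignments, organisms)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    distribution = counts.T.div(counts.sum(axis=0), axis=0)
    k = int(assignments.nunique())
    if explained_variance is None:
        explained_variance = pca(scaled)[1]
    return ClusterReport(k=k, assignments=assignments, feature_means=means,
                         organism_fractions=fractions,
                         organism_distribution=distribution,
                         explained_variance=explained_variance)


def compare_proteomes(matrices: dict[str, pd.DataFrame], seed: int = 0,
                      k: int | None = None, k_max: int = 10) -> ClusterReport:
    """Full comparison: stack per-organism property tables, scale, cluster.

    ``matrices`` maps organism tag -> property table (proteins x features).
    Row ids are prefixed with the organism tag to stay unique.
    """
    frames, tags = [], []
    for org, df in matrices.items():
        frame = df.copy()
        frame.index = [f"{org}:{i}" for i in df.index]
        frames.append(frame)
        tags.extend([org] * len(frame))
    stacked = pd.concat(frames)
    organisms = pd.Series(tags, index=stacked.index)
    scaled = zscale(stacked)
    _, variance = pca(scaled)
    if k is None:
        k = choose_k_elbow(scaled, k_max=k_max, seed=seed)
    assignments, _, _ = kmeans(scaled, k, seed)
    return cluster_profile(assignments, scaled, organisms, variance)
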