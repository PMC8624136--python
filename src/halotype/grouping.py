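"""Ward clustering of genotypes into salinity-tolerance groups.

Genotypes are clustered on seven yield-derived features (GYc, GYs, YSI,
SSI, STI, TOL, GMP), z-standardized, with Ward's minimum-variance
criterion on Euclidean distances, and the tree cut into three groups.
Semantic labels follow the feature profile of each group:

* **salt-tolerant** — highest mean GYc and STI;
* **moderately salt-tolerant** — of the remaining two, higher YSI and
  lower SSI (small relative yield loss);
* **salt-sensitive** — the last group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

SALT_TOLERANT = "salt-tolerant"
SALT_SENSITIVE = "salt-sensitive"
MODERATE = "moderately salt-tolerant"

GROUP_LABELS = (SALT_TOLERANT, SALT_SENSITIVE, MODERATE)


def standardize(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column (population sd, ddof=0).

    Idempotent on already-standardized input; a constant column is an
    error naming the offending feature.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 genotypes to standardize")
    sd = features.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant feature(s) cannot be standardized: {constant}")
    return (features - features.mean()) / sd


class WardToleranceClustering(BaseEstimator, ClusterMixin):
    """Agglomerative Ward clustering of a genotype feature matrix.

    scikit-learn style estimator: ``fit(X)`` accepts a DataFrame (index =
    genotypes) or array, z-standardizes the columns, runs Ward linkage on
    Euclidean distances and cuts the tree into ``n_clusters`` groups.

    Attributes
    ----------
    labels_ : ndarray of int
        1-based cluster ids per row of X.
    linkage_ : ndarray
        scipy condensed linkage matrix (merge heights non-decreasing).
    """

    def __init__(self, n_clusters: int = 3, standardize_features: bool = True):
        self.n_clusters = n_clusters
        self.standardize_features = standardize_features

    def fit(self, X, y=None):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if frame.isna().any().any():
            raise ValueError("feature matrix has missing cells")
        n = len(frame)
        if self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n={n}")
        values = standardize(frame).to_numpy() if self.standardize_features else frame.to_numpy(float)
        self.feature_names_in_ = np.asarray(frame.columns)
        self.index_ = frame.index
        self.linkage_ = linkage(values, method="ward")
        self.labels_ = fcluster(self.linkage_, self.n_clusters, criterion="maxclust")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ToleranceGrouping:
    """Clustering result with semantic labels and group feature means."""

    labels: pd.Series            # genotype -> semantic label
    cluster_ids: pd.Series       # genotype -> raw cluster id
    linkage_matrix: np.ndarray
    group_means: pd.DataFrame    # semantic label x feature means

    @property
    def k(self) -> int:
        return self.cluster_ids.nunique()


def ward_cluster(features: pd.DataFrame, k: int = 3) -> tuple[pd.Series, np.ndarray]:
    """Cluster genotypes; returns (cluster id Series, linkage matrix)."""
    est = WardToleranceClustering(n_clusters=k).fit(features)
    return pd.Series(est.labels_, index=features.index, name="cluster"), est.linkage_


def _rank_groups(group_means: pd.DataFrame) -> dict:
    """Map cluster id -> semantic label from group feature means."""
    needed = {"GYc", "STI", "YSI", "SSI"}
    if not needed <= set(group_means.columns):
        raise ValueError(f"group means lack deciding features {needed}")
    if len(group_means) != 3:
        raise ValueError("semantic labelling requires exactly 3 groups")

    def argmax_checked(col):
        s = group_means[col]
        top = s.idxmax()
        if (s == s.max()).sum() > 1:
            raise ValueError(
                f"tie in group mean {col}; assign labels manually"
            )
        return top

    tol_by_gyc = argmax_checked("GYc")
    tol_by_sti = argmax_checked("STI")
    if tol_by_gyc != tol_by_sti:
        raise ValueError(
            "GYc and STI disagree on the top group; assign labels manually"
        )
    rest = group_means.drop(index=tol_by_gyc)
    mod_by_ysi = rest["YSI"].idxmax()
    mod_by_ssi = rest["SSI"].idxmin()
    if (rest["YSI"] == rest["YSI"].max()).sum() > 1 or mod_by_ysi != mod_by_ssi:
        raise ValueError(
            "YSI and SSI disagree on the moderately tolerant group; "
            "assign labels manually"
        )
    sensitive = rest.drop(index=mod_by_ysi).index[0]
    return {tol_by_gyc: SALT_TOLERANT, mod_by_ysi: MODERATE, sensitive: SALT_SENSITIVE}


def label_groups(
    features: pd.DataFrame, cluster_ids: pd.Series, linkage_matrix: np.ndarray
) -> ToleranceGrouping:
    """Attach semantic tolerance labels to a 3-group clustering."""
    means_by_cluster = features.groupby(cluster_ids).mean()
    mapping = _rank_groups(means_by_cluster)
    labels = cluster_ids.map(mapping).rename("group")
    group_means = features.groupby(labels).mean()
    return ToleranceGrouping(
        labels=labels,
        cluster_ids=cluster_ids,
        linkage_matrix=linkage_matrix,
        group_means=group_means,
    )


def cluster_and_label(features: pd.DataFrame, k: int = 3) -> ToleranceGrouping:
    """Convenience: Ward clustering followed by semantic labelling."""
    ids, Z = ward_cluster(features, k=k)
    if k != 3:
        # no semantic labels outside the 3-group convention
        return ToleranceGrouping(
            labels=ids.astype(str).rename("group"),
            cluster_ids=ids,
            linkage_matrix=Z,
            group_means=features.groupby(ids).mean(),
        )
    return label_groups(features, ids, Z)


def linkage_to_newick(linkage_matrix: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string.

    Branch lengths are differences of merge heights, so the dendrogram
    can be re-plotted from the Newick alone.
    """
    names = list(leaf_names)
    n = len(names)

    def height(node):
        return 0.0 if node < n else linkage_matrix[node - n, 2]

    def render(node, parent_height):
        bl = parent_height - height(node)
        if node < n:
            return f"{names[node]}:{bl:.6g}"
        left, right = int(linkage_matrix[node - n, 0]), int(linkage_matrix[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

    root = n + len(linkage_matrix) - 1
    h = height(root)
    left, right = int(linkage_matrix[-1, 0]), int(linkage_matrix[-1, 1])
    return f"({render(left, h)},{render(right, h)});"
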