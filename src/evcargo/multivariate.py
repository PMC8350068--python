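"""Group-structure diagnostics: PCA and complete-linkage clustering.

Both operate on samples as observations. Missing values are resolved here
(and only here) by feature-wise mean imputation, since both methods need
complete data; statistical testing elsewhere never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from evcargo.datatypes import OmicsMatrix


@dataclass
class PcaResult:
    scores: pd.DataFrame                  # samples x components
    loadings: pd.DataFrame                # features x components
    explained_variance_fraction: np.ndarray

    def component_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class DendrogramResult:
    linkage_matrix: np.ndarray            # scipy linkage encoding
    labels: list[str]                     # item ids, lexicographic
    leaf_order: list[str]
    linkage: str = "complete"
    metric: str = "euclidean"

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Assign each item to one of ``n_clusters`` flat clusters."""
        assign = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-height differences."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            left, right, h, _ = self.linkage_matrix[node - n]
            parts = []
            for child in (int(left), int(right)):
                child_h = heights[child]
                parts.append(f"{render(child)}:{h - child_h:g}")
            heights[node] = h
            return "(" + ",".join(parts) + ")"

        for i in range(n, 2 * n - 1):
            heights[i] = self.linkage_matrix[i - n][2]
        return render(2 * n - 2) + ";" if n > 1 else self.labels[0] + ";"


def impute_feature_mean(m: OmicsMatrix) -> pd.DataFrame:
    """Replace missing cells by the feature's mean over observed samples.

    Features missing everywhere are dropped (nothing to impute from).
    """
    data = m.data.copy()
    all_missing = data.isna().all(axis=1)
    data = data.loc[~all_missing]
    means = data.mean(axis=1, skipna=True)
    return data.apply(lambda row: row.fillna(means[row.name]), axis=1)


def pca(m: OmicsMatrix, scaling: str = "unit_variance") -> PcaResult:
    """PCA of samples over features after centering (and autoscaling).

    ``scaling="unit_variance"`` (MetaboAnalyst-style autoscaling) divides
    each centered feature by its standard deviation; constant features are
    dropped there. ``scaling="center"`` centers only.
    """
    if scaling not in ("center", "unit_variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if len(m.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    data = impute_feature_mean(m)
    x = data.to_numpy(dtype=float).T  # samples x features
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ValueError("constant matrix: no variance to decompose")
    if scaling == "unit_variance":
        keep = sd > 0
        x = x[:, keep]
        features = data.index[keep]
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    else:
        features = data.index
        x = x - x.mean(axis=0)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(x)
    names = [f"PC{i + 1}" for i in range(n_comp)]
    total_var = x.var(axis=0, ddof=1).sum()
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=names),
        loadings=pd.DataFrame(model.components_.T, index=features, columns=names),
        explained_variance_fraction=model.explained_variance_ / total_var,
    )


def hierarchical_cluster(m: OmicsMatrix, axis: str = "samples") -> DendrogramResult:
    """Exact complete-linkage agglomeration with Euclidean distance.

    ``axis`` picks whether samples or features are clustered. Items are
    pre-sorted lexicographically by id, which fixes the tie-break when two
    merges share a height.
    """
    if axis not in ("samples", "features"):
        raise ValueError(f"unknown axis {axis!r}")
    data = impute_feature_mean(m)
    if axis == "samples":
        items = data.T
    else:
        items = data
    if items.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    items = items.loc[sorted(items.index)]
    dist = pdist(items.to_numpy(dtype=float), metric="euclidean")
    z = hierarchy.linkage(dist, method="complete")
    leaves = hierarchy.leaves_list(z)
    labels = list(items.index)
    return DendrogramResult(
        linkage_matrix=z,
        labels=labels,
        leaf_order=[labels[i] for i in leaves],
    )
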