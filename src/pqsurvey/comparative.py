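"""Classification of organisms by their TSS-relative PQS profiles.

Organisms are represented by their normalized distance-distribution vectors
(rows of a profile matrix). Hierarchical clustering uses the Ward
minimum-variance criterion in the "ward.D2" convention — plain Euclidean
distances handed to an algorithm that squares internally — and PCA operates
on column-mean-centered, unscaled vectors (the vectors are already on a
common normalized scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from sklearn.decomposition import PCA

from .tss_profiler import DistributionVector


@dataclass(slots=True)
class ProfileMatrix:
    """Rows = organisms, columns = distance bins (shared binning)."""

    organism_ids: list[str]
    matrix: np.ndarray
    bin_left_edges: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("profile matrix must be 2-D")
        if len(self.organism_ids) != self.matrix.shape[0]:
            raise ValueError("one row per organism required")
        if (self.matrix < 0).any():
            raise ValueError("profile entries must be non-negative")
        if self.labels is not None and len(self.labels) != len(self.organism_ids):
            raise ValueError("one label per organism required")

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[DistributionVector], labels: Sequence[str] | None = None
    ) -> "ProfileMatrix":
        if not vectors:
            raise ValueError("no vectors")
        for v in vectors[1:]:
            if v.bin_size != vectors[0].bin_size or v.window != vectors[0].window:
                raise ValueError("vectors must share bin_size and window")
        return cls(
            organism_ids=[v.organism_id for v in vectors],
            matrix=np.vstack([v.normalized for v in vectors]),
            bin_left_edges=vectors[0].bin_left_edges,
            labels=list(labels) if labels is not None else None,
        )


@dataclass(slots=True)
class Dendrogram:
    """Ward merge tree over organisms (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    organism_ids: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) at the k-cluster cut."""
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.organism_ids[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def hcluster(profiles: ProfileMatrix, method: str = "ward") -> Dendrogram:
    """Hierarchical clustering of profile rows (Euclidean metric).

    ``method="ward"`` follows the ward.D2 convention: the input is plain
    Euclidean distance and the Lance-Williams update squares internally, so
    merge heights are on the distance scale. Deterministic for a given row
    order.
    """
    if profiles.matrix.shape[0] < 2:
        raise ValueError("need at least 2 organisms to cluster")
    Z = linkage(profiles.matrix, method=method, metric="euclidean")
    return Dendrogram(linkage_matrix=Z, organism_ids=list(profiles.organism_ids))


@dataclass(slots=True)
class PCAResult:
    scores: np.ndarray  # (n_organisms, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_components, n_bins) loadings
    organism_ids: list[str]
    degenerate: bool = False


def pca(profiles: ProfileMatrix, n_components: int = 2) -> PCAResult:
    """PCA of mean-centered, unscaled profile vectors.

    Each component is oriented so that its largest-magnitude loading is
    positive (a deterministic sign convention). A constant matrix has zero
    total variance; it is flagged degenerate with all ratios set to 0.
    """
    X = profiles.matrix
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 organisms and >= 2 bins")
    n_components = min(n_components, n - 1, p)
    if np.allclose(X, X[0]):
        return PCAResult(
            scores=np.zeros((n, n_components)),
            explained_variance_ratio=np.zeros(n_components),
            components=np.zeros((n_components, p)),
            organism_ids=list(profiles.organism_ids),
            degenerate=True,
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    components = model.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    return PCAResult(
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        components=components,
        organism_ids=list(profiles.organism_ids),
    )


def classification_concordance(
    dendrogram: Dendrogram, labels: Sequence[str]
) -> int:
    """Count organisms whose cluster's majority label differs from their own.

    The tree is cut into k clusters, k = number of distinct labels; each
    cluster is assigned its majority label (ties broken toward the
    lexicographically smallest label) and mismatching members are counted.
    """
    if len(labels) != len(dendrogram.organism_ids):
        raise ValueError("one label per organism required")
    k = len(set(labels))
    if k == 1:
        return 0
    assignment = dendrogram.cut(k)
    violations = 0
    for cluster in np.unique(assignment):
        members = [i for i, c in enumerate(assignment) if c == cluster]
        counts: dict[str, int] = {}
        for i in members:
            counts[labels[i]] = counts.get(labels[i], 0) + 1
        top = max(counts.values())
        majority = min(l for l, c in counts.items() if c == top)
        violations += sum(1 for i in members if labels[i] != majority)
    return violations


# ---------------------------------------------------------------------------
# serialization

def read_profiles_tsv(path: str | Path, labels_path: str | Path | None = None) -> ProfileMatrix:
    """Read the wide-format profile TSV written by the profiler.

    ``labels_path`` optionally points to a two-column TSV
    (organism_id, label) assigning taxa for concordance analysis.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(
            labels_path, sep="\t", header=None, names=["organism_id", "label"]
        )
        mapping = dict(zip(lab["organism_id"].astype(str), lab["label"].astype(str)))
        labels = [mapping[str(o)] for o in df.index]
    return ProfileMatrix(
        organism_ids=[str(i) for i in df.index],
        matrix=df.to_numpy(dtype=float),
        bin_left_edges=np.array([float(c) for c in df.columns]),
        labels=labels,
    )


def write_pca_tsv(result: PCAResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        ncomp = result.scores.shape[1]
        header = "organism_id\t" + "\t".join(f"PC{k+1}" for k in range(ncomp))
        fh.write(header + "\n")
        for i, org in enumerate(result.organism_ids):
            fh.write(org + "\t" + "\t".join(f"{x:.8g}" for x in result.scores[i]) + "\n")
        fh.write(
            "#variance_ratio\t"
            + "\t".join(f"{x:.8g}" for x in result.explained_variance_ratio)
            + "\n"
        )
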