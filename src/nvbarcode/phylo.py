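"""Euclidean distances, single-linkage dendrograms, Newick export, barcode gap.

Distances are plain Euclidean on the raw (unstandardized) feature vectors:
the count and mean-position features are of order 1e2 and dominate, which is
the behaviour the analyses downstream rely on. An optional z-scaling flag
exists for users who want equalized feature contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    D: np.ndarray  # symmetric, zero diagonal

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """Single-linkage merge tree in scipy linkage-matrix form.

    ``linkage`` rows are (cluster_a, cluster_b, height, size); leaves are
    0..n-1 in ``leaf_ids`` order, internal node i+n is created by row i.
    """

    leaf_ids: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def distance_matrix(features, standardize: bool = False) -> DistanceMatrix:
    """All-pairs Euclidean distance matrix over feature rows."""
    if isinstance(features, pd.DataFrame):
        ids = tuple(str(i) for i in features.index)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        ids = tuple(f"seq{i}" for i in range(X.shape[0]))
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite features in rows: {[ids[i] for i in bad]}")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return DistanceMatrix(ids, squareform(pdist(X, metric="euclidean")))


def single_linkage(D: DistanceMatrix) -> Dendrogram:
    """Agglomerative single-linkage clustering of a distance matrix.

    Merge heights are the minimum inter-cluster pairwise distances; heights
    are non-decreasing (asserted — a theorem for single linkage).
    """
    if len(D.ids) < 2:
        raise ValueError("need at least two leaves")
    Z = hierarchy.linkage(D.condensed(), method="single")
    h = Z[:, 2]
    assert np.all(np.diff(h) >= -1e-12), "single-linkage heights must be monotone"
    return Dendrogram(D.ids, Z)


def _escape_newick(label: str) -> str:
    if any(c in label for c in " (),:;'[]\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram, branch_lengths: str = "height-derived") -> str:
    """Serialize a dendrogram as a Newick string.

    ``height-derived`` sets each branch length to (parent height - child
    height) / 2, so two leaves merged at height h sit at depth h/2 each and
    leaf-to-leaf path lengths reproduce merge heights on ultrametric input.
    ``none`` emits a cladogram without branch lengths. Duplicate leaf labels
    are suffixed with their index.
    """
    if branch_lengths not in ("height-derived", "none"):
        raise ValueError("branch_lengths must be 'height-derived' or 'none'")
    labels = list(tree.leaf_ids)
    if len(set(labels)) != len(labels):
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        labels = [f"{lab}_{i}" if lab in dupes else lab for i, lab in enumerate(labels)]
        import logging
        logging.getLogger(__name__).warning("duplicate leaf labels suffixed with index")
    node = hierarchy.to_tree(tree.linkage)

    def render(nd) -> str:
        if nd.is_leaf():
            return _escape_newick(labels[nd.id]), 0.0
        (ls, lh) = render(nd.left)
        (rs, rh) = render(nd.right)
        if branch_lengths == "height-derived":
            lb = (nd.dist - lh) / 2.0
            rb = (nd.dist - rh) / 2.0
            return f"({ls}:{lb:.10g},{rs}:{rb:.10g})", nd.dist
        return f"({ls},{rs})", nd.dist

    s, _ = render(node)
    return s + ";"


@dataclass(frozen=True)
class GapReport:
    """Intra- vs inter-group pairwise distance distributions at one rank."""

    level: str
    intra: np.ndarray
    inter: np.ndarray
    mean_intra: float | None
    mean_inter: float | None
    bin_width: float

    def histogram(self) -> pd.DataFrame:
        """Shared-bin histogram counts of the two distributions."""
        both = np.concatenate([self.intra, self.inter])
        if both.size == 0:
            return pd.DataFrame(columns=["bin_left", "bin_right", "intra", "inter"])
        hi = max(both.max(), self.bin_width)
        edges = np.arange(0.0, hi + 2 * self.bin_width, self.bin_width)
        ci, _ = np.histogram(self.intra, bins=edges)
        ce, _ = np.histogram(self.inter, bins=edges)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "intra": ci, "inter": ce})


def barcode_gap(features, labels, level: str = "species",
                groups: list[str] | None = None, bin_width: float = 5.0) -> GapReport:
    """Within- vs between-group Euclidean distance distributions.

    ``labels`` assigns each feature row to a group at the chosen rank; the
    barcode gap is present when mean_inter clearly exceeds mean_intra. All
    cross-group pairs enter the inter list (pairwise, not centroid). Means of
    empty lists are reported as None, never 0.
    """
    labels = np.asarray(labels)
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if groups is not None:
        mask = np.isin(labels, groups)
        X, labels = X[mask], labels[mask]
    if X.shape[0] < 2:
        raise ValueError("need at least two grouped rows")
    dist = squareform(pdist(X, metric="euclidean"))
    iu = np.triu_indices(X.shape[0], k=1)
    same = labels[iu[0]] == labels[iu[1]]
    intra = dist[iu][same]
    inter = dist[iu][~same]
    return GapReport(
        level=level,
        intra=intra,
        inter=inter,
        mean_intra=float(intra.mean()) if intra.size else None,
        mean_inter=float(inter.mean()) if inter.size else None,
        bin_width=bin_width,
    )
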