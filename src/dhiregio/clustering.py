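"""Two-stage regionalisation of DHI layers.

Stage one compresses the pixel cloud with a one-pass k-means++ (seeding by
the D² rule, then a single assignment sweep and a single centroid update);
stage two agglomerates the pre-cluster centroids with Ward's minimum-variance
linkage on Euclidean distances and cuts the dendrogram — statically at a
target count, or with a dynamic branch-pruning cut. Labels are mapped back
to the grid and sieved to a minimum map unit.

Features per valid pixel are the three DHIs plus absolute latitude (degrees
from the equator, a proxy for the global temperature gradient), each
winsorised and z-scored. Pixels with zero cumulative fPAR are masked from
the analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.ndimage import label as cc_label
from sklearn.cluster import KMeans, kmeans_plusplus
from sklearn.metrics import silhouette_samples

from .dhi import DhiLayers

log = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "PreClusters",
    "Dendrogram",
    "Regionalisation",
    "K_PRECLUSTERS",
    "build_feature_table",
    "kmeans_pp_precluster",
    "ward_dendrogram",
    "cut_tree",
    "label_map",
    "sieve",
    "validity_curve",
]

K_PRECLUSTERS = 867  # stage-one pre-cluster count (one per terrestrial ecoregion)

FEATURE_NAMES = ("dhi_cum", "dhi_min", "dhi_var", "abs_lat")


@dataclass
class FeatureTable:
    """Scaled per-pixel features with the bookkeeping to map back to the grid."""

    data: np.ndarray                  # (n_pixels, 4), z-scored
    pixel_index: np.ndarray           # flat indices into the grid
    grid_shape: tuple[int, int]
    centers: np.ndarray               # per-column mean used for scaling
    spreads: np.ndarray               # per-column sd used for scaling
    outlier_quantile: float
    clip_bounds: np.ndarray           # (2, 4) winsorisation bounds applied

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]


@dataclass
class PreClusters:
    k: int
    centroids: np.ndarray             # (k, n_features)
    sizes: np.ndarray                 # pixel counts, sum == n rows
    assignment: np.ndarray            # pre-cluster id per feature row

    def __post_init__(self) -> None:
        if self.sizes.sum() != self.assignment.size:
            raise ValueError("pre-cluster sizes do not sum to the row count")
        if np.any(self.sizes == 0):
            raise ValueError("empty pre-cluster present")


@dataclass
class Dendrogram:
    """Ward merge history over pre-cluster centroids (scipy linkage form)."""

    linkage: np.ndarray               # (n_leaves - 1, 4)
    n_leaves: int
    weighted: bool = False

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing (Ward)")

    def to_json(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "weighted": self.weighted,
            "merges": self.linkage.tolist(),
        }


@dataclass
class Regionalisation:
    """Integer label raster; 0 marks masked pixels."""

    labels: np.ndarray
    n_clusters: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.unique(self.labels)
        if vals.min() < 0 or vals.max() > self.n_clusters:
            raise ValueError("labels outside {0} ∪ [1, n_clusters]")


# ---------------------------------------------------------------------------
# stage 0: features

def build_feature_table(
    dhi: DhiLayers,
    latitude: np.ndarray,
    outlier_quantile: float = 0.001,
) -> FeatureTable:
    """Assemble, winsorise and z-score the clustering features.

    Pixels that are invalid in the DHI layers or have zero cumulative fPAR
    are excluded. Latitude enters as absolute degrees from the equator.
    Outliers are clipped (winsorised) at the (q, 1−q) quantiles per column
    rather than deleted, so every retained pixel keeps a feature row; columns
    are then centred and scaled to unit sample standard deviation.
    """
    if latitude.shape != dhi.valid_mask.shape:
        raise ValueError("latitude grid does not match DHI grid")
    keep = dhi.valid_mask & (dhi.cumulative > 0)
    if not keep.any():
        raise ValueError("all pixels masked; nothing to cluster")
    cols = [
        dhi.cumulative[keep],
        dhi.minimum[keep],
        dhi.variation[keep],
        np.abs(latitude[keep]),
    ]
    data = np.column_stack(cols).astype(float)

    q = float(outlier_quantile)
    if not 0.0 <= q < 0.5:
        raise ValueError("outlier_quantile must lie in [0, 0.5)")
    lo = np.quantile(data, q, axis=0)
    hi = np.quantile(data, 1.0 - q, axis=0)
    data = np.clip(data, lo, hi)

    centers = data.mean(axis=0)
    spreads = data.std(axis=0, ddof=1)
    spreads = np.where(spreads > 0, spreads, 1.0)  # constant column stays 0
    data = (data - centers) / spreads
    return FeatureTable(
        data=data,
        pixel_index=np.flatnonzero(keep),
        grid_shape=keep.shape,
        centers=centers,
        spreads=spreads,
        outlier_quantile=q,
        clip_bounds=np.vstack([lo, hi]),
    )


# ---------------------------------------------------------------------------
# stage 1: one-pass k-means++

def kmeans_pp_precluster(
    features: FeatureTable,
    k: int = K_PRECLUSTERS,
    seed: int = 0,
    full: bool = False,
) -> PreClusters:
    """Pre-cluster the feature rows with a one-pass k-means++.

    Centroids are seeded by the k-means++ D² sampling rule; then one full
    nearest-centroid assignment pass and one centroid-update pass. Ties in
    the assignment go to the lowest centroid index. Pre-clusters left empty
    after the single pass are dropped with a warning. With ``full=True``,
    Lloyd iterations run to convergence instead (not the default contract).
    """
    X = features.data
    n_distinct = np.unique(X, axis=0).shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct feature rows")

    if full:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
        assign = km.fit_predict(X)
        centroids = km.cluster_centers_
    else:
        centroids, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
        assign = _nearest_centroid(X, centroids)
        # single centroid-update pass
        for j in range(k):
            members = assign == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
        assign = _nearest_centroid(X, centroids)

    sizes = np.bincount(assign, minlength=k)
    if np.any(sizes == 0):
        empties = int((sizes == 0).sum())
        log.warning("dropping %d empty pre-clusters", empties)
        keep = sizes > 0
        remap = np.cumsum(keep) - 1
        centroids = centroids[keep]
        assign = remap[assign]
        sizes = sizes[keep]
    return PreClusters(
        k=len(sizes), centroids=centroids, sizes=sizes, assignment=assign
    )


def _nearest_centroid(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Chunked argmin of Euclidean distance; argmin takes the lowest index
    on ties."""
    out = np.empty(X.shape[0], dtype=np.int64)
    c2 = (centroids**2).sum(axis=1)
    step = max(1, 2_000_000 // max(1, centroids.shape[0]))
    for start in range(0, X.shape[0], step):
        chunk = X[start:start + step]
        d2 = c2[None, :] - 2.0 * chunk @ centroids.T
        out[start:start + step] = np.argmin(d2, axis=1)
    return out


# ---------------------------------------------------------------------------
# stage 2: Ward agglomeration

def ward_dendrogram(pre: PreClusters, weighting: str = "none") -> Dendrogram:
    """Ward minimum-variance agglomeration of the pre-cluster centroids.

    ``weighting="none"`` treats every centroid as one observation (the
    default, matching distances "between pre-cluster centroids");
    ``weighting="size"`` carries pre-cluster pixel counts through the
    Lance–Williams updates, so populous pre-clusters resist merging.
    """
    if pre.k < 2:
        raise ValueError("need at least 2 centroids to agglomerate")
    if weighting == "none":
        Z = hierarchy.linkage(pre.centroids, method="ward")
        return Dendrogram(linkage=Z, n_leaves=pre.k, weighted=False)
    if weighting != "size":
        raise ValueError("weighting must be 'none' or 'size'")
    Z = _weighted_ward(pre.centroids, pre.sizes.astype(float))
    return Dendrogram(linkage=Z, n_leaves=pre.k, weighted=True)


def _weighted_ward(centroids: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Ward linkage with non-unit initial weights via Lance–Williams.

    Merge cost between clusters A, B with weights wA, wB and centroids
    cA, cB is sqrt(2 wA wB / (wA + wB)) * ||cA − cB|| (the scipy height
    convention at unit weights).
    """
    n = centroids.shape[0]
    w = w.copy()
    # squared-cost matrix
    diff = centroids[:, None, :] - centroids[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    ww = w[:, None] * w[None, :]
    cost2 = 2.0 * ww / (w[:, None] + w[None, :]) * d2
    np.fill_diagonal(cost2, np.inf)

    active = np.ones(n, dtype=bool)
    ids = np.arange(n)          # dendrogram node id of each active cluster
    sizes = np.ones(n)          # leaf counts for the linkage 4th column
    Z = np.zeros((n - 1, 4))
    for m in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], cost2, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        hij = np.sqrt(masked[i, j])
        Z[m] = (min(ids[i], ids[j]), max(ids[i], ids[j]), hij, sizes[i] + sizes[j])
        # Lance–Williams update for Ward on squared costs, with weights
        wi, wj = w[i], w[j]
        for k in np.flatnonzero(active):
            if k in (i, j):
                continue
            wk = w[k]
            tot = wi + wj + wk
            new = (
                (wi + wk) / tot * cost2[i, k]
                + (wj + wk) / tot * cost2[j, k]
                - wk / tot * cost2[i, j]
            )
            cost2[i, k] = cost2[k, i] = new
        active[j] = False
        w[i] = wi + wj
        ids[i] = n + m
        sizes[i] = Z[m, 3]
        cost2[j, :] = cost2[:, j] = np.inf
    # enforce exact monotonicity against floating-point jitter
    Z[:, 2] = np.maximum.accumulate(Z[:, 2])
    return Z


# ---------------------------------------------------------------------------
# dendrogram cuts

def cut_tree(
    dend: Dendrogram,
    target_k: int,
    method: str = "static",
    dynamic_params: dict | None = None,
) -> np.ndarray:
    """Map each leaf (pre-cluster) to one of ``target_k`` clusters.

    ``static`` cuts the merge sequence so exactly ``target_k`` groups
    remain. ``dynamic`` performs a hybrid branch-pruning cut — clusters are
    branches below a cut height, and branches smaller than a minimum size
    are merged into their nearest (centroid-distance in merge-height terms)
    surviving branch — searching a grid of (height quantile, minimum branch
    size) until the cluster count equals ``target_k``, and falling back to
    the static cut with a warning when no parameter pair reaches it.
    Returned labels are 0-based consecutive integers.
    """
    if not 1 <= target_k <= dend.n_leaves:
        raise ValueError(
            f"target_k={target_k} outside [1, {dend.n_leaves}]"
        )
    if method == "static":
        return _static_cut(dend, target_k)
    if method != "dynamic":
        raise ValueError("method must be 'static' or 'dynamic'")

    params = dynamic_params or {}
    min_sizes = params.get("min_sizes", (8, 5, 3, 2, 1))
    n_heights = int(params.get("n_heights", max(4 * target_k, 20)))
    heights = np.sort(dend.linkage[:, 2])
    # candidate cut heights: midpoints between the top merge heights, so each
    # candidate changes the branch count by one
    top = heights[-min(n_heights, heights.size):]
    cuts = np.concatenate([[top[-1] * 1.01 + 1e-12],
                           (top[1:] + top[:-1]) / 2.0])[::-1]
    for min_size in min_sizes:
        for cut_h in cuts:
            labels = _dynamic_cut(dend, float(cut_h), int(min_size))
            if labels.max() + 1 == target_k:
                return labels
    warnings.warn(
        f"dynamic cut could not reach {target_k} clusters; using static cut",
        RuntimeWarning,
    )
    return _static_cut(dend, target_k)


def _static_cut(dend: Dendrogram, target_k: int) -> np.ndarray:
    labels = hierarchy.cut_tree(dend.linkage, n_clusters=target_k).ravel()
    return _canonical(labels)


def _dynamic_cut(dend: Dendrogram, cut_h: float, min_size: int) -> np.ndarray:
    """One hybrid cut: branches below ``cut_h``, undersized ones pruned."""
    labels = hierarchy.fcluster(dend.linkage, t=cut_h, criterion="distance") - 1
    labels = _canonical(labels)
    # prune undersized branches into the branch they merge with lowest
    sizes = np.bincount(labels)
    while (sizes < min_size).any() and len(sizes) > 1:
        small = int(np.argmin(np.where(sizes < min_size, sizes, np.inf)))
        # nearest surviving branch: the one whose leaves join `small`'s
        # leaves lowest in the dendrogram
        merge_h = _branch_join_heights(dend, labels, small)
        merge_h[small] = np.inf
        tgt = int(np.argmin(merge_h))
        labels[labels == small] = tgt
        labels = _canonical(labels)
        sizes = np.bincount(labels)
    return labels


def _branch_join_heights(
    dend: Dendrogram, labels: np.ndarray, branch: int
) -> np.ndarray:
    """Height at which each label's subtree first joins ``branch``'s leaves."""
    n = dend.n_leaves
    n_lab = labels.max() + 1
    # cluster membership per dendrogram node, propagated up the merges
    member = [frozenset([labels[i]]) for i in range(n)]
    out = np.full(n_lab, np.inf)
    for m, (a, b, h, _) in enumerate(dend.linkage):
        sa, sb = member[int(a)], member[int(b)]
        if branch in sa and not (branch in sb):
            for lab in sb:
                out[lab] = min(out[lab], h)
        if branch in sb and not (branch in sa):
            for lab in sa:
                out[lab] = min(out[lab], h)
        member.append(sa | sb)
    return out


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k−1 in order of first appearance."""
    _, canon = np.unique(labels, return_inverse=True)
    return canon


# ---------------------------------------------------------------------------
# back to the map

def label_map(
    features: FeatureTable,
    pre: PreClusters,
    mapping: np.ndarray,
    provenance: dict | None = None,
) -> Regionalisation:
    """Compose pixel → pre-cluster → cluster into a label raster.

    Clusters are renumbered 1..n by descending pixel count (stable,
    comparable outputs); masked pixels stay 0.
    """
    mapping = np.asarray(mapping)
    if mapping.shape[0] != pre.k:
        raise ValueError("mapping does not cover every pre-cluster")
    pix_labels = mapping[pre.assignment]
    counts = np.bincount(pix_labels)
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    raster = np.zeros(features.grid_shape, dtype=np.int32)
    raster.ravel()[features.pixel_index] = rank[pix_labels]
    return Regionalisation(
        labels=raster,
        n_clusters=int(mapping.max() + 1),
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# sieve

_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def sieve(
    region: Regionalisation, min_pixels: int = 20, connectivity: int = 8
) -> Regionalisation:
    """Dissolve connected label components smaller than ``min_pixels``.

    Each undersized component (4- or 8-connectivity) takes the modal label
    of its border neighbours, ties going to the lower label id; the pass
    repeats until no undersized component remains or no further change is
    possible. Masked (0) pixels are never reassigned and never absorb
    anything; components enclosed entirely by mask are left alone. Strict
    "fewer than" rule: a component of exactly ``min_pixels`` is retained.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    struct = _STRUCTS[connectivity]
    labels = region.labels.copy()
    for _ in range(labels.size):  # bound; components shrink far faster
        changed = False
        comp = _per_label_components(labels, struct)
        sizes = np.bincount(comp.ravel())
        small = [c for c in range(1, sizes.size) if 0 < sizes[c] < min_pixels]
        # dissolve smallest first so ties resolve deterministically
        small.sort(key=lambda c: (sizes[c], c))
        for c in small:
            m = comp == c
            if not m.any():        # may have been absorbed this pass
                continue
            border = _dilate(m, struct) & ~m
            neigh = labels[border]
            neigh = neigh[neigh > 0]
            if neigh.size == 0:
                continue           # enclosed by mask; nothing to absorb into
            counts = np.bincount(neigh)
            target = int(np.argmax(counts))  # argmax takes the lower id on ties
            if target == labels[m][0]:
                continue
            labels[m] = target
            changed = True
        if not changed:
            break
        # recompute components after a full pass; loop until fixed point
        comp2 = _per_label_components(labels, struct)
        sizes2 = np.bincount(comp2.ravel())
        if not np.any((sizes2[1:] > 0) & (sizes2[1:] < min_pixels)):
            break
    prov = dict(region.provenance)
    prov["sieve"] = {"min_pixels": min_pixels, "connectivity": connectivity}
    return Regionalisation(
        labels=labels, n_clusters=region.n_clusters, provenance=prov
    )


def _per_label_components(labels: np.ndarray, struct: np.ndarray) -> np.ndarray:
    """Connected components within each label value; 0 stays 0."""
    out = np.zeros_like(labels, dtype=np.int64)
    next_id = 1
    for val in np.unique(labels):
        if val == 0:
            continue
        comp, n = cc_label(labels == val, structure=struct)
        out[comp > 0] = comp[comp > 0] + (next_id - 1)
        next_id += n
    return out


def _dilate(mask: np.ndarray, struct: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, structure=struct)


# ---------------------------------------------------------------------------
# validity metrics

def validity_curve(
    pre: PreClusters,
    dend: Dendrogram,
    k_range,
    size_weighted: bool = False,
) -> "pd.DataFrame":
    """Cluster validity metrics along static dendrogram cuts.

    Per candidate k: mean silhouette over pre-cluster centroids (optionally
    weighted by pre-cluster pixel counts), total within-cluster sum of
    squares of the centroids, and the ratio of mean between- to mean
    within-cluster centroid distance. k < 2 is excluded with a warning.
    """
    import pandas as pd

    rows = []
    for k in k_range:
        if k < 2:
            warnings.warn("silhouette undefined for k < 2; excluded", RuntimeWarning)
            continue
        if k > dend.n_leaves:
            continue
        labels = _static_cut(dend, int(k))
        X = pre.centroids
        if k == dend.n_leaves:
            sil = np.nan  # every centroid a singleton
        else:
            s = silhouette_samples(X, labels)
            weights = pre.sizes if size_weighted else np.ones(pre.k)
            sil = float(np.average(s, weights=weights))
        wss = 0.0
        within, between = [], []
        for c in range(int(labels.max()) + 1):
            pts = X[labels == c]
            centre = pts.mean(axis=0)
            wss += float(((pts - centre) ** 2).sum())
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(pre.k, 1)
        within_d = d[iu][same[iu]]
        between_d = d[iu][~same[iu]]
        ratio = (
            float(between_d.mean() / within_d.mean())
            if within_d.size and between_d.size and within_d.mean() > 0
            else np.nan
        )
        rows.append(
            {"k": int(k), "silhouette": sil, "wss": wss, "between_within_ratio": ratio}
        )
    return pd.DataFrame(rows)
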