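"""Model-style front end for the two-stage regionalisation.

`DhiRegionalization` holds the data (DHI layers + latitude) and the tuning
parameters; `fit()` runs feature construction, one-pass k-means++
pre-clustering, Ward agglomeration, the dendrogram cut and the sieve, and
returns a `RegionalizationResults` carrying the label raster, the full
provenance (centroids, dendrogram, mapping), validity diagnostics, and
evaluation helpers::

    model = DhiRegionalization(dhi, latitude, k_pre=867, n_clusters=14)
    res = model.fit(seed=0)
    print(res.summary())
    res.homogeneity(richness)        # within-region dispersion of a layer
    res.discriminant_power(richness) # between-region separability
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering as cl
from . import evaluation as ev
from .dhi import DhiLayers

__all__ = ["DhiRegionalization", "RegionalizationResults"]


class DhiRegionalization:
    """Two-stage unsupervised regionalisation of a DHI surface.

    Parameters
    ----------
    dhi : DhiLayers
        The three-band DHI surface with validity mask.
    latitude : ndarray
        Per-pixel latitude in degrees (same grid).
    n_clusters : int
        Final cluster count (the published analysis used 14 and 40).
    k_pre : int
        Stage-one pre-cluster count (default 867).
    cut : {"dynamic", "static"}
        Dendrogram cut method; dynamic falls back to static when the
        parameter search cannot reach ``n_clusters``.
    outlier_quantile, ward_weighting, sieve_min_pixels, connectivity
        Feature winsorisation quantile, Ward weighting mode, minimum map
        unit in pixels (0 disables the sieve), and sieve connectivity.
    """

    def __init__(
        self,
        dhi: DhiLayers,
        latitude: np.ndarray,
        n_clusters: int = 14,
        k_pre: int = cl.K_PRECLUSTERS,
        cut: str = "dynamic",
        outlier_quantile: float = 0.001,
        ward_weighting: str = "none",
        sieve_min_pixels: int = 20,
        connectivity: int = 8,
        one_pass: bool = True,
    ) -> None:
        self.dhi = dhi
        self.latitude = latitude
        self.n_clusters = n_clusters
        self.k_pre = k_pre
        self.cut = cut
        self.outlier_quantile = outlier_quantile
        self.ward_weighting = ward_weighting
        self.sieve_min_pixels = sieve_min_pixels
        self.connectivity = connectivity
        self.one_pass = one_pass

    @classmethod
    def from_stack(cls, stack, latitude, qa_threshold=83, min_valid_steps=23,
                   **kwargs):
        """Build directly from a phenology stack (composites + DHIs first)."""
        from .dhi import dhi_stack

        return cls(dhi_stack(stack, qa_threshold, min_valid_steps), latitude,
                   **kwargs)

    def fit(self, seed: int = 0) -> "RegionalizationResults":
        features = cl.build_feature_table(
            self.dhi, self.latitude, self.outlier_quantile
        )
        k_pre = min(self.k_pre, np.unique(features.data, axis=0).shape[0])
        pre = cl.kmeans_pp_precluster(
            features, k=k_pre, seed=seed, full=not self.one_pass
        )
        dend = cl.ward_dendrogram(pre, weighting=self.ward_weighting)
        mapping = cl.cut_tree(dend, self.n_clusters, method=self.cut)
        provenance = {
            "n_clusters": self.n_clusters,
            "k_pre": int(pre.k),
            "cut": self.cut,
            "ward_weighting": self.ward_weighting,
            "outlier_quantile": self.outlier_quantile,
            "sieve_min_pixels": self.sieve_min_pixels,
            "connectivity": self.connectivity,
            "one_pass": self.one_pass,
            "seed": seed,
        }
        region = cl.label_map(features, pre, mapping, provenance=provenance)
        if self.sieve_min_pixels > 0:
            region = cl.sieve(region, self.sieve_min_pixels, self.connectivity)
        return RegionalizationResults(
            model=self, features=features, preclusters=pre, dendrogram=dend,
            mapping=mapping, regionalisation=region, seed=seed,
        )


@dataclass
class RegionalizationResults:
    """Fitted regionalisation: label raster plus everything used to make it."""

    model: DhiRegionalization
    features: cl.FeatureTable
    preclusters: cl.PreClusters
    dendrogram: cl.Dendrogram
    mapping: np.ndarray
    regionalisation: cl.Regionalisation
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return self.regionalisation.labels

    @property
    def n_clusters(self) -> int:
        return int(self.regionalisation.n_clusters)

    # ------------------------------------------------------------------ diag
    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster pixel counts and mean raw DHI/latitude values."""
        dhi = self.model.dhi
        rows = []
        for c in range(1, self.n_clusters + 1):
            m = self.labels == c
            if not m.any():
                continue
            rows.append({
                "cluster": c,
                "pixels": int(m.sum()),
                "dhi_cum": float(np.nanmean(dhi.cumulative[m])),
                "dhi_min": float(np.nanmean(dhi.minimum[m])),
                "dhi_var": float(np.nanmean(dhi.variation[m])),
                "abs_lat": float(np.mean(np.abs(self.model.latitude[m]))),
            })
        return pd.DataFrame(rows).set_index("cluster")

    def validity_curve(self, k_range=None, size_weighted: bool = False):
        if k_range is None:
            k_range = range(2, min(41, self.preclusters.k))
        return cl.validity_curve(self.preclusters, self.dendrogram, k_range,
                                 size_weighted=size_weighted)

    def percentile_rankings(self) -> pd.DataFrame:
        tab = self.cluster_table()[["dhi_cum", "dhi_min", "dhi_var"]]
        return ev.percentile_rankings(tab)

    def combined_z(self) -> pd.Series:
        tab = self.cluster_table()[["dhi_cum", "dhi_min", "dhi_var"]]
        return ev.combined_z(tab)

    # ------------------------------------------------------------------ eval
    def homogeneity(self, layer: np.ndarray, **kwargs) -> ev.HomogeneityReport:
        return ev.homogeneity_report(self.labels, layer, **kwargs)

    def discriminant_power(self, layer: np.ndarray, **kwargs):
        return ev.discriminant_power(self.labels, layer, **kwargs)

    def overlap(self, other_labels: np.ndarray, cell_area=1.0, **kwargs):
        return ev.overlap_table(self.labels, other_labels, cell_area, **kwargs)

    # ------------------------------------------------------------------ plot
    def plot_map(self, ax=None):
        """Label raster as a categorical map (masked pixels black)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib import colors

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        cmap = plt.get_cmap("tab20", max(self.n_clusters, 1))
        cmap = colors.ListedColormap(
            [(0, 0, 0)] + [cmap(i) for i in range(self.n_clusters)]
        )
        ax.imshow(self.labels, cmap=cmap, interpolation="nearest",
                  vmin=0, vmax=self.n_clusters)
        ax.set_title(f"DHI regionalisation (k={self.n_clusters})")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        tab = self.cluster_table()
        prov = self.regionalisation.provenance
        lines = [
            "DHI Regionalisation Results",
            "=" * 60,
            f"clusters:        {self.n_clusters}",
            f"pre-clusters:    {self.preclusters.k}",
            f"valid pixels:    {self.features.n_pixels}",
            f"cut method:      {self.model.cut}",
            f"sieve:           <{self.model.sieve_min_pixels} px, "
            f"{self.model.connectivity}-connectivity",
            f"seed:            {self.seed}",
            "-" * 60,
            tab.to_string(float_format=lambda v: f"{v:.3f}"),
            "=" * 60,
        ]
        _ = prov
        return "\n".join(lines)
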