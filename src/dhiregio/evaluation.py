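"""Quantitative comparison of regionalisations.

Within-region homogeneity is summarised by three scale-free dispersion
measures computed per region and averaged (unweighted) across regions:

* CV — sample standard deviation divided by the mean;
* IQR-CV — interquartile range divided by the median (linear-interpolation
  quantiles);
* L-CV — ratio of the second to the first sample L-moment, estimated via
  probability-weighted moments; a robust dispersion measure from regional
  frequency analysis.

Between-region *discriminant power* is the proportion of region pairs whose
sampled values differ significantly under Games-Howell pairwise tests
(Welch-type standard errors, studentized-range reference distribution; by
default applied to global ranks, the nonparametric variant). The sampling
(n per region) and testing cycle repeats many times to give a distribution
of proportions.

Spatial correspondence between two label rasters is summarised as two-way
percent-area overlap tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "cv",
    "iqr_cv",
    "l_cv",
    "HomogeneityReport",
    "homogeneity_report",
    "games_howell",
    "DiscriminantPowerResult",
    "discriminant_power",
    "OverlapTable",
    "overlap_table",
    "percentile_rankings",
    "combined_z",
    "PERCENTILE_BINS",
]

MEASURES = ("CV", "IQR-CV", "L-CV")


# ---------------------------------------------------------------------------
# dispersion measures

def cv(values) -> float:
    """Coefficient of variation: sample (n−1) standard deviation over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m)


def iqr_cv(values) -> float:
    """Interquartile range over median, linear-interpolation quantiles."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("IQR-CV needs at least 4 values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    if med == 0:
        raise ValueError("IQR-CV undefined for zero median")
    return float((q3 - q1) / med)


def l_cv(values) -> float:
    """L-moment ratio t = l2/l1 via probability-weighted moments.

    On the sorted sample x(1..n): b0 = mean, b1 = Σ (i−1)/(n−1) x(i) / n,
    l1 = b0, l2 = 2 b1 − b0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("L-CV needs at least 2 values")
    b0 = x.mean()
    b1 = np.sum((np.arange(n) / (n - 1)) * x) / n
    l1, l2 = b0, 2 * b1 - b0
    if l1 == 0:
        raise ValueError("L-CV undefined for zero first L-moment")
    return float(l2 / l1)


_MEASURE_FUNCS = {"CV": cv, "IQR-CV": iqr_cv, "L-CV": l_cv}


# ---------------------------------------------------------------------------
# homogeneity

@dataclass
class HomogeneityReport:
    """Per-region dispersion values and their unweighted across-region means."""

    per_region: pd.DataFrame   # columns: region, measure, value
    means: dict[str, float]    # measure -> mean across regions
    excluded: list[int] = field(default_factory=list)


def homogeneity_report(
    labels: np.ndarray,
    layer: np.ndarray,
    measures=MEASURES,
    min_region_pixels: int = 4,
) -> HomogeneityReport:
    """Dispersion of ``layer`` within each region of the label raster.

    Regions with fewer than ``min_region_pixels`` finite values, or where a
    measure is undefined (zero mean/median), are skipped for that measure
    and logged. The summary is the unweighted mean of each measure across
    the regions that yielded a value.
    """
    if labels.shape != layer.shape:
        raise ValueError("label and layer grids differ")
    rows = []
    excluded: list[int] = []
    region_ids = [int(r) for r in np.unique(labels) if r != 0]
    for r in region_ids:
        vals = layer[labels == r]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_region_pixels:
            excluded.append(r)
            log.debug("region %d below pixel threshold; excluded", r)
            continue
        for meas in measures:
            try:
                v = _MEASURE_FUNCS[meas](vals)
            except ValueError as e:
                log.warning("region %d, %s skipped: %s", r, meas, e)
                continue
            rows.append({"region": r, "measure": meas, "value": v})
    df = pd.DataFrame(rows, columns=["region", "measure", "value"])
    if df.empty:
        raise ValueError("no eligible region for any measure")
    means = df.groupby("measure")["value"].mean().to_dict()
    return HomogeneityReport(per_region=df, means=means, excluded=excluded)


# ---------------------------------------------------------------------------
# Games-Howell

def games_howell(
    groups: list[np.ndarray], alpha: float = 0.05, on_ranks: bool = True
) -> pd.DataFrame:
    """Games-Howell pairwise comparisons across ``groups``.

    For each pair: Welch-type standard error √(s²ᵢ/nᵢ + s²ⱼ/nⱼ),
    Welch–Satterthwaite degrees of freedom, studentized-range statistic
    q = |Δ|·√2/SE, and p from the studentized-range distribution with
    k = number of groups. With ``on_ranks`` (default) all values are
    replaced by their global midranks first — the nonparametric variant.

    Degenerate pairs (both variances zero) record p = 1 when the means are
    equal and p = 0 otherwise.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if on_ranks:
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)  # midranks on ties
        out, start = [], 0
        for g in groups:
            out.append(ranks[start:start + g.size])
            start += g.size
        groups = out

    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = m[i] - m[j]
            se2 = v[i] / n[i] + v[j] / n[j]
            if se2 == 0:
                p = 1.0 if diff == 0 else 0.0
                log.warning("degenerate pair (%d, %d): zero variance, p=%g", i, j, p)
                rows.append(
                    {"i": i, "j": j, "diff": diff, "se": 0.0, "df": np.nan,
                     "q": np.inf if diff else 0.0, "p": p,
                     "significant": p < alpha}
                )
                continue
            se = np.sqrt(se2)
            df = se2**2 / (
                (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
            )
            q = abs(diff) * np.sqrt(2.0) / se
            p = float(stats.studentized_range.sf(q, k, df))
            p = min(max(p, 0.0), 1.0)
            rows.append(
                {"i": i, "j": j, "diff": diff, "se": se, "df": df, "q": q,
                 "p": p, "significant": p < alpha}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discriminant power

@dataclass
class DiscriminantPowerResult:
    """Distribution of significant-pair proportions over resampling cycles."""

    proportions: np.ndarray
    n_per_region: int
    reps: int
    alpha: float
    seed: int
    on_ranks: bool
    regions: list[int]

    @property
    def median(self) -> float:
        return float(np.median(self.proportions))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.proportions, [25, 75])
        return (float(lo), float(hi))

    @property
    def mean(self) -> float:
        return float(self.proportions.mean())


def discriminant_power(
    labels: np.ndarray,
    layer: np.ndarray,
    n_per_region: int = 100,
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    on_ranks: bool = True,
    small_region_mode: str = "replace",
) -> DiscriminantPowerResult:
    """Repeatedly sample each region and count significant Games-Howell pairs.

    Per repetition: draw ``n_per_region`` values per region (without
    replacement; regions smaller than that are sampled *with* replacement
    when ``small_region_mode="replace"``, or dropped with ``"exclude"``),
    run Games-Howell over all sampled regions, and record the proportion of
    the R(R−1)/2 pairs significant at ``alpha``.
    """
    if labels.shape != layer.shape:
        raise ValueError("label and layer grids differ")
    region_ids = [int(r) for r in np.unique(labels) if r != 0]
    pools = {}
    for r in region_ids:
        vals = layer[labels == r]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            log.warning("region %d has <2 values; excluded", r)
            continue
        if vals.size < n_per_region:
            if small_region_mode == "exclude":
                log.warning("region %d smaller than n=%d; excluded", r, n_per_region)
                continue
            log.warning(
                "region %d smaller than n=%d; sampling with replacement",
                r, n_per_region,
            )
        pools[r] = vals
    if len(pools) < 2:
        raise ValueError("fewer than 2 usable regions")

    rng = np.random.default_rng(seed)
    props = np.empty(reps)
    for rep in range(reps):
        samples = [
            rng.choice(v, size=n_per_region, replace=v.size < n_per_region)
            for v in pools.values()
        ]
        table = games_howell(samples, alpha=alpha, on_ranks=on_ranks)
        props[rep] = table["significant"].mean()
    return DiscriminantPowerResult(
        proportions=props,
        n_per_region=n_per_region,
        reps=reps,
        alpha=alpha,
        seed=seed,
        on_ranks=on_ranks,
        regions=sorted(pools),
    )


# ---------------------------------------------------------------------------
# spatial overlap

@dataclass
class OverlapTable:
    """Two-way percent-area overlap between regionalisations A and B."""

    a_by_b: pd.DataFrame       # rows: A regions; % of each A region per B region
    b_by_a: pd.DataFrame       # rows: B regions; % of each B region per A region
    display_threshold: float = 10.0

    def rendered(self, which: str = "a_by_b") -> pd.DataFrame:
        """Copy with entries below the display threshold blanked (NaN)."""
        df = getattr(self, which).copy()
        return df.where(df >= self.display_threshold)


def overlap_table(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    cell_area: np.ndarray | float = 1.0,
    display_threshold: float = 10.0,
) -> OverlapTable:
    """Cross-tabulate the areas shared by two label rasters.

    Only pixels labelled (non-zero) in *both* rasters participate. Rows of
    ``a_by_b`` give the percent of each A-region's area falling in each
    B-region (rows sum to 100); ``b_by_a`` is the transpose-normalised view.
    Entries below ``display_threshold`` are blanked only at render time —
    the full matrices are retained.
    """
    if labels_a.shape != labels_b.shape:
        raise ValueError("label grids differ")
    area = np.broadcast_to(np.asarray(cell_area, dtype=float), labels_a.shape)
    joint = (labels_a > 0) & (labels_b > 0)
    if not joint.any():
        raise ValueError("empty joint mask")
    a = labels_a[joint]
    b = labels_b[joint]
    w = area[joint]
    a_ids = np.unique(a)
    b_ids = np.unique(b)
    mat = np.zeros((a_ids.size, b_ids.size))
    ai = np.searchsorted(a_ids, a)
    bi = np.searchsorted(b_ids, b)
    np.add.at(mat, (ai, bi), w)
    a_by_b = pd.DataFrame(
        100.0 * mat / mat.sum(axis=1, keepdims=True), index=a_ids, columns=b_ids
    )
    b_by_a = pd.DataFrame(
        (100.0 * mat / mat.sum(axis=0, keepdims=True)).T, index=b_ids, columns=a_ids
    )
    return OverlapTable(a_by_b=a_by_b, b_by_a=b_by_a,
                        display_threshold=display_threshold)


# ---------------------------------------------------------------------------
# cluster summaries

# seven discrete percentile ranges: a 40–60 median band, three below, three above
PERCENTILE_BINS = (0.0, 10.0, 25.0, 40.0, 60.0, 75.0, 90.0, 100.0)
_BIN_LABELS = ("<10", "10-25", "25-40", "40-60", "60-75", "75-90", ">90")


def percentile_rankings(cluster_means: pd.DataFrame) -> pd.DataFrame:
    """Bin each cluster's mean into one of seven percentile ranges per variable.

    Percentiles among the cluster means use the midrank rule
    (r − 0.5)/n · 100, so equal means land together in the 40–60 median
    band. Input: DataFrame indexed by cluster, one column per variable;
    output has the same shape with string bin labels.
    """
    if cluster_means.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    out = {}
    n = cluster_means.shape[0]
    for col in cluster_means.columns:
        r = stats.rankdata(cluster_means[col])  # midranks
        pct = (r - 0.5) / n * 100.0
        idx = np.clip(
            np.searchsorted(PERCENTILE_BINS, pct, side="right") - 1,
            0, len(_BIN_LABELS) - 1,
        )
        out[col] = [_BIN_LABELS[i] for i in idx]
    return pd.DataFrame(out, index=cluster_means.index)


def combined_z(cluster_means: pd.DataFrame) -> pd.Series:
    """Combined DHI score per cluster: z(cumulative) + z(minimum) − z(variation).

    Each DHI is z-scored across clusters (sample sd); a component with zero
    spread contributes 0 and is logged. Expects columns named
    ``dhi_cum``, ``dhi_min``, ``dhi_var``.
    """
    if cluster_means.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    score = pd.Series(0.0, index=cluster_means.index)
    for col, sign in (("dhi_cum", 1.0), ("dhi_min", 1.0), ("dhi_var", -1.0)):
        x = cluster_means[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0:
            log.warning("component %s has zero spread; contributes 0", col)
            continue
        score = score + sign * (x - x.mean()) / sd
    return score
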