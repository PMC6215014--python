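"""Dynamic Habitat Indices from multi-year fPAR phenology stacks.

The three DHIs summarise a year of vegetation productivity per pixel:

* ``cumulative`` — integrated annual productive capacity, here the plain sum
  of the composite phenology curve over its valid steps (step-sum units);
* ``minimum`` — the lowest composite fPAR of the year;
* ``variation`` — intra-annual seasonality, the coefficient of variation
  (sample standard deviation / mean) of the composite curve.

The composite phenology curve is, per time step, the median across years of
the quality-screened observations: an observation participates only if its
integer quality value passes the strict rule ``qa < qa_threshold`` (default
83). Compositing the median over many years suppresses snow/cloud noise
before the indices are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhenologyStack",
    "CompositeCurve",
    "DhiTriple",
    "DhiLayers",
    "QA_THRESHOLD",
    "MIN_VALID_STEPS",
    "composite_phenology",
    "compute_dhi",
    "dhi_stack",
]

QA_THRESHOLD = 83     # strict less-than pass rule
MIN_VALID_STEPS = 23  # half of the 46-step year


@dataclass
class PhenologyStack:
    """fPAR observations ``values[..., step, year]`` with parallel QA integers.

    The leading axes are pixel axes: ``()`` for a single pixel, ``(n,)`` for a
    pixel table, ``(rows, cols)`` for a raster. NaN marks a missing
    observation independent of its QA value.
    """

    values: np.ndarray
    qa: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.qa = np.asarray(self.qa)
        if self.values.size == 0:
            raise ValueError("empty phenology stack")
        if self.values.shape != self.qa.shape:
            raise ValueError(
                f"values shape {self.values.shape} != qa shape {self.qa.shape}"
            )
        if self.values.ndim < 2:
            raise ValueError("stack needs at least (step, year) axes")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("fPAR values must lie in [0, 1]")

    @property
    def n_steps(self) -> int:
        return self.values.shape[-2]

    @property
    def n_years(self) -> int:
        return self.values.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.values.shape[:-2]


@dataclass
class CompositeCurve:
    """Median phenology curve(s): ``median_fpar[..., step]``.

    ``valid`` flags steps with at least one passing observation;
    ``n_valid_obs`` counts the passing observations behind each median.
    """

    median_fpar: np.ndarray
    valid: np.ndarray
    n_valid_obs: np.ndarray


@dataclass(frozen=True)
class DhiTriple:
    cumulative: float
    minimum: float
    variation: float


@dataclass
class DhiLayers:
    """Per-pixel DHI bands on a raster grid, plus the validity mask.

    Band order is fixed: (cumulative, minimum, variation). Invalid pixels
    hold NaN in every band.
    """

    cumulative: np.ndarray
    minimum: np.ndarray
    variation: np.ndarray
    valid_mask: np.ndarray
    min_valid_steps: int = MIN_VALID_STEPS

    band_names = ("dhi_cum", "dhi_min", "dhi_var")

    @property
    def bands(self) -> np.ndarray:
        return np.stack([self.cumulative, self.minimum, self.variation])


def composite_phenology(
    stack: PhenologyStack, qa_threshold: int = QA_THRESHOLD
) -> CompositeCurve:
    """Median-composite the stack across years with QA screening.

    For every (pixel, step), the median over years of observations with
    ``qa < qa_threshold``; with an even number of passing observations the
    median is the midpoint of the two central values. Steps where no
    observation passes are flagged invalid (NaN median).
    """
    passing = (stack.qa < qa_threshold) & np.isfinite(stack.values)
    vals = np.where(passing, stack.values, np.nan)
    n_valid = passing.sum(axis=-1)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            median = np.nanmedian(vals, axis=-1)
    return CompositeCurve(median_fpar=median, valid=n_valid > 0, n_valid_obs=n_valid)


def compute_dhi(
    curve: CompositeCurve, min_valid_steps: int = MIN_VALID_STEPS
) -> DhiLayers:
    """Reduce composite curve(s) to the DHI triple per pixel.

    cumulative = sum of the curve over valid steps; minimum = min over valid
    steps; variation = sample (n−1) standard deviation / mean. A pixel is
    invalid when it has fewer than ``min_valid_steps`` valid steps or a zero
    curve mean (variation undefined; such pixels are also masked downstream
    as zero-cumulative).
    """
    m = np.asarray(curve.median_fpar, dtype=float)
    valid = np.asarray(curve.valid, dtype=bool)
    vals = np.where(valid, m, np.nan)
    n_valid = valid.sum(axis=-1)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cumulative = np.nansum(vals, axis=-1)
        minimum = np.nanmin(np.where(valid, m, np.inf), axis=-1)
        mean = np.nanmean(vals, axis=-1)
        sd = np.nanstd(vals, axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        variation = sd / mean

    ok = (n_valid >= max(int(min_valid_steps), 2)) & np.isfinite(mean) & (mean > 0)
    cumulative = np.where(ok, cumulative, np.nan)
    minimum = np.where(ok & np.isfinite(minimum), minimum, np.nan)
    variation = np.where(ok, variation, np.nan)
    return DhiLayers(
        cumulative=cumulative,
        minimum=minimum,
        variation=variation,
        valid_mask=ok,
        min_valid_steps=min_valid_steps,
    )


def dhi_triple(
    curve: CompositeCurve, min_valid_steps: int = MIN_VALID_STEPS
) -> DhiTriple | None:
    """Scalar convenience for a single-pixel curve; None when invalid."""
    layers = compute_dhi(curve, min_valid_steps)
    if not np.all(layers.valid_mask):
        return None
    return DhiTriple(
        float(layers.cumulative), float(layers.minimum), float(layers.variation)
    )


def dhi_stack(
    stack: PhenologyStack,
    qa_threshold: int = QA_THRESHOLD,
    min_valid_steps: int = MIN_VALID_STEPS,
) -> DhiLayers:
    """QA-screen, composite and reduce a gridded stack to DhiLayers."""
    curve = composite_phenology(stack, qa_threshold)
    return compute_dhi(curve, min_valid_steps)
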