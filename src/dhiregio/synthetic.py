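"""Synthetic worlds with known ground-truth regionalisation.

The generator emulates the statistical structure the regionalisation
pipeline assumes, at desk scale and with a known answer:

* a latitude-banded map of phenology *archetypes* (the ground truth the
  clustering should recover), each archetype a sinusoid family
  ``fpar(step) = baseline + amplitude * sin(2π step / n_steps + phase)``
  spanning a tropics-like constant-high family, strongly seasonal
  boreal-like families, and a desert-like constant-low family;
* multi-year 46-step fPAR observations = archetype template + Gaussian
  noise, clipped to [0, 1], with integer QA values that fail the strict
  ``qa < 83`` screen with a configurable dropout probability;
* species ranges whose placement density scales with cumulative
  productivity (available-energy coupling), rasterised to richness counts;
* canopy height as an affine function of cumulative productivity minus
  seasonality, plus noise;
* a comparator regionalisation made by perturbing the truth map along its
  region boundaries — a stand-in for an independently drawn conventional
  regionalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .dhi import PhenologyStack, dhi_stack
from .io_layers import GridSpec, RangeSet

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "archetype_params",
    "phenology_template",
    "make_world",
    "make_species_ranges",
    "perturb_regionalisation",
]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of one synthetic world; defaults are the study conditions."""

    grid_rows: int = 64
    grid_cols: int = 128
    lat_range: tuple[float, float] = (-60.0, 60.0)
    n_archetypes: int = 6
    n_years: int = 12          # observations per step, as in the composite
    n_steps: int = 46          # 8-day steps in a year
    noise_sd: float = 0.03    # fPAR units, per observation
    qa_dropout_prob: float = 0.1
    n_species: int = 3000  # 1000 per taxon: overall richness then reaches the
                           # hundreds-per-cell magnitude of real range stacks,
                           # keeping ratio dispersion measures well-behaved
    energy_coupling: float = 1.0   # 0 = uniform ranges, 1 = fully energy-driven
    comparator_perturbation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.n_archetypes < 2:
            raise ValueError("n_archetypes must be >= 2")
        for name in ("qa_dropout_prob", "energy_coupling", "comparator_perturbation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_species < 0:
            raise ValueError("n_species must be non-negative")
        if self.lat_range[0] >= self.lat_range[1]:
            raise ValueError("lat_range must be (min, max) with min < max")

    def grid_spec(self) -> GridSpec:
        cell = (self.lat_range[1] - self.lat_range[0]) / self.grid_rows
        return GridSpec(
            rows=self.grid_rows,
            cols=self.grid_cols,
            origin=(0.0, self.lat_range[0]),
            cell_size=cell,
        )


@dataclass
class SyntheticWorld:
    """All generated layers plus the ground truth behind them."""

    config: WorldConfig
    grid: GridSpec
    truth_labels: np.ndarray        # int, values 1..n_archetypes
    latitude: np.ndarray            # degrees, per pixel
    phenology: PhenologyStack
    richness: dict[str, np.ndarray]  # per-taxon count rasters + "overall"
    canopy_height: np.ndarray        # metres
    comparator_labels: np.ndarray    # perturbed copy of truth_labels
    ranges: RangeSet | None = None

    def __post_init__(self) -> None:
        shp = self.truth_labels.shape
        for name in ("latitude", "canopy_height", "comparator_labels"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} does not share the grid shape {shp}")
        if self.phenology.grid_shape != shp:
            raise ValueError("phenology does not share the grid shape")
        lab = self.truth_labels
        if lab.min() < 1 or lab.max() > self.config.n_archetypes:
            raise ValueError("truth labels out of [1, n_archetypes]")


# ---------------------------------------------------------------------------
# archetype templates

def archetype_params(config: WorldConfig) -> np.ndarray:
    """(baseline, amplitude, phase) per archetype, id order 1..n.

    Archetype 1 is tropics-like (high constant fPAR, tiny amplitude), the
    last is desert-like (low constant); intermediate archetypes descend in
    baseline while amplitude peaks mid-gradient (boreal-like strong
    seasonality). Baselines are strictly decreasing, so the archetypes are
    pairwise distinct in cumulative productivity by construction, and
    baseline ± amplitude stays inside [0, 1] so the noiseless template never
    clips.
    """
    g = config.n_archetypes
    t = np.linspace(0.0, 1.0, g)
    baseline = 0.85 - 0.70 * t
    amplitude = 0.04 + 0.36 * np.sin(np.pi * t)
    amplitude = np.minimum(amplitude, np.minimum(baseline, 1 - baseline) - 0.01)
    phase = np.zeros(g)
    return np.column_stack([baseline, amplitude, phase])


def phenology_template(
    archetype_id: int, step: int | np.ndarray, config: WorldConfig
) -> float | np.ndarray:
    """Noiseless template fPAR of one archetype at one (or many) step(s)."""
    if not 1 <= archetype_id <= config.n_archetypes:
        raise ValueError(f"unknown archetype id {archetype_id}")
    step = np.asarray(step)
    if np.any(step < 0) or np.any(step >= config.n_steps):
        raise ValueError("step out of range")
    b, a, ph = archetype_params(config)[archetype_id - 1]
    val = b + a * np.sin(2 * np.pi * step / config.n_steps + ph)
    out = np.clip(val, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# world assembly

def _truth_bands(config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """Latitude-banded archetype map with wiggly band boundaries.

    Bands are equal-height row blocks (archetype 1 northernmost); each
    internal boundary is displaced by a smooth per-column sinusoid so region
    outlines are patchy rather than ruler-straight, keeping latitude
    informative without making bands trivial stripes.
    """
    rows, cols, g = config.grid_rows, config.grid_cols, config.n_archetypes
    edges = np.linspace(0, rows, g + 1)[1:-1]  # internal boundaries, row units
    wiggle_amp = max(1.0, 0.25 * rows / g)
    col = np.arange(cols)
    boundary = np.empty((g - 1, cols))
    for i, e in enumerate(edges):
        f1, f2 = rng.uniform(1, 3, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        w = np.sin(2 * np.pi * f1 * col / cols + p1) + 0.5 * np.sin(
            2 * np.pi * f2 * col / cols + p2
        )
        boundary[i] = e + wiggle_amp * w
    boundary = np.sort(boundary, axis=0)  # keep bands ordered
    row = np.arange(rows)[:, None, None]          # (rows, 1, 1)
    labels = 1 + (row >= boundary[None, :, :]).sum(axis=1)
    return labels.astype(np.int32)


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world; identical (config, seed) pairs
    give bit-identical worlds."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid_spec()
    latitude = grid.latitude_raster()

    truth = _truth_bands(config, rng)

    # per-pixel multi-year observations: template + noise, clipped
    params = archetype_params(config)
    steps = np.arange(config.n_steps)
    templates = params[:, 0:1] + params[:, 1:2] * np.sin(
        2 * np.pi * steps[None, :] / config.n_steps + params[:, 2:3]
    )
    templates = np.clip(templates, 0.0, 1.0)  # (g, n_steps)
    base = templates[truth - 1]               # (rows, cols, n_steps)
    shape = (*truth.shape, config.n_steps, config.n_years)
    values = base[..., None] + rng.normal(0.0, config.noise_sd, size=shape)
    np.clip(values, 0.0, 1.0, out=values)

    # QA: passing observations draw integers < 83, dropouts >= 83
    dropped = rng.random(shape) < config.qa_dropout_prob
    qa = np.where(
        dropped,
        rng.integers(83, 255, size=shape),
        rng.integers(0, 83, size=shape),
    ).astype(np.int16)
    phen = PhenologyStack(values=values, qa=qa)

    # cumulative productivity of the *templates* drives richness and height
    cum_template = templates.sum(axis=1)[truth - 1]

    world = SyntheticWorld(
        config=config,
        grid=grid,
        truth_labels=truth,
        latitude=latitude,
        phenology=phen,
        richness={"overall": np.zeros(truth.shape, dtype=np.int32)},
        canopy_height=np.zeros(truth.shape),
        comparator_labels=perturb_regionalisation(
            truth, config.comparator_perturbation, seed=int(rng.integers(2**31))
        ),
    )

    ranges, richness = make_species_ranges(world, config, _rng=rng)
    world.ranges = ranges
    world.richness = richness

    # canopy height: taller where cumulative productivity is high and
    # seasonality low (coefficients are generator config, not claims)
    seasonality = templates.std(axis=1, ddof=1)[truth - 1] / np.maximum(
        templates.mean(axis=1)[truth - 1], 1e-9
    )
    height = 2.0 + 1.5 * cum_template - 8.0 * seasonality
    height = height + rng.normal(0.0, 1.5, size=height.shape)
    world.canopy_height = np.clip(height, 0.0, None)
    return world


# ---------------------------------------------------------------------------
# species ranges

def make_species_ranges(
    world: SyntheticWorld,
    config: WorldConfig,
    _rng: np.random.Generator | None = None,
) -> tuple[RangeSet, dict[str, np.ndarray]]:
    """Draw contiguous (disk) species ranges and count richness per cell.

    Each species picks a centre cell with probability proportional to
    ``(1 − c) + c · P/mean(P)`` where ``P`` is local cumulative template
    productivity and ``c`` the energy coupling: at ``c = 0`` placement is
    uniform, at ``c = 1`` fully proportional to available energy. The range
    is a disk of random radius around the centre; richness is the per-cell
    count of covering disks (a disk covers a cell when it reaches the cell
    centre, consistent with disk membership on the grid). Returns the disk
    polygons (for GeoJSON export) alongside the richness rasters.
    """
    rng = _rng if _rng is not None else np.random.default_rng(config.seed + 1)
    grid = world.grid
    rows, cols = grid.shape
    params = archetype_params(config)
    steps = np.arange(config.n_steps)
    templates = np.clip(
        params[:, 0:1]
        + params[:, 1:2] * np.sin(2 * np.pi * steps[None, :] / config.n_steps),
        0, 1,
    )
    cum = templates.sum(axis=1)[world.truth_labels - 1]

    c = config.energy_coupling
    w = (1.0 - c) + c * cum / cum.mean()
    p = (w / w.sum()).ravel()

    taxa_names = ("amphibians", "birds", "mammals")
    richness = {t: np.zeros(grid.shape, dtype=np.int32) for t in taxa_names}
    polys, sids, taxa = [], [], []

    if config.n_species > 0:
        # right-skewed range sizes: many small ranges, few large ones
        radii_px = np.clip(
            rng.lognormal(mean=np.log(6.0), sigma=0.8, size=config.n_species),
            2.0, 0.35 * min(rows, cols),
        )
        # Centres may fall up to one range-radius beyond the top/bottom grid
        # edge (weights edge-replicated): the window then behaves like a cut
        # from a larger stationary world, so edge cells are not artificially
        # species-poor relative to the interior of their band.
        centres_r = np.empty(config.n_species, dtype=int)
        centres_c = np.empty(config.n_species, dtype=int)
        pads = np.ceil(radii_px).astype(int)
        for pad in np.unique(pads):
            sel = np.flatnonzero(pads == pad)
            w_ext = np.vstack([
                np.repeat(w[:1], pad, axis=0), w, np.repeat(w[-1:], pad, axis=0)
            ])
            p_ext = (w_ext / w_ext.sum()).ravel()
            flat = rng.choice(w_ext.size, size=sel.size, p=p_ext)
            centres_r[sel] = flat // cols - pad
            centres_c[sel] = flat % cols
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        lon0, lat0 = grid.origin
        top = lat0 + rows * grid.cell_size
        for i in range(config.n_species):
            r0, c0 = int(centres_r[i]), int(centres_c[i])
            taxon = taxa_names[i % len(taxa_names)]
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radii_px[i] ** 2
            richness[taxon] += inside.astype(np.int32)
            cx = lon0 + (c0 + 0.5) * grid.cell_size
            cy = top - (r0 + 0.5) * grid.cell_size
            polys.append(
                shapely.Point(cx, cy).buffer(radii_px[i] * grid.cell_size, 32)
            )
            sids.append(f"sp{i:04d}")
            taxa.append(taxon)

    richness["overall"] = sum(richness[t] for t in taxa_names)
    richness["overall"] = np.asarray(richness["overall"], dtype=np.int32)
    return RangeSet(polys, sids, taxa), richness


# ---------------------------------------------------------------------------
# comparator regionalisation

def perturb_regionalisation(
    truth: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Degrade a label map by flipping blocks along region boundaries.

    Boundary-adjacent 3×3 blocks are reassigned to the label of a
    neighbouring region until about ``fraction`` of pixels disagree with the
    input; the label set never grows. ``fraction = 0`` returns the input
    unchanged (a copy).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    labels = np.array(truth, copy=True)
    if fraction == 0.0:
        return labels
    rng = np.random.default_rng(seed)
    rows, cols = labels.shape
    target = int(round(fraction * labels.size))
    max_iter = 50 * labels.size
    it = 0
    while np.count_nonzero(labels != truth) < target and it < max_iter:
        it += 1
        # boundary pixels of the *current* map keep the perturbation growing
        # outward from the original region edges
        diff = np.zeros_like(labels, dtype=bool)
        diff[:-1, :] |= labels[:-1, :] != labels[1:, :]
        diff[1:, :] |= labels[1:, :] != labels[:-1, :]
        diff[:, :-1] |= labels[:, :-1] != labels[:, 1:]
        diff[:, 1:] |= labels[:, 1:] != labels[:, :-1]
        cand = np.flatnonzero(diff)
        if cand.size == 0:
            break
        n_flip = max(1, (target - np.count_nonzero(labels != truth)) // 9)
        picks = rng.choice(cand, size=min(n_flip, cand.size), replace=False)
        for flat in picks:
            r, c = divmod(int(flat), cols)
            r0, r1 = max(0, r - 1), min(rows, r + 2)
            c0, c1 = max(0, c - 1), min(cols, c + 2)
            neigh = labels[r0:r1, c0:c1]
            other = neigh[neigh != labels[r, c]]
            if other.size == 0:
                continue
            labels[r0:r1, c0:c1] = other[rng.integers(other.size)]
    return labels
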