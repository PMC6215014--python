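# dhiregio

Productivity-based ecological regionalisation from satellite phenology.

Ecoregion and biome maps underpin conservation planning, but conventional
regionalisations are drawn by expert judgement and are hard to revise.
`dhiregio` implements a fully quantitative alternative: it summarises a
multi-year time series of fPAR (the fraction of photosynthetically active
radiation absorbed by vegetation, a per-pixel productivity proxy in [0, 1])
into the three **Dynamic Habitat Indices (DHIs)**, partitions the landscape
by unsupervised clustering of those indices, and quantifies how well any
regionalisation — this one or a conventional comparator — explains
independent biodiversity layers such as species richness and canopy height.

## The method

**Dynamic Habitat Indices.** For each pixel, a composite phenology curve is
built per 8-day time step as the median across years of quality-screened
observations (an observation passes only if its integer QA value satisfies
`qa < 83`). From the composite curve `f(1..T)` (T = 46 steps):

- cumulative DHI: `DHI_cum = Σ_t f(t)` — integrated annual productive capacity;
- minimum DHI: `DHI_min = min_t f(t)` — the year's productivity floor;
- variation DHI: `DHI_var = sd(f) / mean(f)` — intra-annual seasonality
  (coefficient of variation, sample sd).

Pixels with too few valid steps or zero cumulative fPAR are masked.

**Two-stage clustering.** Features per valid pixel are the three DHIs plus
absolute latitude, winsorised and z-scored. Stage one compresses the pixel
cloud into pre-clusters (default 867) with a one-pass k-means++ (D² seeding,
one assignment sweep, one centroid update). Stage two agglomerates the
pre-cluster centroids with Ward's minimum-variance linkage on Euclidean
distances; the dendrogram is cut — dynamically (branch pruning with a
parameter search) or statically — into the target number of clusters, mapped
back to the grid, and sieved to a minimum map unit of 20 contiguous pixels.

**Evaluation.** Within-region homogeneity: CV (sd/mean), IQR-CV
(interquartile range/median) and L-CV (second/first L-moment, estimated via
probability-weighted moments), averaged across regions. Between-region
*discriminant power*: the proportion of region pairs whose random samples
(n = 100 per region) differ significantly under Games-Howell pairwise tests
on ranks (p < 0.05), repeated 500 times. Spatial correspondence between two
regionalisations: two-way percent-area overlap tables with cos-latitude
area weighting.

Because real MODIS/IUCN inputs are not required, the package ships a
synthetic-world generator with a known ground-truth regionalisation
(latitude-banded phenology archetypes), energy-coupled species ranges, a
productivity-driven canopy-height layer, and a boundary-perturbed comparator
map — so the whole pipeline can be exercised and validated end to end.

## Worked example

```python
from dhiregio import WorldConfig, make_world, DhiRegionalization
from dhiregio.dhi import dhi_stack
from dhiregio.evaluation import homogeneity_report

cfg = WorldConfig(seed=7)                      # 64×128 world, 6 archetypes
world = make_world(cfg)
layers = dhi_stack(world.phenology)            # QA screen, composite, DHIs
model = DhiRegionalization(layers, world.latitude, n_clusters=6, k_pre=150)
res = model.fit(seed=7)
print(res.summary())
```

```
DHI Regionalisation Results
============================================================
clusters:        6
pre-clusters:    150
valid pixels:    8192
cut method:      dynamic
sieve:           <20 px, 8-connectivity
seed:            7
------------------------------------------------------------
         pixels  dhi_cum  dhi_min  dhi_var  abs_lat
cluster
1          1467   32.659    0.449    0.254   28.687
2          1462   13.338    0.029    0.622   30.627
3          1403   39.100    0.795    0.036   49.376
4          1313   19.779    0.040    0.636   10.525
5          1280    6.902    0.095    0.204   50.117
6          1267   26.223    0.180    0.480    9.200
============================================================
```

The table lists, per recovered cluster, its pixel count and mean raw
feature values: cluster 3 is the tropics-like archetype (high cumulative and
minimum productivity, near-zero seasonality), cluster 5 the desert-like one
(low productivity, low seasonality). On this world the recovered labels
match the generating archetypes exactly (adjusted Rand index 1.0), and the
recovered clusters are more homogeneous in overall species richness than
the 30%-perturbed comparator map:

```python
rich = world.richness["overall"].astype(float)
homogeneity_report(res.labels, rich).means["CV"]               # 0.199
homogeneity_report(world.comparator_labels, rich).means["CV"]  # 0.236
```

A full run (synthetic world → DHIs → clustering → evaluation, with all
intermediate layers, reports and a DHI RGB render written to disk) is one
command:

```sh
dhiregio run --config examples/demo.yaml --out artifacts/
```

See `docs/methods.md` for the model's assumptions, parameter defaults and
numerical conventions.

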