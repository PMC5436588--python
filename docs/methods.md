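# Methods

`forestscape` reconstructs and analyses the spatio-temporal dynamics of
natural forest cover (NFC) on a gridded landscape. This note documents the
models and procedures, the choices made where the design was genuinely
open, and what the synthetic test landscape does and does not show.

## The analysis frame

All geometry lives in a single projected planar CRS in metres; geographic
inputs must be projected before use. A square lattice (default 5 × 5 km)
is laid over the land mask, with its origin snapped down to a multiple of
the cell size from the mask's bounding-box lower-left corner (recorded in
output metadata). Cells with less than half their area on land are
excluded — the conventional guard against coastal slivers biasing cover
proportions low. The boundary is closed: `land_fraction >= 0.5` is
retained.

Per-cell NFC is the exact polygon-overlay fraction
`area(cell ∩ forest) / area(cell)`; overlapping forest polygons are
unioned first. Raster covariates (elevation ELE in m, slope SLO in
degrees, climatic potential productivity CPP in kg hm⁻² a⁻¹) are averaged
over the pixels whose centroids fall inside each cell, with the half-open
rule `[x0, x1) × [y0, y1)` resolving edge ties so each pixel counts in at
most one cell. Topography and climate are treated as static over the
study horizon; only the road network and the forest respond to time.

## Road indicators

Roads carry a two-class hierarchy — `main` (trunk/highway-grade) and
`secondary` (cart and rural roads) — and a period stamp. Four per-cell,
per-class indicators summarise network density and configuration:

| indicator | definition | unit |
|---|---|---|
| SRL | clipped road length in the cell / cell area | km km⁻² |
| DNR | centroid distance to the nearest road of the class, network-wide | km |
| NON | planar-graph nodes in the cell / cell area | km⁻² |
| MND | mean degree of those nodes (÷ cell area by default) | km⁻² |

The planar graph is built by noding all segment crossings and dissolving
degree-2 pass-through vertices, so nodes are junctions (degree ≥ 3) and
terminals (degree 1). Exact duplicate geometries are dropped before
noding. MND's per-area convention follows the published unit ("ea km⁻²");
the plain mean degree is available via `mnd_per_area=False`. A cell class
with no segments anywhere yields DNR = NaN — an explicit missing flag,
not a cap — which the models impute as 1.5 × the largest observed DNR of
that class plus a 0/1 missingness indicator column ("no road anywhere" is
informatively far).

## Cover models, NMSE, and hindcasting

NFC is regressed on (ELE, SLO, CPP) plus the eight road indicators with
one model pooled over the observed periods (no period feature; a cell's
static covariates appear once per period row). Four interchangeable
backends are provided: ordinary least squares, an additive spline model
(per-feature cubic B-splines with a light ridge penalty), a single-hidden-
layer perceptron on standardised inputs, and a random forest (500 trees,
⌊p/3⌋ features per split, minimum leaf 5 — conventional regression-forest
defaults). Predictions are clipped to [0, 1].

Backends are compared by normalized mean square error,

    NMSE = MSE / population variance of the observations,

so 0 is perfect and 1 matches the constant-mean predictor; values above 1
(worse than the mean) are possible and reported as such — [0, 1] is the
useful range, not a hard bound. The comparison uses 10-fold
cross-validation with folds assigned *by cell*, so all periods of a cell
share a fold and a cell's static covariates never straddle the split;
NMSE is computed on the pooled out-of-fold predictions. The lowest-NMSE
backend is refit on all observed rows and applied to the road metrics of
unobserved periods (with the static covariates unchanged) to hindcast
historical cover.

## Change analysis

For a period pair (t1, t2) the change rate is ΔNFC per decade,
`(NFC(t2) − NFC(t1)) / (Δt / 10 yr)`; raw ΔNFC and the relative change
ΔNFC/NFC(t1) (cells at zero dropped) are available variants. Three
analyses follow:

* **Indicator power.** The rate is regressed on each indicator's change,
  one at a time; explanatory power is the adjusted R² in percent, with
  two-sided F-test p-values and no multiple-testing correction.
* **Variation partition.** Adjusted R² from three multiple regressions —
  main-road deltas, secondary-road deltas, all eight — decomposes into
  unique and shared components by the standard partition algebra
  (`unique_main + unique_secondary + shared = combined`, an exact
  identity). Collinear columns are dropped with a warning; a group whose
  deltas are all zero (a frozen road class) contributes zero explained
  variance by convention.
* **Vulnerability.** The rate is regressed on initial cover NFC(t1); a
  positive slope means low-cover cells lose cover fastest.

OLS summaries are computed in closed form (normal equations via a
rank-guarded least-squares solve) with F-distribution p-values; they are
cross-checked against statsmodels in the test suite.

## Hot spots

Local clustering of a change field uses the Getis-Ord Gi* statistic with
self-inclusive binary weights:

    Gi* = [Σⱼ wᵢⱼxⱼ − X̄ Σⱼ wᵢⱼ] / ( S · sqrt{ [n Σⱼ wᵢⱼ² − (Σⱼ wᵢⱼ)²] / (n−1) } )

where S is the global population standard deviation. Gi* is already a
z-score; cells are classed hot/cold at the two-sided normal quantiles
1.645 / 1.960 / 2.576. The default weights are queen contiguity with
self-weight 1; rook and distance-band schemes are available, and the
scheme is recorded in output metadata since published maps rarely
document it. An exactly constant field makes the statistic undefined and
is flagged as such rather than returned as zeros. On a cover-*change*
field, negative clusters are deforestation hot spots.

## The synthetic island

Because digitized historical forest and road maps are rarely
redistributable, the package ships a generator whose defaults emulate a
large tropical island (~31,400 km², ~1,260 retained cells, four 20-year
periods):

* **Terrain.** A radial dome (max 1,850 m) plus Gaussian-filtered noise
  whose amplitude grows with the dome — a rugged central massif and flat
  coastal plains, giving realistic cell-mean slopes of ~1–8°. Slope is
  computed by central finite differences.
* **Productivity.** Highest in the humid eastern lowlands, declining with
  elevation and to the west.
* **Roads.** Towns are sampled preferentially in the lowlands; main roads
  connect them along a minimum-spanning-tree backbone with later extra
  links, and long links detour radially outward (~0.85 R) the way real
  trunk roads skirt a massif. Secondary roads branch off the network as
  short lowland spurs. Networks are strictly nested over periods; the
  secondary class is frozen after the second period while main roads keep
  growing — reproducing the published qualitative Table-style pattern of
  saturating rural networks and ever-densifying trunk networks. Default
  per-period means (SRL_main ≈ 0.15→0.52 km km⁻², SRL_sec ≈ 0.18→0.36)
  sit near the published magnitudes.
* **Cover.** True NFC is inverse-logit of a linear predictor in scaled
  covariates — positive in elevation and slope, negative in productivity
  and road density — plus a road × slope interaction whose damping of
  road harm saturates at 5° cell-mean slope (steep cells are shielded,
  never *gaining* forest from roads). i.i.d. Gaussian noise (default
  sd 0.05) is added per cell-period and the result clipped to [0, 1];
  more than 5 % clipping triggers a warning. With the default
  coefficients the island-mean cover declines strictly (~0.50 → 0.39)
  and, because road growth concentrates where cover is already low, the
  change rate correlates positively with initial cover.
* **Forest masks.** Per-period 100-m binary rasters reproduce each cell's
  NFC to within half a pixel-area quantum (pixel fraction 1/2500 ≈
  4 × 10⁻⁴) by foresting the top-k pixels of a smooth "suitability" field
  shared across periods — so masks nest as cover declines and the
  polygon-overlay round trip is exact up to quantisation.

Every stage draws from an independent stream derived from the scenario
seed via a stable CRC, so a fixed seed gives bit-identical outputs across
processes.

**What the generator does not emulate:** spatially autocorrelated
*noise* (spatial structure enters only through covariates — deliberate,
to keep recovery experiments interpretable), socio-economic road-growth
dynamics, typhoon or cultural ("geomantic forest") effects, digitisation
artifacts beyond exact duplicates, and datum/projection error. Passing
recovery tests therefore demonstrates the pipeline's correctness and
statistical behaviour under a known data-generating process, not accuracy
on any particular real landscape.

## Numerical and design notes

* GeoJSON is written/read directly (shapely geometries + `json`); rasters
  use the plain-text ESRI ASCII grid format. Both keep the whole artifact
  text-only and dependency-light.
* Geometry tolerances: vertex snapping at 10⁻⁶ m during planarization;
  overlay conservation holds to ~10⁻⁹ relative.
* Degenerate inputs fail loudly: constant observations in NMSE, constant
  predictors in OLS, constant fields in Gi*, empty grids, unknown road
  classes.
* Problem sizes in the test suite: unit tests run on a 32-km-radius
  island (~50 cells); the acceptance tests and `scripts/acceptance.py`
  use the full default scenario (~1,260 cells), chosen to sit inside the
  published study's cell-count range.
* The published study's absolute numbers (total cover 41.4 % → 24.2 %,
  1,360 cells, specific adjusted R² values) depend on undeposited
  digitized maps and are not reproducible from first principles; the
  pipeline targets the qualitative structure — declining cover, main
  roads outranking secondary roads, low-cover vulnerability, coherent
  hot-spot geography — which the synthetic defaults do reproduce.

## Known limitations

* `DNR` uses Euclidean, not network, distance.
* The additive and neural backends are deliberately thin comparators, not
  tuned models; no hyperparameter search is performed anywhere.
* Hindcasts carry no uncertainty intervals.
* Gi* significance is reported without false-discovery-rate correction,
  matching common GIS practice.
* Exact replication of any published hot-spot map is impossible even with
  the original data, since the weights scheme and significance convention
  of the original GIS runs are undocumented.
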