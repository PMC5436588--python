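"""Synthetic tropical island with terrain, roads, and declining forest cover.

Every downstream stage of the pipeline is exercised on a fully synthetic
landscape with known ground truth: a roughly circular island with a central
mountain massif, a climatic-productivity surface, a two-class road network
that densifies over four periods (main roads keep growing; the secondary
network saturates after the second period), and per-cell natural forest
cover (NFC) generated from a known monotone function of the covariates plus
bounded noise.

The generative rule for forest cover is logistic:

    NFC_true = expit( beta . x  +  gamma * SRL_main * SLO~ ) + eps,
    eps ~ N(0, noise_sd), clipped to [0, 1]

where x = (1, ELE/1000 m, SLO/10 deg, CPP/10^4 kg hm^-2 a^-1, SRL_main,
SRL_secondary, DNR_main km).  Elevation and slope enter positively (steep,
high terrain keeps forest), productivity and road density negatively
(farmable, accessible land loses forest), distance-to-road positively.
The road x slope interaction (gamma) makes the true surface non-additive,
so tree ensembles genuinely outperform a linear fit.  Noise is i.i.d. per
cell-period; spatial structure enters only through the covariates, which
keeps recovery experiments interpretable.

Because towns — and hence road growth — sit preferentially in the lowlands
where forest cover is already low, forest loss concentrates in low-NFC
cells, reproducing the qualitative "low cover, faster loss" pattern.

All outputs are bit-identical under a fixed scenario seed.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .geojson_io import write_features
from .gridding import GridSystem, aggregate_raster, build_grid
from .raster import Raster, write_ascii_grid
from .road_metrics import RoadNetwork, metrics_table

__all__ = [
    "SyntheticScenario",
    "SyntheticDataset",
    "generate_land_mask",
    "slope_degrees",
    "generate_terrain",
    "generate_cpp",
    "generate_roads",
    "generate_nfc",
    "generate_forest_masks",
    "generate_dataset",
    "write_dataset",
]

#: scale divisors that bring covariates to order one inside the link
ELE_SCALE = 1000.0   # m
SLO_SCALE = 10.0     # degrees
CPP_SCALE = 1.0e4    # kg hm^-2 a^-1

#: coefficient order inside ``nfc_coefficients``
COEF_NAMES = ("intercept", "ELE", "SLO", "CPP", "SRL_main", "SRL_secondary", "DNR_main")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic island experiment.

    Defaults emulate the study system the pipeline targets: a ~31,000 km²
    island gridded into 5-km cells (~1,200–1,300 retained), four 20-year
    periods, main roads growing every period while the secondary network
    is frozen after the second period, and a coefficient vector tuned so
    the island-mean forest cover declines from roughly 0.4 to roughly
    0.25 across the four periods.
    """

    seed: int = 42
    island_radius_km: float = 100.0
    cell_size_km: float = 5.0
    periods: tuple[str, ...] = ("p1", "p2", "p3", "p4")
    period_years: float = 20.0
    #: new (main, secondary) segments entering the network at each period
    road_growth: tuple[tuple[int, int], ...] = ((55, 1700), (40, 1800), (30, 0), (40, 0))
    n_towns: int = 12
    terrain_res_m: float = 1000.0
    forest_res_m: float = 100.0
    max_elevation_m: float = 1850.0
    nfc_coefficients: tuple[float, ...] = (0.3, 1.0, 0.7, -0.5, -3.2, -1.5, 0.01)
    #: road x slope interaction strength (0 = purely additive truth)
    interaction: float = 3.0
    #: cell-mean slope (degrees) at which the interaction's damping of
    #: road harm saturates (cells steeper than this are maximally shielded)
    slope_immunity_deg: float = 5.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.island_radius_km <= 0 or self.cell_size_km <= 0:
            raise ValueError("island radius and cell size must be positive")
        if self.terrain_res_m <= 0 or self.forest_res_m <= 0:
            raise ValueError("raster resolutions must be positive")
        if not 0 <= self.noise_sd <= 0.2:
            raise ValueError("noise_sd must lie in [0, 0.2]")
        if len(self.periods) != len(self.road_growth):
            raise ValueError("road_growth must give one (main, secondary) pair per period")
        if self.n_towns < 2:
            raise ValueError("need at least two towns to anchor main roads")
        if len(self.nfc_coefficients) != len(COEF_NAMES):
            raise ValueError(f"nfc_coefficients must have {len(COEF_NAMES)} entries {COEF_NAMES}")
        # the secondary network must be frozen from the second period on
        for main_n, sec_n in self.road_growth[2:]:
            if sec_n != 0:
                raise ValueError("secondary-road growth must be zero after the second period")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        kwargs = dict(d)
        if "periods" in kwargs:
            kwargs["periods"] = tuple(kwargs["periods"])
        if "road_growth" in kwargs:
            kwargs["road_growth"] = tuple(tuple(p) for p in kwargs["road_growth"])
        if "nfc_coefficients" in kwargs:
            kwargs["nfc_coefficients"] = tuple(kwargs["nfc_coefficients"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "island_radius_km": self.island_radius_km,
            "cell_size_km": self.cell_size_km,
            "periods": list(self.periods),
            "period_years": self.period_years,
            "road_growth": [list(p) for p in self.road_growth],
            "n_towns": self.n_towns,
            "terrain_res_m": self.terrain_res_m,
            "forest_res_m": self.forest_res_m,
            "max_elevation_m": self.max_elevation_m,
            "nfc_coefficients": list(self.nfc_coefficients),
            "interaction": self.interaction,
            "slope_immunity_deg": self.slope_immunity_deg,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def main_road_driven(cls, **overrides) -> "SyntheticScenario":
        """Variant where only main-road density drives forest loss.

        Secondary-road and distance terms are zeroed, so in the change
        analysis the main-road length delta should rank first among the
        eight indicators.
        """
        kwargs = dict(
            # mild static terms keep cells off the logistic tails so the
            # main-road length signal stays close to linear in the rate
            nfc_coefficients=(0.4, 0.4, 0.2, -0.2, -3.0, 0.0, 0.0),
            interaction=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _sub_rng(scenario: SyntheticScenario, stage: str) -> np.random.Generator:
    """Independent per-stage stream derived from the scenario seed.

    The stage name enters through a stable CRC so the streams are
    reproducible across processes (unlike the builtin string hash).
    """
    key = zlib.crc32(stage.encode()) % 2**31
    return np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(key,))
    )


def generate_land_mask(scenario: SyntheticScenario) -> Polygon:
    """Irregular island outline: a circle with smooth radial perturbation."""
    rng = _sub_rng(scenario, "land_mask")
    n = 720
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    # low-order harmonic perturbation keeps the coastline smooth
    radius = np.ones(n)
    for k in range(2, 7):
        amp = 0.04 * rng.standard_normal()
        phase = rng.uniform(0, 2 * math.pi)
        radius += amp * np.cos(k * theta + phase)
    radius = np.clip(radius, 0.7, 1.3) * scenario.island_radius_km * 1e3
    cx = cy = scenario.island_radius_km * 1.5e3  # keep coordinates positive
    xs = cx + radius * np.cos(theta)
    ys = cy + radius * np.sin(theta)
    return Polygon(zip(xs, ys))


def _dome_noise_field(scenario: SyntheticScenario, raster: Raster,
                      land_mask: Polygon) -> np.ndarray:
    """Unmasked elevation surface: central dome plus smoothed noise (m)."""
    rng = _sub_rng(scenario, "terrain")
    xs, ys = raster.pixel_centroids()
    cx, cy = land_mask.centroid.x, land_mask.centroid.y
    d = np.hypot(xs - cx, ys - cy) / (scenario.island_radius_km * 1e3)
    dome = scenario.max_elevation_m * np.clip(1.0 - d, 0.0, None) ** 1.6
    # short-wavelength relief grows with the dome: rugged massif, flat coast
    noise = gaussian_filter(rng.standard_normal(raster.shape), sigma=1.5)
    noise /= noise.std()  # unit variance regardless of smoothing scale
    relief = 0.15 + 0.85 * dome / scenario.max_elevation_m
    noise *= 0.18 * scenario.max_elevation_m * relief
    return np.clip(dome + noise, 0.0, None)


def _land_pixel_mask(raster: Raster, land_mask: BaseGeometry) -> np.ndarray:
    import shapely

    xs, ys = raster.pixel_centroids()
    pts = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.contains(land_mask, pts).reshape(raster.shape)
    return inside


def slope_degrees(elevation: np.ndarray, res: float) -> np.ndarray:
    """Slope (degrees) by central finite differences on an elevation grid."""
    gy, gx = np.gradient(np.asarray(elevation, dtype=float), res)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def generate_terrain(scenario: SyntheticScenario,
                     land_mask: Polygon | None = None) -> tuple[Raster, Raster]:
    """Elevation and slope rasters, masked to land.

    Elevation is a radial dome (central mountains) plus Gaussian-filtered
    white noise; slope is computed by central finite differences on the
    *unmasked* surface and expressed in degrees, then masked to land so
    coastal pixels keep clean gradients.
    """
    if land_mask is None:
        land_mask = generate_land_mask(scenario)
    res = scenario.terrain_res_m
    xmin, ymin, xmax, ymax = land_mask.bounds
    xll = math.floor(xmin / res) * res
    yll = math.floor(ymin / res) * res
    nx = math.ceil((xmax - xll) / res)
    ny = math.ceil((ymax - yll) / res)
    base = Raster(np.zeros((ny, nx)), xll, yll, res)
    elev = _dome_noise_field(scenario, base, land_mask)
    slope = slope_degrees(elev, res)
    inside = _land_pixel_mask(base, land_mask)
    elev = np.where(inside, elev, np.nan)
    slope = np.where(inside, slope, np.nan)
    return base.copy_with(elev), base.copy_with(slope)


def generate_cpp(scenario: SyntheticScenario, land_mask: Polygon | None = None,
                 elevation: Raster | None = None) -> Raster:
    """Climatic potential productivity surface (kg hm^-2 a^-1).

    Productivity is highest in the warm, humid eastern lowlands and drops
    with elevation and towards the drier west; a smooth noise component
    adds local variation.
    """
    if land_mask is None:
        land_mask = generate_land_mask(scenario)
    if elevation is None:
        elevation, _ = generate_terrain(scenario, land_mask)
    rng = _sub_rng(scenario, "cpp")
    xs, _ = elevation.pixel_centroids()
    xmin, _, xmax, _ = elevation.bounds
    east = (xs - xmin) / max(xmax - xmin, 1.0)
    elev_term = np.nan_to_num(elevation.data, nan=0.0) / scenario.max_elevation_m
    noise = gaussian_filter(rng.standard_normal(elevation.shape), sigma=6.0)
    cpp = 1.4e4 * (0.75 + 0.25 * east) * (1.0 - 0.45 * elev_term) + 1.2e3 * noise
    cpp = np.clip(cpp, 1e3, None)
    cpp = np.where(np.isnan(elevation.data), np.nan, cpp)
    return elevation.copy_with(cpp)


def _elevation_at(elevation: Raster, x: float, y: float) -> float:
    ny, nx = elevation.shape
    col = int((x - elevation.xll) // elevation.cellsize)
    row = int(ny - 1 - (y - elevation.yll) // elevation.cellsize)
    if 0 <= row < ny and 0 <= col < nx:
        v = elevation.data[row, col]
        return 0.0 if np.isnan(v) else float(v)
    return 0.0


def _sample_lowland_points(
    rng: np.random.Generator, land_mask: Polygon, elevation: Raster,
    n: int, *, scale_m: float = 350.0,
) -> list[Point]:
    """Rejection-sample points on land, preferring low elevation."""
    xmin, ymin, xmax, ymax = land_mask.bounds
    pts: list[Point] = []
    while len(pts) < n:
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if not land_mask.contains(Point(x, y)):
            continue
        if rng.random() < math.exp(-_elevation_at(elevation, x, y) / scale_m):
            pts.append(Point(x, y))
    return pts


def _jittered_line(
    rng: np.random.Generator, a: Point, b: Point,
    center: tuple[float, float] | None = None, radius_m: float | None = None,
) -> LineString:
    """Town-to-town connection with a mild midpoint deflection.

    When the island centre is given, a midpoint that would cut through the
    central massif is pushed radially outward, so long links skirt the
    mountains the way real trunk roads do.
    """
    mx, my = (a.x + b.x) / 2, (a.y + b.y) / 2
    length = a.distance(b)
    if center is not None and radius_m is not None:
        dx, dy = mx - center[0], my - center[1]
        d = math.hypot(dx, dy)
        target = 0.85 * radius_m  # trunk links hug the coastal lowlands
        if 0 < d < target:
            push = (target - d) * rng.uniform(0.8, 1.05)
            mx += push * dx / d
            my += push * dy / d
    mx += rng.normal(0, 0.05 * length)
    my += rng.normal(0, 0.05 * length)
    return LineString([(a.x, a.y), (mx, my), (b.x, b.y)])


def _mst_edges(points: list[Point]) -> list[tuple[int, int]]:
    """Minimum spanning tree over point-to-point Euclidean distances."""
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import pdist, squareform

    coords = np.array([[p.x, p.y] for p in points])
    dist = squareform(pdist(coords))
    mst = minimum_spanning_tree(dist).tocoo()
    return [(int(i), int(j)) for i, j in zip(mst.row, mst.col)]


def generate_roads(
    scenario: SyntheticScenario,
    land_mask: Polygon | None = None,
    elevation: Raster | None = None,
) -> dict[str, RoadNetwork]:
    """Nested road networks, one per period.

    Main roads first connect the sampled towns along a minimum spanning
    tree, then add further town-to-town and outward links; secondary roads
    branch off the existing network with short lowland spurs.  Each
    period's network is a strict superset of the previous one (roads are
    never removed), and no secondary segment is added after the second
    period.
    """
    if land_mask is None:
        land_mask = generate_land_mask(scenario)
    if elevation is None:
        elevation, _ = generate_terrain(scenario, land_mask)
    rng = _sub_rng(scenario, "roads")
    towns = _sample_lowland_points(rng, land_mask, elevation, scenario.n_towns)

    # pool of candidate main connections: MST first, then extra links
    main_pool: list[tuple[Point, Point]] = []
    for i, j in _mst_edges(towns):
        main_pool.append((towns[i], towns[j]))
    total_main = sum(m for m, _ in scenario.road_growth)
    while len(main_pool) < total_main:
        if rng.random() < 0.5 and scenario.n_towns >= 3:
            i, j = rng.choice(scenario.n_towns, size=2, replace=False)
            main_pool.append((towns[int(i)], towns[int(j)]))
        else:
            # outward extension from a town to a fresh lowland target
            i = int(rng.integers(scenario.n_towns))
            target = _sample_lowland_points(rng, land_mask, elevation, 1)[0]
            main_pool.append((towns[i], target))

    segments: list[LineString] = []
    classes: list[str] = []
    networks: dict[str, RoadNetwork] = {}
    main_used = 0
    for period, (n_main, n_sec) in zip(scenario.periods, scenario.road_growth):
        for _ in range(n_main):
            a, b = main_pool[main_used % len(main_pool)]
            main_used += 1
            line = _jittered_line(
                rng, a, b,
                center=(land_mask.centroid.x, land_mask.centroid.y),
                radius_m=scenario.island_radius_km * 1e3,
            )
            clipped = line.intersection(land_mask)
            parts = [clipped] if isinstance(clipped, LineString) else [
                g for g in getattr(clipped, "geoms", []) if isinstance(g, LineString)
            ]
            for part in parts:
                if part.length > 0:
                    segments.append(part)
                    classes.append("main")
        for _ in range(n_sec):
            if not segments:
                break
            host = segments[int(rng.integers(len(segments)))]
            anchor = host.interpolate(rng.uniform(0, host.length))
            # short lowland spur, retried a few times to stay on land
            for _ in range(8):
                ang = rng.uniform(0, 2 * math.pi)
                length = rng.uniform(1.5e3, 5e3)
                end = Point(anchor.x + length * math.cos(ang),
                            anchor.y + length * math.sin(ang))
                if not land_mask.contains(end):
                    continue
                if rng.random() < math.exp(-_elevation_at(elevation, end.x, end.y) / 500.0):
                    segments.append(LineString([(anchor.x, anchor.y), (end.x, end.y)]))
                    classes.append("secondary")
                    break
        networks[period] = RoadNetwork(
            period=period, segments=list(segments), classes=list(classes)
        )
    return networks


def _linear_predictor(scenario: SyntheticScenario, table: pd.DataFrame) -> np.ndarray:
    beta = dict(zip(COEF_NAMES, scenario.nfc_coefficients))
    ele = table["ELE"].to_numpy(dtype=float) / ELE_SCALE
    slo = table["SLO"].to_numpy(dtype=float) / SLO_SCALE
    cpp = table["CPP"].to_numpy(dtype=float) / CPP_SCALE
    srl_m = table["SRL_main"].to_numpy(dtype=float)
    srl_s = table["SRL_secondary"].to_numpy(dtype=float)
    dnr_m = table["DNR_main"].to_numpy(dtype=float)
    dnr_m = np.where(np.isnan(dnr_m), scenario.island_radius_km, dnr_m)
    eta = (
        beta["intercept"]
        + beta["ELE"] * ele
        + beta["SLO"] * slo
        + beta["CPP"] * cpp
        + beta["SRL_main"] * srl_m
        + beta["SRL_secondary"] * srl_s
        + beta["DNR_main"] * dnr_m
        # road harm is damped on steep ground; the damping saturates at
        # slope_immunity_deg so steep cells are merely shielded, never
        # *gaining* forest from roads
        + scenario.interaction * srl_m
        * np.minimum(slo * SLO_SCALE / scenario.slope_immunity_deg, 1.0)
    )
    return eta


def generate_nfc(scenario: SyntheticScenario, covariate_table: pd.DataFrame) -> pd.Series:
    """Ground-truth NFC per (cell, period) from the logistic rule plus noise.

    ``covariate_table`` must be indexed by (cell_id, period) and carry the
    covariate columns the rule uses.  Noise is i.i.d. Gaussian with the
    scenario's ``noise_sd``, and the result is clipped to [0, 1]; a
    warning is raised if the coefficients clip more than 5 % of values.
    """
    needed = ["ELE", "SLO", "CPP", "SRL_main", "SRL_secondary", "DNR_main"]
    missing = [c for c in needed if c not in covariate_table.columns]
    if missing:
        raise ValueError(f"covariate table lacks column(s): {missing}")
    if covariate_table[["ELE", "SLO", "CPP"]].isna().any().any():
        raise ValueError("covariate table has missing topography/climate values")
    eta = _linear_predictor(scenario, covariate_table)
    true = expit(eta)
    rng = _sub_rng(scenario, "nfc_noise")
    noisy = true + rng.normal(0.0, scenario.noise_sd, size=true.shape) \
        if scenario.noise_sd > 0 else true
    clipped_frac = float(((noisy < 0) | (noisy > 1)).mean())
    if clipped_frac > 0.05:
        warnings.warn(
            f"{clipped_frac:.1%} of NFC values clipped to [0, 1]; "
            "consider milder coefficients", stacklevel=2,
        )
    return pd.Series(np.clip(noisy, 0.0, 1.0), index=covariate_table.index, name="NFC")


def generate_forest_masks(
    scenario: SyntheticScenario,
    grid: GridSystem,
    nfc: pd.DataFrame | pd.Series,
) -> dict[str, Raster]:
    """Per-period binary forest rasters that reproduce the cell NFC exactly.

    A single smooth "suitability" field is drawn once; within each cell the
    ``round(NFC * n_pixels)`` most suitable pixels are forested.  Sharing
    the field across periods makes the masks nest as cover declines (forest
    retreats to the most suitable ground), and guarantees the overlay
    round-trip recovers each cell's NFC to within half a pixel-area
    quantum.
    """
    if isinstance(nfc, pd.Series):
        nfc = nfc.unstack("period") if isinstance(nfc.index, pd.MultiIndex) else nfc.to_frame()
    res = scenario.forest_res_m
    cs = grid.cell_size
    per_side = int(round(cs / res))
    if abs(per_side * res - cs) > 1e-6:
        raise ValueError("forest resolution must divide the cell size")
    rows = [c.row for c in grid.cells]
    cols = [c.col for c in grid.cells]
    nrow, ncol = max(rows) + 1, max(cols) + 1
    ox, oy = grid.origin
    ny, nx = nrow * per_side, ncol * per_side
    rng = _sub_rng(scenario, "forest_suitability")
    suitability = gaussian_filter(rng.standard_normal((ny, nx)), sigma=5.0)

    masks = {
        str(period): np.full((ny, nx), np.nan) for period in nfc.columns
    }
    npix = per_side * per_side
    for cell in grid.cells:
        r0 = ny - (cell.row + 1) * per_side  # raster row of the cell's top
        c0 = cell.col * per_side
        block = suitability[r0:r0 + per_side, c0:c0 + per_side]
        order = np.argsort(block.ravel())[::-1]  # most suitable first
        for period in nfc.columns:
            k = int(round(float(nfc.loc[cell.id, period]) * npix))
            flat = np.zeros(npix)
            flat[order[:k]] = 1.0
            masks[str(period)][r0:r0 + per_side, c0:c0 + per_side] = flat.reshape(
                per_side, per_side
            )
    return {
        p: Raster(m, ox, oy, res) for p, m in masks.items()
    }


@dataclass
class SyntheticDataset:
    """Everything one scenario generates, ready for the pipeline stages."""

    scenario: SyntheticScenario
    land_mask: Polygon
    elevation: Raster
    slope: Raster
    cpp: Raster
    grid: GridSystem
    networks: dict[str, RoadNetwork]
    cell_table: pd.DataFrame  # (cell_id, period) x covariates + true NFC
    forest_masks: dict[str, Raster] = field(default_factory=dict)


def generate_dataset(
    scenario: SyntheticScenario, *, with_forest_masks: bool = False
) -> SyntheticDataset:
    """Run the full generative chain for one scenario.

    Terrain → grid → covariate aggregation → roads → road metrics →
    ground-truth NFC (→ optional forest-mask rasters).  The returned cell
    table is indexed by (cell_id, period) and contains ELE/SLO/CPP (static
    across periods), the eight road indicators, and the true NFC.
    """
    land = generate_land_mask(scenario)
    elevation, slope = generate_terrain(scenario, land)
    cpp = generate_cpp(scenario, land, elevation)
    grid = build_grid(land, scenario.cell_size_km * 1e3)
    ele_cell = aggregate_raster(grid, elevation)
    slo_cell = aggregate_raster(grid, slope)
    cpp_cell = aggregate_raster(grid, cpp)
    networks = generate_roads(scenario, land, elevation)
    roads = metrics_table(grid, networks)

    frames = []
    for period in scenario.periods:
        static = pd.DataFrame(
            {"ELE": ele_cell, "SLO": slo_cell, "CPP": cpp_cell}
        )
        static["period"] = period
        frames.append(static.set_index("period", append=True))
    table = pd.concat(frames)
    table.index.names = ["cell_id", "period"]
    table = table.join(roads, how="left")
    # coastal cells with no raster pixel centroid would lack covariates;
    # drop them from the frame (they are rare and carry no information)
    table = table.dropna(subset=["ELE", "SLO", "CPP"])
    table["NFC"] = generate_nfc(scenario, table)
    table = table.sort_index()
    kept_ids = set(table.index.get_level_values("cell_id"))
    grid = GridSystem(
        cell_size=grid.cell_size, origin=grid.origin,
        cells=[c for c in grid.cells if c.id in kept_ids],
    )

    ds = SyntheticDataset(
        scenario=scenario, land_mask=land, elevation=elevation, slope=slope,
        cpp=cpp, grid=grid, networks=networks, cell_table=table,
    )
    if with_forest_masks:
        ds.forest_masks = generate_forest_masks(scenario, grid, table["NFC"].unstack("period"))
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset as plain-text files (ASCII grids, GeoJSON, CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(ds.elevation, outdir / "elevation.asc")
    write_ascii_grid(ds.slope, outdir / "slope.asc")
    write_ascii_grid(ds.cpp, outdir / "cpp.asc")
    write_features(outdir / "land_mask.geojson", [(ds.land_mask, {})])
    for period, net in ds.networks.items():
        net.to_geojson(outdir / f"roads_{period}.geojson")
    for period, mask in ds.forest_masks.items():
        write_ascii_grid(mask, outdir / f"forest_{period}.asc")
    ds.grid.write_geojson(outdir / "grid.geojson")
    ds.cell_table.to_csv(outdir / "cell_table.csv")
    with open(outdir / "scenario.yaml", "w") as fh:
        yaml.safe_dump(ds.scenario.to_dict(), fh)
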