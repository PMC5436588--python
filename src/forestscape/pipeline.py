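"""End-to-end orchestration: simulate → grid → metrics → fit → hindcast →
change → hotspots, driven by one YAML config.

The pipeline mirrors the standard reconstruction workflow: observed forest
polygons (or synthetic masks) are overlaid on the grid for the observed
periods, a regression backend is selected by cross-validated NMSE and
fitted on those periods, unobserved periods are hindcast from their road
metrics, and the resulting cover series feeds the change-rate, explanatory
-power, variation-partition and hot-spot analyses.

Every file the run writes is deterministic under the config's seed, and a
manifest (config hash, seed, library versions) makes the bundle
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change_analysis import (
    change_rate,
    indicator_power,
    nfc_vs_rate_slope,
    variation_partition,
)
from .gridding import GridSystem, overlay_nfc, polygonize_mask
from .hotspots import build_weights, hotspot_report
from .models import BACKENDS, ModelSpec, compare_backends, fit, hindcast
from .synthetic import SyntheticScenario, generate_dataset, write_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run"]


@dataclass
class PipelineConfig:
    """One run: a synthetic scenario (or file inputs), model and analysis knobs."""

    outdir: str
    seed: int = 42
    scenario: SyntheticScenario | None = None
    #: file-based inputs (mutually exclusive with `scenario`): paths for
    #: land_mask, per-period forest GeoJSON, per-period roads GeoJSON,
    #: and rasters {ELE, SLO, CPP}
    inputs: dict | None = None
    cell_size_m: float = 5000.0
    periods: tuple[str, ...] = ("p1", "p2", "p3", "p4")
    #: periods with observed forest maps; the rest are hindcast
    observed_periods: tuple[str, ...] = ("p2", "p3", "p4")
    period_years: float = 20.0
    backends: tuple[str, ...] = BACKENDS
    k_folds: int = 10
    change_pairs: tuple[tuple[str, str], ...] = (
        ("p1", "p4"), ("p1", "p2"), ("p2", "p3"), ("p3", "p4"),
    )
    weights_scheme: str = "queen"
    weights_parameter: float | None = None
    mnd_per_area: bool = True
    write_inputs: bool = False

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("provide exactly one of scenario / inputs")
        known = set(self.periods)
        for p in self.observed_periods:
            if p not in known:
                raise ValueError(f"observed period {p!r} not in the period list")
        for a, b in self.change_pairs:
            if a not in known or b not in known:
                raise ValueError(f"change pair ({a}, {b}) references unknown period(s)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "scenario" in kwargs and kwargs["scenario"] is not None:
            kwargs["scenario"] = SyntheticScenario.from_dict(kwargs["scenario"])
        for key in ("periods", "observed_periods", "backends"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "change_pairs" in kwargs:
            kwargs["change_pairs"] = tuple(
                tuple(p.split(":")) if isinstance(p, str) else tuple(p)
                for p in kwargs["change_pairs"]
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "inputs": self.inputs,
            "cell_size_m": self.cell_size_m,
            "periods": list(self.periods),
            "observed_periods": list(self.observed_periods),
            "period_years": self.period_years,
            "backends": list(self.backends),
            "k_folds": self.k_folds,
            "change_pairs": [list(p) for p in self.change_pairs],
            "weights_scheme": self.weights_scheme,
            "weights_parameter": self.weights_parameter,
            "mnd_per_area": self.mnd_per_area,
            "write_inputs": self.write_inputs,
        }
        return d


@dataclass
class PipelineResult:
    """In-memory handles to everything the run computed and wrote."""

    config: PipelineConfig
    grid: GridSystem
    cell_table: pd.DataFrame
    nfc_series: pd.DataFrame  # cells x periods, observed + hindcast
    nmse_table: pd.DataFrame
    winner: str
    changes: dict[tuple[str, str], pd.DataFrame] = dc_field(default_factory=dict)
    power_tables: dict[tuple[str, str], pd.DataFrame] = dc_field(default_factory=dict)
    partitions: dict[tuple[str, str], object] = dc_field(default_factory=dict)
    slopes: dict[tuple[str, str], object] = dc_field(default_factory=dict)
    hotspot_fields: dict[tuple[str, str], object] = dc_field(default_factory=dict)


def _load_file_inputs(config: PipelineConfig):
    """Assemble grid + cell table from user-supplied files."""
    from .geojson_io import read_features
    from .gridding import aggregate_raster, build_grid
    from .raster import read_ascii_grid
    from .road_metrics import RoadNetwork, metrics_table
    from shapely import union_all

    paths = config.inputs
    land = union_all([g for g, _ in read_features(paths["land_mask"])])
    grid = build_grid(land, config.cell_size_m)
    static = {}
    for name in ("ELE", "SLO", "CPP"):
        static[name] = aggregate_raster(grid, read_ascii_grid(paths["rasters"][name]))
    networks = {
        p: RoadNetwork.from_geojson(paths["roads"][p], period=p)
        for p in config.periods
    }
    roads = metrics_table(grid, networks, mnd_per_area=config.mnd_per_area)
    frames = []
    for period in config.periods:
        f = pd.DataFrame(static)
        f["period"] = period
        frames.append(f.set_index("period", append=True))
    table = pd.concat(frames)
    table.index.names = ["cell_id", "period"]
    table = table.join(roads, how="left").dropna(subset=["ELE", "SLO", "CPP"])
    observed = {}
    for p in config.observed_periods:
        polys = [g for g, _ in read_features(paths["forest"][p])]
        observed[p] = overlay_nfc(grid, polys)
    kept = set(table.index.get_level_values("cell_id"))
    grid = GridSystem(
        cell_size=grid.cell_size, origin=grid.origin,
        cells=[c for c in grid.cells if c.id in kept],
    )
    return grid, table, observed


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the output bundle.

    Stages fail loudly: any exception is re-raised annotated with the
    stage name so a broken input is traceable.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.scenario is not None:
            ds = generate_dataset(config.scenario, with_forest_masks=True)
            grid, table = ds.grid, ds.cell_table.copy()
            if config.write_inputs:
                write_dataset(ds, outdir / "inputs")
            stage = "grid"
            observed = {}
            for p in config.observed_periods:
                rects = polygonize_mask(ds.forest_masks[p])
                observed[p] = overlay_nfc(grid, rects, disjoint=True)
        else:
            stage = "grid"
            grid, table, observed = _load_file_inputs(config)

        # observed NFC replaces the generator's truth in the working table;
        # the truth stays available as NFC_true for recovery diagnostics
        if "NFC" in table.columns:
            table = table.rename(columns={"NFC": "NFC_true"})
        table["NFC"] = np.nan
        for p, series in observed.items():
            rows = table.index.get_level_values("period") == p
            ids = table.index.get_level_values("cell_id")[rows]
            table.loc[rows, "NFC"] = series.reindex(ids).to_numpy()

        stage = "fit"
        specs = [ModelSpec(backend=b, seed=config.seed) for b in config.backends]
        comparison = compare_backends(
            table.dropna(subset=["NFC"]), specs,
            periods=list(config.observed_periods),
            k_folds=config.k_folds, seed=config.seed,
        )
        winner_spec = next(s for s in specs if s.backend == comparison.winner)
        model = fit(table.dropna(subset=["NFC"]), winner_spec,
                    list(config.observed_periods))

        stage = "hindcast"
        nfc_series = pd.DataFrame(
            {p: table.xs(p, level="period")["NFC"] for p in config.periods}
        )
        hindcast_periods = [p for p in config.periods if p not in config.observed_periods]
        for p in hindcast_periods:
            nfc_series[p] = hindcast(model, table, p)
        nfc_series = nfc_series.sort_index()
        # the change analysis runs on the completed series
        analysis_table = table.copy()
        for p in config.periods:
            rows = analysis_table.index.get_level_values("period") == p
            ids = analysis_table.index.get_level_values("cell_id")[rows]
            analysis_table.loc[rows, "NFC"] = nfc_series[p].reindex(ids).to_numpy()

        stage = "change"
        order = {p: i for i, p in enumerate(config.periods)}
        result = PipelineResult(
            config=config, grid=grid, cell_table=analysis_table,
            nfc_series=nfc_series, nmse_table=comparison.table,
            winner=comparison.winner,
        )
        for pair in config.change_pairs:
            t1, t2 = pair
            years = abs(order[t2] - order[t1]) * config.period_years
            ch = change_rate(analysis_table, t1, t2, years=years)
            result.changes[pair] = ch
            result.power_tables[pair] = indicator_power(ch)
            result.partitions[pair] = variation_partition(ch)
            result.slopes[pair] = nfc_vs_rate_slope(
                analysis_table, t1, t2, years=years
            )

        stage = "hotspots"
        weights = build_weights(grid, config.weights_scheme, config.weights_parameter)
        for pair, ch in result.changes.items():
            result.hotspot_fields[pair] = hotspot_report(
                grid, ch["d_nfc"], weights,
                geojson_path=outdir / f"hotspots_{pair[0]}_{pair[1]}.geojson",
                field_name=f"d_nfc_{pair[0]}_{pair[1]}",
            )

        stage = "write"
        _write_bundle(result, outdir)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    config = result.config
    result.grid.write_geojson(outdir / "grid.geojson")
    result.cell_table.sort_index().to_csv(outdir / "cell_table.csv")
    result.nfc_series.to_csv(outdir / "nfc_series.csv")
    nmse_out = result.nmse_table.copy()
    nmse_out["fold_nmse"] = nmse_out["fold_nmse"].map(
        lambda v: ";".join(f"{x:.10g}" for x in v)
    )
    nmse_out.rename_axis("backend").to_csv(outdir / "nmse_comparison.csv")

    power_rows = []
    for (t1, t2), tab in result.power_tables.items():
        t = tab.reset_index()
        t.insert(0, "pair", f"{t1}:{t2}")
        power_rows.append(t)
    pd.concat(power_rows, ignore_index=True).to_csv(
        outdir / "indicator_power.csv", index=False
    )

    part_rows = []
    for (t1, t2), part in result.partitions.items():
        part_rows.append(
            {
                "pair": f"{t1}:{t2}",
                "adj_r2_main": part.adj_r2_main,
                "adj_r2_secondary": part.adj_r2_secondary,
                "adj_r2_combined": part.adj_r2_combined,
                "unique_main": part.unique_main,
                "unique_secondary": part.unique_secondary,
                "shared": part.shared,
                "p_main": part.p_main,
                "p_secondary": part.p_secondary,
                "p_combined": part.p_combined,
            }
        )
    pd.DataFrame(part_rows).to_csv(outdir / "partition.csv", index=False)

    slope_rows = []
    for (t1, t2), s in result.slopes.items():
        slope_rows.append(
            {"pair": f"{t1}:{t2}", "slope": s.slope, "intercept": s.intercept,
             "adj_r2_pct": s.adj_r2_pct, "f_stat": s.f_stat,
             "p_value": s.p_value, "n": s.n}
        )
    pd.DataFrame(slope_rows).to_csv(outdir / "nfc_vs_rate.csv", index=False)

    hot_rows = []
    for (t1, t2), fieldres in result.hotspot_fields.items():
        frame = fieldres.frame().reset_index()
        frame.insert(0, "pair", f"{t1}:{t2}")
        hot_rows.append(frame)
    pd.concat(hot_rows, ignore_index=True).to_csv(outdir / "hotspots.csv", index=False)

    # the output directory is where the bundle lands, not part of what was
    # computed; leaving it out keeps manifests of identical runs identical
    config_dict = config.to_dict()
    config_dict.pop("outdir")
    manifest = {
        "forestscape_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "versions": _library_versions(),
        "winner_backend": result.winner,
        "n_cells": len(result.grid),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import shapely
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }
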