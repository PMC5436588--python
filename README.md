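# forestscape

Grid-based analysis of natural-forest-cover (NFC) change for landscape
ecologists and conservation planners: given multi-period forest maps, a
classed road network, and terrain/climate rasters, the package

1. lays a square cell lattice over the land mask (default 5 × 5 km,
   cells < 50 % on land excluded) and derives per-cell NFC and covariates;
2. computes four road indicators per cell, class, and period — road
   density SRL (km km⁻²), centroid distance to the nearest road DNR (km),
   planar-graph node density NON (km⁻²), and mean node degree MND;
3. selects a regression backend (GLM / additive / neural / random forest)
   by cell-blocked cross-validated **NMSE** = MSE / Var(observed) and
   **hindcasts** NFC for periods that lack maps from their road metrics,
   holding topography and climate fixed;
4. quantifies change: per-decade change rates, per-indicator explanatory
   power (adjusted R², %), adjusted-R² **variation partitioning** of main
   vs secondary roads, and the cover-vulnerability regression of rate on
   initial NFC;
5. maps spatial clusters of change with the **Getis-Ord Gi\*** statistic,

   Gi\* = [Σⱼ wᵢⱼxⱼ − X̄ Σⱼ wᵢⱼ] / ( S·√{ [n Σⱼ wᵢⱼ² − (Σⱼ wᵢⱼ)²]/(n−1) } ),

   a z-score classed hot/cold at ±1.645 / ±1.960 / ±2.576.

Because historical map archives are rarely redistributable, a first-class
synthetic generator builds a tropical island — rugged central massif,
productivity gradient, a two-class road network that densifies over four
periods (secondary roads saturate after the second), and ground-truth NFC
from a known logistic rule — so the entire chain is testable end to end
with no downloads. See `docs/methods.md` for the models and their
assumptions.

## Worked example

```python
from forestscape.pipeline import PipelineConfig, run
from forestscape.synthetic import SyntheticScenario

config = PipelineConfig(outdir="out", seed=42,
                        scenario=SyntheticScenario(seed=42))
result = run(config)

print("retained cells:", len(result.grid))
print("cross-validated NMSE:", result.nmse_table["nmse"].round(4).to_dict())
print("winner backend:", result.winner)
print("island-mean NFC by period:", result.nfc_series.mean().round(3).to_dict())
slope = result.slopes[("p1", "p4")]
print(f"rate-vs-cover slope: {slope.slope:.4f} (p = {slope.p_value:.2e})")
part = result.partitions[("p1", "p4")]
print(f"adjusted R2: main {part.adj_r2_main:.1f}%, "
      f"secondary {part.adj_r2_secondary:.1f}%, combined {part.adj_r2_combined:.1f}%")
```

prints

```
retained cells: 1259
cross-validated NMSE: {'linear': 0.1197, 'additive': 0.0828, 'neural': 0.0922, 'forest': 0.0493}
winner backend: forest
island-mean NFC by period: {'p1': 0.495, 'p2': 0.446, 'p3': 0.417, 'p4': 0.393}
rate-vs-cover slope: 0.0276 (p = 1.31e-25)
adjusted R2: main 31.7%, secondary 9.6%, combined 39.4%
```

Reading the output: the random forest wins the NMSE comparison (0.049,
i.e. ~95 % of the cover variance explained out of fold), the island loses
forest cover every period, the positive slope says cells that start with
*low* cover lose cover fastest — the vulnerability pattern that directs
conservation attention to already-degraded cells — and main roads explain
about three times more of the change-rate variance than secondary roads.
The run also writes, under `out/`, the grid and hot-spot GeoJSON layers,
the cell table, NMSE comparison, indicator-power and partition CSVs, and
a provenance manifest. Running the same config twice yields byte-identical
outputs.

The same stages are available from the shell:

```bash
forestscape simulate --out island/           # synthetic inputs as text files
forestscape run --config pipeline.yaml       # full pipeline from YAML
forestscape metrics --roads p2=island/roads_p2.geojson \
    --grid island/grid.geojson --out metrics.csv
forestscape fit --table island/cell_table.csv --backend forest \
    --periods p2,p3,p4 --seed 3 --out model.joblib
forestscape hindcast --model model.joblib --table island/cell_table.csv \
    --period p1 --out hindcast.csv
```

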