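"""Aggregate a small campaign into a Gi* hot-spot map.

Several participants walk the same route; their georeferenced stress events
are rasterized onto a 25 m grid, cell-wise stress rates are scored with the
Getis-Ord Gi* statistic and classified into hot/cold spots at the 90/95/99 %
confidence levels. Writes the map layers (GeoJSON + CSV) and a PNG.

Run:  python examples/02_hotspot_map.py
"""
import dataclasses
from pathlib import Path

import numpy as np

from stressmap import (
    GridSpec,
    ScenarioConfig,
    SpatialWeights,
    classify,
    detect_mos,
    generate_campaign,
    gi_star,
    locate_many,
    preprocess,
    rasterize,
    write_layers,
)
from stressmap.georef import georeference_events
from stressmap.viz import plot_hotspots

# Keep measurements along the whole route but concentrate the stressors in
# the middle third, so the map has genuinely hot and cold stretches.
cfg = ScenarioConfig.default_walk(n_sites=30, seed=7, n_participants=4)
middle = cfg.stressor_sites[10:20]
cfg = dataclasses.replace(cfg, stressor_sites=middle)
campaign = generate_campaign(cfg)

sample_pts, mos_pts = [], []
for p in campaign:
    lon, lat, ok = locate_many(p.trace.times(), p.track)
    sample_pts.append(np.column_stack([lon[ok], lat[ok]]))
    events = georeference_events(detect_mos(preprocess(p.trace)), p.track)
    mos_pts.extend((e.lon, e.lat) for e in events if e.located)

samples = np.vstack(sample_pts)
spec = GridSpec.from_points(samples[:, 0], samples[:, 1], cell_size_m=25.0)
to_xy = lambda pts: np.column_stack(spec.crs.project(pts[:, 0], pts[:, 1]))
grid = rasterize(spec, to_xy(samples), to_xy(np.asarray(mos_pts)), min_support=10)

result = gi_star(grid, SpatialWeights.from_grid(grid))
layers = classify(result)

out = Path("scratch/example_hotspots")
out.mkdir(parents=True, exist_ok=True)
write_layers(layers, out / "cells.geojson", out / "cells.csv")
plot_hotspots(result, out / "hotspots.png")

table = layers["table"]
print(f"grid: {spec.nx} x {spec.ny} cells of {spec.cell_size_m:g} m ({spec.crs.name})")
print(f"included cells (>= {grid.min_support} measurements): {len(table)}")
print(table["class"].value_counts().to_string())
print(f"\nlayers written to {out}/")
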