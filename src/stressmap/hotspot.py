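"""Spatial aggregation and Getis-Ord Gi* hot/cold-spot analysis.

Located stress events, raw sensor samples and diary reports are aggregated
onto a metric grid (UTM, default 25 m cells). Because participants do not
cover the study area uniformly, raw event counts per cell mostly mirror foot
traffic; each cell's value is therefore the event count standardised by the
number of georeferenced sensor samples recorded in that cell:

    x_j = n_events(j) / n_measurements(j)

Cells with fewer than ``min_support`` samples are excluded — a rate from a
nearly empty cell is noise.

The Getis-Ord Gi* statistic then scores each cell's neighbourhood (a fixed
distance band around the cell, self-inclusive) against the global mean:

    z_i = (sum_j w_ij x_j - xbar W_i) / (S * sqrt((n S1_i - W_i^2)/(n - 1)))

with W_i = sum_j w_ij, S1_i = sum_j w_ij^2, xbar the mean of x over the n
included cells and S = sqrt(sum x^2 / n - xbar^2). Large positive z marks a
hot spot (clustered high stress rates), large negative z a cold spot.
Classification uses the conventional two-sided normal thresholds 1.645 /
1.96 / 2.576 (90 / 95 / 99%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ContractError, InsufficientCellsError, UndefinedChangeError
from .utm import UtmCrs

Z_THRESHOLDS = ((2.576, "99"), (1.96, "95"), (1.645, "90"))

COUNT_KINDS = ("meas", "mos", "diary_neg", "diary_pos")


@dataclass(frozen=True)
class GridSpec:
    """A metric raster: UTM CRS, cell size, snapped origin, extent in cells."""

    crs: UtmCrs
    cell_size_m: float
    x0: float
    y0: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ConfigError("cell_size_m must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ConfigError("grid extent must be at least 1x1 cells")

    @classmethod
    def from_points(
        cls, lon, lat, cell_size_m: float = 25.0, crs: Optional[UtmCrs] = None
    ) -> "GridSpec":
        """Cover the lon/lat points; origin snapped to a cell-size multiple."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        crs = crs or UtmCrs.for_points(lon, lat)
        x, y = crs.project(lon, lat)
        s = cell_size_m
        x0 = np.floor(x.min() / s) * s
        y0 = np.floor(y.min() / s) * s
        nx = int(np.floor((x.max() - x0) / s)) + 1
        ny = int(np.floor((y.max() - y0) / s)) + 1
        return cls(crs=crs, cell_size_m=s, x0=float(x0), y0=float(y0), nx=nx, ny=ny)

    def cell_index(self, x, y):
        """Half-open membership [x0+i*s, x0+(i+1)*s): edge points go right/top."""
        ix = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_size_m).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_size_m).astype(int)
        return ix, iy

    def centroid(self, ix, iy):
        s = self.cell_size_m
        return (self.x0 + (np.asarray(ix) + 0.5) * s,
                self.y0 + (np.asarray(iy) + 0.5) * s)

    def cell_polygon_lonlat(self, ix: int, iy: int) -> list[list[float]]:
        s = self.cell_size_m
        xs = self.x0 + np.array([ix, ix + 1, ix + 1, ix, ix]) * s
        ys = self.y0 + np.array([iy, iy, iy + 1, iy + 1, iy]) * s
        lon, lat = self.crs.unproject(xs, ys)
        return [[float(a), float(b)] for a, b in zip(lon, lat)]


@dataclass
class HotspotGrid:
    """Per-cell counts and standardised rates on a :class:`GridSpec`.

    Count arrays are indexed ``[ix, iy]``. ``overflow`` counts points that
    fell outside the declared extent, per kind.
    """

    spec: GridSpec
    n_meas: np.ndarray
    n_mos: np.ndarray
    n_diary_neg: np.ndarray
    n_diary_pos: np.ndarray
    min_support: int = 10
    overflow: dict = field(default_factory=lambda: {k: 0 for k in COUNT_KINDS})

    @property
    def included(self) -> np.ndarray:
        return self.n_meas >= self.min_support

    def counts(self, kind: str) -> np.ndarray:
        return getattr(self, f"n_{kind}")

    def rate(self, kind: str = "mos") -> np.ndarray:
        """Standardised rate x(c) = n_kind / n_meas on included cells, else NaN."""
        out = np.full(self.n_meas.shape, np.nan)
        inc = self.included
        out[inc] = self.counts(kind)[inc] / self.n_meas[inc]
        return out

    def included_cells(self) -> list[tuple[int, int]]:
        ix, iy = np.nonzero(self.included)
        return list(zip(ix.tolist(), iy.tolist()))


def _bincount(spec: GridSpec, xy: Optional[np.ndarray]) -> tuple[np.ndarray, int]:
    counts = np.zeros((spec.nx, spec.ny), dtype=np.int64)
    if xy is None or len(xy) == 0:
        return counts, 0
    xy = np.asarray(xy, dtype=float)
    ix, iy = spec.cell_index(xy[:, 0], xy[:, 1])
    inside = (ix >= 0) & (ix < spec.nx) & (iy >= 0) & (iy < spec.ny)
    np.add.at(counts, (ix[inside], iy[inside]), 1)
    return counts, int((~inside).sum())


def rasterize(
    spec: GridSpec,
    samples_xy: Optional[np.ndarray],
    mos_xy: Optional[np.ndarray] = None,
    diary_neg_xy: Optional[np.ndarray] = None,
    diary_pos_xy: Optional[np.ndarray] = None,
    min_support: int = 10,
) -> HotspotGrid:
    """Aggregate projected points (metres, same CRS as ``spec``) to cells.

    Counts are conserved: in-grid cell sums plus the overflow bin equal the
    input sizes for every kind.
    """
    arrays = {}
    overflow = {}
    for kind, xy in (("meas", samples_xy), ("mos", mos_xy),
                     ("diary_neg", diary_neg_xy), ("diary_pos", diary_pos_xy)):
        arrays[kind], overflow[kind] = _bincount(spec, xy)
    return HotspotGrid(
        spec=spec,
        n_meas=arrays["meas"],
        n_mos=arrays["mos"],
        n_diary_neg=arrays["diary_neg"],
        n_diary_pos=arrays["diary_pos"],
        min_support=min_support,
        overflow=overflow,
    )


# ---------------------------------------------------------------------------
# spatial weights and Gi*

@dataclass
class SpatialWeights:
    """Binary, symmetric, self-inclusive weights between included cells."""

    w: np.ndarray  # (k, k) 0/1 matrix, w[i, i] == 1

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConfigError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ConfigError("weights must be symmetric")
        if not np.all(np.diag(w) == 1):
            raise ConfigError("self weight w_ii = 1 is required (the Gi* 'star')")
        self.w = w

    @classmethod
    def distance_band(cls, coords: np.ndarray, band_m: float) -> "SpatialWeights":
        """w_ij = 1 iff centroid distance <= band_m (includes self, d=0)."""
        coords = np.asarray(coords, dtype=float)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        return cls(w=(d2 <= band_m**2).astype(float))

    @classmethod
    def from_grid(cls, grid: HotspotGrid, band_m: Optional[float] = None) -> "SpatialWeights":
        band = band_m if band_m is not None else 2.0 * grid.spec.cell_size_m
        cells = grid.included_cells()
        cx, cy = grid.spec.centroid([c[0] for c in cells], [c[1] for c in cells])
        return cls.distance_band(np.column_stack([cx, cy]), band)


def gi_star_z(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gi* z-scores for values ``x`` under weight matrix ``w``.

    Degenerate cases: S = 0 (all values equal) gives z = 0 everywhere, and a
    cell whose neighbourhood is the whole field (denominator 0) gets z = 0.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientCellsError(f"Gi* needs >= 2 cells, got {n}")
    xbar = x.mean()
    s = np.sqrt(np.maximum((x**2).mean() - xbar**2, 0.0))
    if s == 0:
        return np.zeros(n)
    w_sum = w.sum(axis=1)
    s1 = (w**2).sum(axis=1)
    num = w @ x - xbar * w_sum
    denom_sq = (n * s1 - w_sum**2) / (n - 1)
    z = np.zeros(n)
    pos = denom_sq > 0
    z[pos] = num[pos] / (s * np.sqrt(denom_sq[pos]))
    return z


@dataclass
class GiStarResult:
    """Gi* z-scores and hot/cold classification over included cells."""

    grid: HotspotGrid
    cells: list[tuple[int, int]]
    z: np.ndarray
    x: np.ndarray
    n: int
    xbar: float
    s: float

    def classification(self) -> list[str]:
        return [classify_z(float(v)) for v in self.z]


def classify_z(z: float) -> str:
    for thr, level in Z_THRESHOLDS:
        if z >= thr:
            return f"hot{level}"
        if z <= -thr:
            return f"cold{level}"
    return "neutral"


def gi_star(
    grid: HotspotGrid,
    weights: Optional[SpatialWeights] = None,
    value: str = "mos",
) -> GiStarResult:
    """Getis-Ord Gi* over the included cells of a grid."""
    cells = grid.included_cells()
    if len(cells) < 2:
        raise InsufficientCellsError(
            f"only {len(cells)} cells have >= {grid.min_support} samples"
        )
    weights = weights or SpatialWeights.from_grid(grid)
    if weights.w.shape[0] != len(cells):
        raise ContractError("weights size does not match included cells")
    rate = grid.rate(value)
    x = np.array([rate[c] for c in cells])
    z = gi_star_z(x, weights.w)
    return GiStarResult(
        grid=grid, cells=cells, z=z, x=x, n=len(x),
        xbar=float(x.mean()),
        s=float(np.sqrt(max((x**2).mean() - x.mean() ** 2, 0.0))),
    )


def classify(result: GiStarResult) -> dict:
    """Map layers: GeoJSON cell polygons plus a flat summary table."""
    spec = result.grid.spec
    features = []
    rows = []
    for (ix, iy), z, x, cls_ in zip(result.cells, result.z, result.x,
                                    result.classification()):
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [spec.cell_polygon_lonlat(ix, iy)],
            },
            "properties": {"ix": int(ix), "iy": int(iy), "z": float(z),
                           "rate": float(x), "class": cls_},
        })
        rows.append({"ix": int(ix), "iy": int(iy), "z": float(z),
                     "rate": float(x), "class": cls_})
    return {
        "geojson": {"type": "FeatureCollection", "features": features},
        "table": pd.DataFrame(rows),
    }


def write_layers(layers: dict, out_geojson, out_csv) -> None:
    with open(out_geojson, "w") as fh:
        json.dump(layers["geojson"], fh, indent=1)
    layers["table"].to_csv(out_csv, index=False)


# ---------------------------------------------------------------------------
# difference map: sensor-derived vs diary-derived stress surfaces

def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def difference_map(
    sensor_grid: HotspotGrid,
    diary_grid: HotspotGrid,
    sensor_value: str = "mos",
    diary_value: str = "diary_neg",
) -> dict:
    """Signed per-cell difference of min-max-normalised rates (sensor - diary).

    Cells present in either grid contribute; a side missing a cell counts as
    0 after normalisation over its own included cells.
    """
    if sensor_grid.spec != diary_grid.spec:
        raise ContractError("difference_map requires grids on the same GridSpec")

    def normalised(grid: HotspotGrid, value: str) -> dict[tuple[int, int], float]:
        cells = grid.included_cells()
        if not cells:
            return {}
        rate = grid.rate(value)
        vals = np.array([rate[c] for c in cells])
        norm = _minmax(vals)
        return dict(zip(cells, norm.tolist()))

    a = normalised(sensor_grid, sensor_value)
    b = normalised(diary_grid, diary_value)
    cells = sorted(set(a) | set(b))
    diff = np.array([a.get(c, 0.0) - b.get(c, 0.0) for c in cells])
    spec = sensor_grid.spec
    features = [{
        "type": "Feature",
        "geometry": {"type": "Polygon",
                     "coordinates": [spec.cell_polygon_lonlat(ix, iy)]},
        "properties": {"ix": int(ix), "iy": int(iy), "difference": float(d)},
    } for (ix, iy), d in zip(cells, diff)]
    return {
        "cells": cells,
        "difference": diff,
        "geojson": {"type": "FeatureCollection", "features": features},
    }


# ---------------------------------------------------------------------------
# pre-post campaign comparison

@dataclass
class CampaignChange:
    """Percent change in the stress statistic, overall and per zone."""

    overall_pct: float
    zones: dict[str, float] = field(default_factory=dict)
    mode: str = "raw_counts"


def _zone_stats(source, zones, mode: str) -> dict[str, tuple[float, float]]:
    """Normalise input to {zone: (count, exposure)}.

    ``source`` is a HotspotGrid (zones tested against cell centroids) or a
    mapping {zone: {"mos": n, "exposure": e}} / {zone: (n, e)}.
    """
    if isinstance(source, HotspotGrid):
        out: dict[str, tuple[float, float]] = {}
        ix, iy = np.nonzero(np.ones_like(source.n_meas, dtype=bool))
        cx, cy = source.spec.centroid(ix, iy)
        mos = source.n_mos[ix, iy].astype(float)
        meas = source.n_meas[ix, iy].astype(float)
        if zones is None:
            out["overall"] = (float(mos.sum()), float(meas.sum()))
        else:
            from shapely.geometry import Point
            for name, poly in zones.items():
                mask = np.array([poly.covers(Point(x, y)) for x, y in zip(cx, cy)])
                out[name] = (float(mos[mask].sum()), float(meas[mask].sum()))
            out["overall"] = (float(mos.sum()), float(meas.sum()))
        return out
    out = {}
    for name, val in source.items():
        if isinstance(val, Mapping):
            out[name] = (float(val["mos"]), float(val.get("exposure", 1.0)))
        else:
            out[name] = (float(val[0]), float(val[1]))
    if "overall" not in out:
        out["overall"] = (sum(v[0] for v in out.values()),
                          sum(v[1] for v in out.values()))
    return out


def compare_campaigns(
    pre,
    post,
    mode: str = "raw_counts",
    zones: Optional[dict] = None,
) -> CampaignChange:
    """Percent change (post - pre) / pre * 100 of the stress statistic.

    ``raw_counts`` compares event counts directly; ``exposure_rate`` divides
    counts by exposure (measurement time or sample count) first, so campaigns
    with unequal coverage remain comparable.
    """
    if mode not in ("raw_counts", "exposure_rate"):
        raise ConfigError(f"unknown comparison mode {mode!r}")
    pre_stats = _zone_stats(pre, zones, mode)
    post_stats = _zone_stats(post, zones, mode)

    def stat(count: float, exposure: float) -> float:
        if mode == "raw_counts":
            return count
        if exposure == 0:
            raise UndefinedChangeError("zero exposure in exposure_rate mode")
        return count / exposure

    changes = {}
    for name in pre_stats:
        if name not in post_stats:
            continue
        s_pre = stat(*pre_stats[name])
        s_post = stat(*post_stats[name])
        if s_pre == 0:
            raise UndefinedChangeError(
                f"pre-campaign statistic is zero in zone {name!r}; percent change undefined"
            )
        changes[name] = (s_post - s_pre) / s_pre * 100.0
    overall = changes.pop("overall")
    return CampaignChange(overall_pct=overall, zones=changes, mode=mode)
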