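"""Synthetic farmed-island landscape.

A square extent in projected metres (a fictional national-grid-like
frame) is tiled with rectangular farms, each subdivided into fields; a
subset of fields is designated for shooting.  A 7-class habitat raster,
a sparse road network and a handful of night roosts complete the
structure the downstream analyses need: farm membership for modal-farm
grouping, field polygons for in-field exposure, habitat codes and road
distances for resource selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box, mapping, shape
from shapely.strtree import STRtree

from fearscape.config import HABITAT_CODES, SimulationConfig


@dataclass
class Landscape:
    extent: tuple              # (x0, y0, x1, y1) metres
    farms: dict                # farm_id -> shapely Polygon
    fields: dict               # field_id -> shapely Polygon
    field_farm: dict           # field_id -> farm_id
    shooting_fields: tuple     # field_ids eligible for shooting
    habitat: np.ndarray        # int codes, row 0 = northern edge
    cell_size: float
    roads: list                # list of LineString
    roosts: list               # list of Point
    _farm_tree: STRtree | None = field(default=None, repr=False, compare=False)
    _farm_ids: list | None = field(default=None, repr=False, compare=False)

    # -- geometry helpers ---------------------------------------------

    def farm_at(self, x: float, y: float):
        """Farm id containing (x, y); boundary points count as inside."""
        if self._farm_tree is None:
            self._farm_ids = sorted(self.farms)
            self._farm_tree = STRtree([self.farms[f] for f in self._farm_ids])
        hits = self._farm_tree.query(Point(x, y), predicate="covered_by")
        if len(hits) == 0:
            return None
        return self._farm_ids[min(hits)]

    def farms_at(self, xs, ys) -> np.ndarray:
        """Vectorised :meth:`farm_at` over coordinate arrays."""
        import shapely

        if self._farm_tree is None:
            self._farm_ids = sorted(self.farms)
            self._farm_tree = STRtree([self.farms[f] for f in self._farm_ids])
        pts = shapely.points(np.asarray(xs, float), np.asarray(ys, float))
        out = np.full(len(pts), None, dtype=object)
        pt_idx, farm_idx = self._farm_tree.query(pts, predicate="covered_by")
        # boundary points can match two farms: keep the lexicographically
        # smallest id so membership is deterministic
        order = np.lexsort((farm_idx, pt_idx))
        for i, j in zip(pt_idx[order[::-1]], farm_idx[order[::-1]]):
            out[i] = self._farm_ids[j]
        return out

    def habitat_at(self, xs, ys) -> np.ndarray:
        """Habitat code at coordinates; -1 for off-raster points."""
        x0, y0, x1, y1 = self.extent
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        nrow, ncol = self.habitat.shape
        col = np.floor((xs - x0) / self.cell_size).astype(int)
        row = np.floor((y1 - ys) / self.cell_size).astype(int)
        # points on the far extent edge belong to the last cell
        col = np.where((xs == x1) & (col == ncol), ncol - 1, col)
        row = np.where((ys == y0) & (row == nrow), nrow - 1, row)
        ok = (col >= 0) & (col < ncol) & (row >= 0) & (row < nrow)
        out = np.full(xs.shape, -1, dtype=int)
        out[ok] = self.habitat[row[ok], col[ok]]
        return out

    def habitat_fractions(self) -> dict:
        codes, counts = np.unique(self.habitat, return_counts=True)
        total = self.habitat.size
        return {int(c): n / total for c, n in zip(codes, counts)}

    def contains(self, x, y) -> np.ndarray:
        x0, y0, x1, y1 = self.extent
        return (np.asarray(x) >= x0) & (np.asarray(x) <= x1) & \
               (np.asarray(y) >= y0) & (np.asarray(y) <= y1)


def _habitat_raster(n: int, proportions: dict, rng: np.random.Generator) -> np.ndarray:
    """Spatially coherent class raster with exact class proportions.

    A coarse Gaussian noise field is upsampled to the raster grid, a
    little fine noise is added to break ties, and cells are classified
    by rank so each class receives exactly its configured share.
    """
    coarse = max(8, n // 20)
    base = rng.standard_normal((coarse, coarse))
    rep = int(np.ceil(n / coarse))
    fine = np.kron(base, np.ones((rep, rep)))[:n, :n]
    fine = fine + 0.15 * rng.standard_normal((n, n))
    order = np.argsort(fine, axis=None, kind="stable")
    raster = np.empty(n * n, dtype=int)
    start = 0
    items = sorted(proportions.items(), key=lambda kv: HABITAT_CODES[kv[0]])
    for i, (name, frac) in enumerate(items):
        stop = n * n if i == len(items) - 1 else start + int(round(frac * n * n))
        raster[order[start:stop]] = HABITAT_CODES[name]
        start = stop
    return raster.reshape(n, n)


def generate_landscape(config: SimulationConfig) -> Landscape:
    """Build a deterministic landscape from the configuration seed."""
    if config.extent_m <= 0:
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    L = config.extent_m
    nr, nc = config.n_farm_rows, config.n_farm_cols

    # jittered interior grid lines -> rectangular, mutually disjoint farms
    def cuts(k):
        c = np.linspace(0, L, k + 1)
        c[1:-1] += rng.uniform(-0.15, 0.15, k - 1) * (L / k)
        return c

    xs, ys = cuts(nc), cuts(nr)
    farms, fields, field_farm = {}, {}, {}
    for r in range(nr):
        for c in range(nc):
            farm_id = f"F{r * nc + c + 1:02d}"
            farms[farm_id] = box(xs[c], ys[r], xs[c + 1], ys[r + 1])
            m = config.fields_per_farm_side
            fx = np.linspace(xs[c], xs[c + 1], m + 1)
            fy = np.linspace(ys[r], ys[r + 1], m + 1)
            for i in range(m):
                for j in range(m):
                    fid = f"{farm_id}-{i * m + j + 1}"
                    fields[fid] = box(fx[j], fy[i], fx[j + 1], fy[i + 1])
                    field_farm[fid] = farm_id

    field_ids = sorted(fields)
    n_shoot = max(1, int(round(config.shooting_field_fraction * len(field_ids))))
    shooting = tuple(sorted(rng.choice(field_ids, size=n_shoot, replace=False)))

    # roads: alternating horizontal/vertical polylines with gentle jitter
    roads = []
    for i in range(config.n_roads):
        offset = rng.uniform(0.1, 0.9) * L
        s = np.linspace(0, L, 21)
        wiggle = np.cumsum(rng.normal(0, L / 200, s.size))
        wiggle -= wiggle.mean()
        if i % 2 == 0:
            pts = np.column_stack([s, np.clip(offset + wiggle, 0, L)])
        else:
            pts = np.column_stack([np.clip(offset + wiggle, 0, L), s])
        roads.append(LineString(pts))

    # roosts in the outer ring of the island (lochs/coast analogue)
    roosts = []
    for _ in range(config.n_roosts):
        edge = rng.integers(4)
        along = rng.uniform(0.15, 0.85) * L
        depth = rng.uniform(0.05, 0.15) * L
        xy = [(along, depth), (along, L - depth), (depth, along), (L - depth, along)][edge]
        roosts.append(Point(*xy))

    n_cells = int(round(L / config.cell_size_m))
    habitat = _habitat_raster(n_cells, config.habitat_proportions, rng)

    return Landscape(
        extent=(0.0, 0.0, L, L),
        farms=farms,
        fields=fields,
        field_farm=field_farm,
        shooting_fields=shooting,
        habitat=habitat,
        cell_size=config.cell_size_m,
        roads=roads,
        roosts=roosts,
    )


# -- serialization ----------------------------------------------------

def write_landscape_geojson(landscape: Landscape, path) -> None:
    """Farms, fields, roads and roosts as one GeoJSON FeatureCollection."""
    feats = []
    for fid in sorted(landscape.farms):
        feats.append({"type": "Feature", "properties": {"kind": "farm", "id": fid},
                      "geometry": mapping(landscape.farms[fid])})
    for fid in sorted(landscape.fields):
        feats.append({"type": "Feature",
                      "properties": {"kind": "field", "id": fid,
                                     "farm_id": landscape.field_farm[fid],
                                     "shooting": fid in landscape.shooting_fields},
                      "geometry": mapping(landscape.fields[fid])})
    for i, road in enumerate(landscape.roads):
        feats.append({"type": "Feature", "properties": {"kind": "road", "id": f"R{i + 1}"},
                      "geometry": mapping(road)})
    for i, roost in enumerate(landscape.roosts):
        feats.append({"type": "Feature", "properties": {"kind": "roost", "id": f"roost{i + 1}"},
                      "geometry": mapping(roost)})
    bundle = {"type": "FeatureCollection",
              "properties": {"extent": list(landscape.extent),
                             "cell_size": landscape.cell_size},
              "features": feats}
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def read_landscape_geojson(path, habitat: np.ndarray | None = None) -> Landscape:
    with open(path) as fh:
        bundle = json.load(fh)
    farms, fields, field_farm, roads, roosts, shooting = {}, {}, {}, [], [], []
    for feat in bundle["features"]:
        props, geom = feat["properties"], shape(feat["geometry"])
        if props["kind"] == "farm":
            farms[props["id"]] = geom
        elif props["kind"] == "field":
            fields[props["id"]] = geom
            field_farm[props["id"]] = props["farm_id"]
            if props.get("shooting"):
                shooting.append(props["id"])
        elif props["kind"] == "road":
            roads.append(geom)
        elif props["kind"] == "roost":
            roosts.append(geom)
    extent = tuple(bundle["properties"]["extent"])
    cell = bundle["properties"]["cell_size"]
    if habitat is None:
        n = int(round((extent[2] - extent[0]) / cell))
        habitat = np.zeros((n, n), dtype=int)
    return Landscape(extent=extent, farms=farms, fields=fields, field_farm=field_farm,
                     shooting_fields=tuple(sorted(shooting)), habitat=habitat,
                     cell_size=cell, roads=roads, roosts=roosts)


def write_ascii_grid(raster: np.ndarray, cell_size: float, path,
                     xll: float = 0.0, yll: float = 0.0) -> None:
    """ESRI ASCII grid (.asc): portable plain-text raster."""
    nrow, ncol = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\nnrows {nrow}\nxllcorner {xll}\nyllcorner {yll}\n")
        fh.write(f"cellsize {cell_size}\nNODATA_value -9999\n")
        np.savetxt(fh, raster, fmt="%d")


def read_ascii_grid(path):
    """Returns (raster, cell_size, xll, yll)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        raster = np.loadtxt(fh, dtype=int)
    raster = raster.reshape(int(header["nrows"]), int(header["ncols"]))
    return raster, header["cellsize"], header["xllcorner"], header["yllcorner"]
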