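"""Spatial plumbing: unit geometries, contiguity weights, population-weighted centroids.

Coordinates are assumed planar/projected (meters). Geographic lat/lon input
must be projected before use — scan distances and weighted centroids are
Euclidean. Loaders refuse coordinate ranges that look geographic
(|x| <= 180 and |y| <= 90) unless explicitly overridden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "UnitGeometry",
    "ContiguityWeights",
    "build_contiguity_weights",
    "population_weighted_centroid",
    "unit_centroids",
    "read_units_geojson",
    "write_units_geojson",
    "read_grid_csv",
]


@dataclass
class UnitGeometry:
    """A spatial analysis unit (ZIP-5-like) with a planar polygon."""

    unit_id: str
    polygon: BaseGeometry
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"invalid polygon for unit {self.unit_id!r}")


@dataclass
class ContiguityWeights:
    """First-order contiguity neighbor structure over a unit collection.

    ``neighbors`` maps unit_id -> list of neighboring unit_ids. The binary
    relation is symmetric with no self-neighbors. ``weights`` holds the
    per-neighbor weight (1/|N(i)| if row-standardized, else 1). Units with
    no neighbors (islands) are retained with empty lists.
    """

    neighbors: dict[str, list[str]]
    order: str = "queen"
    row_standardized: bool = False
    weights: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = {
                i: [
                    (1.0 / len(nbrs) if self.row_standardized else 1.0)
                    for _ in nbrs
                ]
                for i, nbrs in self.neighbors.items()
            }

    @property
    def ids(self) -> list[str]:
        return list(self.neighbors)

    @property
    def islands(self) -> list[str]:
        return [i for i, nbrs in self.neighbors.items() if not nbrs]

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(sum(sum(w) for w in self.weights.values()))

    def to_matrix(self, ids: list[str] | None = None) -> np.ndarray:
        """Dense weight matrix ordered by ``ids`` (default: insertion order)."""
        ids = ids if ids is not None else self.ids
        pos = {u: k for k, u in enumerate(ids)}
        W = np.zeros((len(ids), len(ids)))
        for i, nbrs in self.neighbors.items():
            for j, w in zip(nbrs, self.weights[i]):
                W[pos[i], pos[j]] = w
        return W

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            (i, j, w)
            for i, nbrs in self.neighbors.items()
            for j, w in zip(nbrs, self.weights[i])
        ]
        return pd.DataFrame(rows, columns=["i", "j", "w"])


def _check_planar(xs: np.ndarray, ys: np.ndarray, allow_geographic: bool) -> None:
    if allow_geographic:
        return
    if np.all(np.abs(xs) <= 180.0) and np.all(np.abs(ys) <= 90.0):
        raise ValueError(
            "coordinates look geographic (lat/lon); project to planar meters "
            "first or pass allow_geographic=True"
        )


def build_contiguity_weights(
    units: list[UnitGeometry],
    order: str = "queen",
    row_standardize: bool = False,
) -> ContiguityWeights:
    """Build first-order queen or rook contiguity weights.

    Queen contiguity: any shared boundary point (a corner suffices).
    Rook contiguity: a shared boundary segment of positive length.

    Islands (units touching nothing) are retained with an empty neighbor
    list and reported through the module logger; downstream statistics that
    are undefined for islands (smoothing, LISA) skip them.
    """
    if order not in ("queen", "rook"):
        raise ValueError(f"order must be 'queen' or 'rook', got {order!r}")
    if len(units) < 2:
        raise ValueError("need at least 2 units to build contiguity weights")
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_id in unit collection")
    for u in units:
        if not u.polygon.is_valid:
            raise ValueError(f"invalid polygon for unit {u.unit_id!r}")

    geoms = [u.polygon for u in units]
    tree = STRtree(geoms)
    neighbors: dict[str, set[str]] = {i: set() for i in ids}
    for a, ga in enumerate(geoms):
        for b in tree.query(ga, predicate="intersects"):
            b = int(b)
            if b == a:
                continue
            inter = ga.intersection(geoms[b])
            if inter.is_empty:
                continue
            if order == "queen" or inter.length > 0:
                neighbors[ids[a]].add(ids[b])
                neighbors[ids[b]].add(ids[a])

    nbr_lists = {i: sorted(neighbors[i]) for i in ids}
    islands = [i for i, n in nbr_lists.items() if not n]
    if islands:
        logger.warning("%d island unit(s) with no neighbors: %s", len(islands), islands[:10])
    return ContiguityWeights(
        neighbors=nbr_lists, order=order, row_standardized=row_standardize
    )


def population_weighted_centroid(
    x: np.ndarray,
    y: np.ndarray,
    population: np.ndarray,
    *,
    unit_id: str | None = None,
    fallback_arithmetic: bool = False,
) -> tuple[float, float]:
    """Population-weighted mean of grid-cell centroids.

    X̄ = Σ ω_i x_i / Σ ω_i, Ȳ = Σ ω_i y_i / Σ ω_i, with ω the cell
    populations. The result lies in the convex hull of the cell centroids.
    A unit whose cells carry zero total population is an error unless
    ``fallback_arithmetic`` permits the plain arithmetic centroid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(population, dtype=float)
    if x.size == 0:
        raise ValueError(f"no grid cells for unit {unit_id!r}")
    if np.any(w < 0):
        raise ValueError(f"negative cell population for unit {unit_id!r}")
    total = w.sum()
    if total <= 0:
        if fallback_arithmetic:
            return float(x.mean()), float(y.mean())
        raise ValueError(f"total population is zero for unit {unit_id!r}")
    return float((w * x).sum() / total), float((w * y).sum() / total)


def unit_centroids(
    grid: pd.DataFrame, *, fallback_arithmetic: bool = False, allow_geographic: bool = False
) -> pd.DataFrame:
    """Population-weighted centroid per unit from a grid-cell table.

    ``grid`` needs columns x, y, population, unit_id. Returns a frame
    indexed by unit_id with columns x, y, population (unit total).
    """
    required = {"x", "y", "population", "unit_id"}
    missing = required - set(grid.columns)
    if missing:
        raise ValueError(f"grid table missing columns: {sorted(missing)}")
    _check_planar(grid["x"].to_numpy(), grid["y"].to_numpy(), allow_geographic)
    rows = {}
    for uid, g in grid.groupby("unit_id", sort=True):
        cx, cy = population_weighted_centroid(
            g["x"].to_numpy(),
            g["y"].to_numpy(),
            g["population"].to_numpy(),
            unit_id=str(uid),
            fallback_arithmetic=fallback_arithmetic,
        )
        rows[uid] = (cx, cy, float(g["population"].sum()))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y", "population"])
    out.index.name = "unit_id"
    return out


def read_units_geojson(path, *, allow_geographic: bool = False) -> list[UnitGeometry]:
    """Read unit polygons from a GeoJSON FeatureCollection (property ``unit_id``)."""
    with open(path) as fh:
        gj = json.load(fh)
    units = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        uid = str(feat["properties"]["unit_id"])
        xs, ys = np.asarray(geom.exterior.coords).T if geom.geom_type == "Polygon" else (
            np.asarray(geom.bounds[::2]),
            np.asarray(geom.bounds[1::2]),
        )
        _check_planar(xs, ys, allow_geographic)
        units.append(UnitGeometry(unit_id=uid, polygon=geom))
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_id in GeoJSON")
    return units


def write_units_geojson(units: list[UnitGeometry], path, properties: dict[str, dict] | None = None) -> None:
    """Write a unit collection as a GeoJSON FeatureCollection."""
    feats = []
    for u in units:
        props = {"unit_id": u.unit_id}
        if properties and u.unit_id in properties:
            props.update(properties[u.unit_id])
        feats.append(
            {"type": "Feature", "geometry": mapping(u.polygon), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_grid_csv(path) -> pd.DataFrame:
    """Read a grid-cell table (columns x, y, population, unit_id)."""
    grid = pd.read_csv(path, dtype={"unit_id": str})
    return grid
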