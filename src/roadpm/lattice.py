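"""Regular lattice geometries standing in for county maps.

A lattice of congruent square cells is the synthetic analogue of a county
polygon map: it has the Queen-contiguity structure (8-neighbourhood) that the
spatial panel models need, planar centroid coordinates in km for the GTWR
distance kernel, and polygons that round-trip through GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box, mapping, shape

__all__ = ["LatticeGeometry", "make_lattice", "write_geojson", "read_geojson"]


@dataclass
class LatticeGeometry:
    """A rectangular grid of square cells with ids, centroids and polygons.

    Attributes
    ----------
    county_ids : list of str
        Ordered opaque unit identifiers (row-major over the grid).
    centroids : ndarray, shape (n, 2)
        Planar (x, y) centroid coordinates in km.
    polygons : list of shapely.Polygon
        One square cell per unit, congruent, non-overlapping.
    n_rows, n_cols : int
        Grid dimensions; ``n = n_rows * n_cols``.
    cell_km : float
        Side length of each cell in km.
    """

    county_ids: list[str]
    centroids: np.ndarray
    polygons: list[Polygon]
    n_rows: int
    n_cols: int
    cell_km: float = field(default=1.0)

    @property
    def n(self) -> int:
        return len(self.county_ids)

    def __post_init__(self) -> None:
        if self.n != self.n_rows * self.n_cols:
            raise ValueError(
                f"{self.n} units inconsistent with {self.n_rows}x{self.n_cols} grid"
            )
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (self.n, 2):
            raise ValueError("centroids must have shape (n, 2)")


def make_lattice(n_rows: int, n_cols: int, cell_km: float) -> LatticeGeometry:
    """Build an ``n_rows x n_cols`` lattice of square cells of side ``cell_km``.

    Cells are laid out row-major with the origin at the south-west corner;
    the unit in grid position (r, c) has id ``c%04d`` over the flat index
    ``r * n_cols + c`` and centroid ``((c + 1/2) s, (r + 1/2) s)``.

    Deterministic given its arguments.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive integers")
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    s = float(cell_km)
    ids, cents, polys = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"c{r * n_cols + c:04d}")
            cents.append(((c + 0.5) * s, (r + 0.5) * s))
            polys.append(box(c * s, r * s, (c + 1) * s, (r + 1) * s))
    return LatticeGeometry(
        county_ids=ids,
        centroids=np.asarray(cents),
        polygons=polys,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_km=s,
    )


def write_geojson(geometry: LatticeGeometry, path) -> None:
    """Serialize polygons + ids as a GeoJSON FeatureCollection."""
    features = []
    for i, (cid, poly) in enumerate(zip(geometry.county_ids, geometry.polygons)):
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "county_id": cid,
                    "x": float(geometry.centroids[i, 0]),
                    "y": float(geometry.centroids[i, 1]),
                },
                "geometry": mapping(poly),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "n_rows": geometry.n_rows,
            "n_cols": geometry.n_cols,
            "cell_km": geometry.cell_km,
        },
        "features": features,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_geojson(path) -> LatticeGeometry:
    """Read a FeatureCollection written by :func:`write_geojson`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    ids, cents, polys = [], [], []
    for feat in doc["features"]:
        props = feat["properties"]
        ids.append(str(props["county_id"]))
        poly = shape(feat["geometry"])
        if "x" in props and "y" in props:
            cents.append((float(props["x"]), float(props["y"])))
        else:
            cents.append((poly.centroid.x, poly.centroid.y))
        polys.append(poly)
    meta = doc.get("properties", {})
    n_rows = int(meta.get("n_rows", 1))
    n_cols = int(meta.get("n_cols", len(ids)))
    return LatticeGeometry(
        county_ids=ids,
        centroids=np.asarray(cents),
        polygons=polys,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_km=float(meta.get("cell_km", 1.0)),
    )
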