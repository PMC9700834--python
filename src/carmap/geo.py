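"""Queen-contiguity neighbour structure for areal units.

Areal disease-mapping models borrow strength across neighbouring zones
through a spatial weight matrix.  Here two zones are neighbours (queen
contiguity) when their boundaries share at least one point -- an edge or
a single corner both count, like the moves of a chess queen.  The weight
matrix is binary and symmetric with a zero diagonal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


class GeometryValidationError(ValueError):
    """Raised when a GeoJSON input violates the id/geometry contract."""


class AdjacencyValidationError(ValueError):
    """Raised when a weight matrix violates a structural invariant."""


@dataclass
class ZoneGeometry:
    """One areal unit: an id label plus its polygon geometry (WGS84 lon/lat)."""

    zone_id: str
    geometry: BaseGeometry
    area_name: str | None = None


@dataclass
class AdjacencyMatrix:
    """Binary symmetric queen-contiguity weights over an ordered zone set.

    Attributes
    ----------
    zone_ids : list of str
        Zone order; indexes rows/columns of ``weights``.
    weights : ndarray, shape (n, n)
        0/1 entries, symmetric, zero diagonal.
    neighbors : list of lists of int
        Per-zone neighbour indices, consistent with ``weights``.
    islands : set of str
        Zones with no neighbours (zero row sum).
    n_components : int
        Connected components of the contiguity graph (islands count as
        singleton components).
    """

    zone_ids: list[str]
    weights: np.ndarray
    neighbors: list[list[int]] = field(default_factory=list)
    islands: set[str] = field(default_factory=set)
    n_components: int = 0

    @property
    def n(self) -> int:
        return len(self.zone_ids)

    @property
    def row_sums(self) -> np.ndarray:
        """Number of neighbours m_i per zone."""
        return self.weights.sum(axis=1)

    def components(self) -> list[set[int]]:
        """Connected components as sets of zone indices."""
        g = nx.from_numpy_array(self.weights)
        return [set(c) for c in nx.connected_components(g)]


def read_geojson(path, id_property: str = "zone_id",
                 name_property: str = "area_name") -> list[ZoneGeometry]:
    """Read a GeoJSON FeatureCollection into a list of :class:`ZoneGeometry`.

    Feature order is preserved; MultiPolygon features stay a single zone.
    Raises :class:`GeometryValidationError` on a missing or duplicated id
    property, naming the offending feature.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeometryValidationError(f"{path}: not a GeoJSON FeatureCollection")
    zones: list[ZoneGeometry] = []
    seen: dict[str, int] = {}
    for idx, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise GeometryValidationError(
                f"feature {idx}: missing id property {id_property!r}")
        zid = str(props[id_property])
        if zid in seen:
            raise GeometryValidationError(
                f"duplicate zone id {zid!r} (features {seen[zid]} and {idx})")
        seen[zid] = idx
        geom = shape(feat["geometry"])
        zones.append(ZoneGeometry(zone_id=zid, geometry=geom,
                                  area_name=props.get(name_property)))
    return zones


def write_geojson(zones: list[ZoneGeometry], path,
                  extra_properties: dict[str, dict] | None = None,
                  id_property: str = "zone_id") -> None:
    """Write zones (optionally with per-zone property dicts) as GeoJSON."""
    feats = []
    for z in zones:
        props = {id_property: z.zone_id}
        if z.area_name is not None:
            props["area_name"] = z.area_name
        if extra_properties and z.zone_id in extra_properties:
            props.update(extra_properties[z.zone_id])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(z.geometry)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def queen_adjacency(zones: list[ZoneGeometry], tol: float = 0.0) -> AdjacencyMatrix:
    """Build the binary queen-contiguity weight matrix.

    w_ij = 1 iff zones i != j share at least one boundary point; with
    tol > 0 the touch test becomes "within tol" (for dirty real-world
    geometries with hairline gaps).  Zero-area polygons trigger a warning
    but are still processed.
    """
    if not zones:
        raise ValueError("queen_adjacency requires at least one zone")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    n = len(zones)
    for z in zones:
        if z.geometry.area == 0:
            warnings.warn(f"zone {z.zone_id!r} has zero area", stacklevel=2)
    W = np.zeros((n, n), dtype=int)
    geoms = [z.geometry for z in zones]
    for i in range(n):
        for j in range(i + 1, n):
            if tol > 0:
                touch = geoms[i].distance(geoms[j]) <= tol
            else:
                touch = geoms[i].intersects(geoms[j])
            if touch:
                W[i, j] = W[j, i] = 1
    return _finalize(zones, W)


def _finalize(zones: list[ZoneGeometry], W: np.ndarray) -> AdjacencyMatrix:
    neighbors = [list(np.flatnonzero(W[i])) for i in range(len(zones))]
    islands = {zones[i].zone_id for i in range(len(zones)) if not neighbors[i]}
    g = nx.from_numpy_array(W)
    ncomp = nx.number_connected_components(g)
    if islands:
        warnings.warn(
            f"{len(islands)} island zone(s) with no neighbours: {sorted(islands)}",
            stacklevel=3)
    return AdjacencyMatrix([z.zone_id for z in zones], W, neighbors, islands, ncomp)


def validate_adjacency(A: AdjacencyMatrix) -> dict:
    """Assert structural invariants of a weight matrix.

    Returns a report dict with per-zone neighbour counts and component
    count.  Raises :class:`AdjacencyValidationError` listing offending
    entries on any violation (asymmetry, nonzero diagonal, non-binary
    entries, inconsistent neighbour lists).
    """
    W = np.asarray(A.weights)
    problems: list[str] = []
    if W.ndim != 2 or W.shape[0] != W.shape[1] or W.shape[0] != len(A.zone_ids):
        raise AdjacencyValidationError(f"weight matrix shape {W.shape} does not "
                                       f"match {len(A.zone_ids)} zones")
    bad_diag = np.flatnonzero(np.diag(W) != 0)
    for i in bad_diag[:10]:
        problems.append(f"nonzero diagonal at ({i},{i})")
    asym = np.argwhere(W != W.T)
    for i, j in asym[:10]:
        if i < j:
            problems.append(f"asymmetry at ({i},{j}): {W[i, j]} vs {W[j, i]}")
    nonbin = np.argwhere((W != 0) & (W != 1))
    for i, j in nonbin[:10]:
        problems.append(f"non-binary entry {W[i, j]} at ({i},{j})")
    if A.neighbors:
        for i, nb in enumerate(A.neighbors):
            if sorted(nb) != list(np.flatnonzero(W[i])):
                problems.append(f"neighbour list of zone {i} inconsistent with weights")
    if problems:
        raise AdjacencyValidationError("; ".join(problems))
    g = nx.from_numpy_array(W)
    row_sums = W.sum(axis=1)
    return {
        "n_zones": len(A.zone_ids),
        "row_sums": row_sums,
        "n_edges": int(row_sums.sum()) // 2,
        "islands": [A.zone_ids[i] for i in np.flatnonzero(row_sums == 0)],
        "n_components": nx.number_connected_components(g),
    }


def write_neighbor_list(A: AdjacencyMatrix, path) -> None:
    """Plain-text neighbour list: one line per zone: id, m_i, neighbour ids."""
    with open(path, "w") as fh:
        for i, zid in enumerate(A.zone_ids):
            nb = [A.zone_ids[j] for j in A.neighbors[i]]
            fh.write(f"{zid}\t{len(nb)}\t{' '.join(nb)}\n")


def write_weights_csv(A: AdjacencyMatrix, path) -> None:
    """Dense CSV weight matrix with zone ids as header and index."""
    import pandas as pd

    pd.DataFrame(A.weights, index=A.zone_ids, columns=A.zone_ids).to_csv(path)


def read_weights_csv(path) -> AdjacencyMatrix:
    """Read back a dense CSV weight matrix written by :func:`write_weights_csv`."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    zones = [ZoneGeometry(str(z), shape({"type": "Point", "coordinates": [0, 0]}))
             for z in df.index]
    W = df.to_numpy(dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = _finalize(zones, W)
    return A
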