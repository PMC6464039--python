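"""Contiguity-based neighborhood dictionaries for spatial smoothing.

Two regions are neighbors under *queen* contiguity if their boundaries share
any point (corner contact counts), and under *rook* contiguity only if they
share a boundary segment of positive length.  The resulting symmetric,
irreflexive mapping is what the spatial smoother pools over: each region is
shrunk toward the crude rate of its combined neighbors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from shapely import STRtree
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

from .ingest import ValidationError

__all__ = [
    "NeighborhoodDictionary",
    "build_adjacency",
    "save_dictionary",
    "load_dictionary",
    "read_geojson",
    "grid_geometries",
]

#: boundaries closer than this (layer coordinate units) count as touching —
#: absorbs coordinate rounding in exported polygon layers
GEOMETRIC_TOLERANCE = 1e-9


@dataclass(frozen=True)
class NeighborhoodDictionary:
    """Symmetric, irreflexive region adjacency; isolated regions map to ()."""

    neighbors: Mapping[str, tuple[str, ...]]
    rule: str = "queen"

    def __post_init__(self) -> None:
        if self.rule not in ("queen", "rook"):
            raise ValidationError(f"unknown contiguity rule {self.rule!r}")
        clean: dict[str, tuple[str, ...]] = {}
        for rid, nbrs in self.neighbors.items():
            clean[str(rid)] = tuple(sorted(str(x) for x in nbrs))
        for rid, nbrs in clean.items():
            if rid in nbrs:
                raise ValidationError(f"self-loop {rid}")
            for other in nbrs:
                if other not in clean:
                    raise ValidationError(f"neighbor {other!r} of {rid!r} is not a region key")
                if rid not in clean[other]:
                    raise ValidationError(f"asymmetric pair ({rid},{other})")
        object.__setattr__(self, "neighbors", clean)

    def __getitem__(self, region_id: str) -> tuple[str, ...]:
        return self.neighbors[str(region_id)]

    def __contains__(self, region_id: str) -> bool:
        return str(region_id) in self.neighbors

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.neighbors))

    def degree(self, region_id: str) -> int:
        return len(self[region_id])


def build_adjacency(
    geometries: Mapping[str, BaseGeometry],
    rule: str = "queen",
    tolerance: float = GEOMETRIC_TOLERANCE,
) -> NeighborhoodDictionary:
    """Derive the neighborhood dictionary from region polygons.

    Parameters
    ----------
    geometries
        Polygon or MultiPolygon per region id.  Ids must be unique and the
        mapping non-empty.
    rule
        ``"queen"`` (any boundary contact, the default) or ``"rook"``
        (shared edge of positive length).
    tolerance
        Boundaries within this distance are treated as touching.
    """
    if rule not in ("queen", "rook"):
        raise ValidationError(f"unknown contiguity rule {rule!r}")
    ids = [str(k) for k in geometries]
    if not ids:
        raise ValidationError("empty geometry set")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate region ids in geometry set")

    geoms = list(geometries.values())
    for rid, g in zip(ids, geoms):
        if g is None or g.is_empty:
            raise ValidationError(f"region {rid}: empty geometry")

    tree = STRtree(geoms)
    nbrs: dict[str, set[str]] = {rid: set() for rid in ids}
    for i, g in enumerate(geoms):
        # candidate pruning only; exact predicate decides
        for k in tree.query(g.buffer(tolerance) if tolerance > 0 else g):
            k = int(k)
            if k <= i:
                continue
            other = geoms[k]
            if g.distance(other) > tolerance:
                continue
            if rule == "rook":
                # shared-edge test: the polygon intersection of two touching
                # regions is their common boundary; require positive length
                if g.intersection(other).length <= tolerance:
                    continue
            nbrs[ids[i]].add(ids[k])
            nbrs[ids[k]].add(ids[i])
    return NeighborhoodDictionary(neighbors={k: tuple(sorted(v)) for k, v in nbrs.items()}, rule=rule)


def save_dictionary(nd: NeighborhoodDictionary, path: str | Path) -> None:
    """Persist as diff-stable JSON ``{region_id: [sorted ids], "_rule": ...}``."""
    payload: dict[str, object] = {rid: list(nd.neighbors[rid]) for rid in sorted(nd.neighbors)}
    payload["_rule"] = nd.rule
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_dictionary(path: str | Path) -> NeighborhoodDictionary:
    """Load and re-validate a saved neighborhood dictionary."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed adjacency file {path}: {exc}") from None
    if not isinstance(payload, dict):
        raise ValidationError(f"malformed adjacency file {path}: expected a JSON object")
    rule = payload.pop("_rule", "queen")
    neighbors = {str(k): tuple(str(x) for x in v) for k, v in payload.items()}
    return NeighborhoodDictionary(neighbors=neighbors, rule=str(rule))


def read_geojson(path: str | Path, id_field: str = "GEOID") -> dict[str, BaseGeometry]:
    """Read region polygons from a GeoJSON FeatureCollection.

    The region id is taken from ``properties[id_field]`` (falling back to the
    feature-level ``id`` member when the property is absent).
    """
    data = json.loads(Path(path).read_text())
    features = data.get("features")
    if features is None:
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    out: dict[str, BaseGeometry] = {}
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        rid = props.get(id_field, feat.get("id"))
        if rid is None:
            raise ValidationError(f"{path}: feature {k} has no {id_field!r} property or id")
        rid = str(rid)
        if rid in out:
            raise ValidationError(f"{path}: duplicate region id {rid!r}")
        out[rid] = _shapely_shape(feat["geometry"])
    if not out:
        raise ValidationError(f"{path}: no features")
    return out


def grid_geometries(rows: int, cols: int) -> dict[str, BaseGeometry]:
    """Unit-square lattice of ``rows × cols`` regions, ids ``r{r:02d}c{c:02d}``.

    Shared as the geometry backbone of the simulation study and the test
    fixture generator.
    """
    from shapely.geometry import box

    if rows < 1 or cols < 1:
        raise ValidationError(f"degenerate grid {rows}x{cols}")
    return {
        f"r{r:02d}c{c:02d}": box(c, rows - 1 - r, c + 1, rows - r)
        for r in range(rows)
        for c in range(cols)
    }
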