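"""Georeferencing: private-coordinate promotion, reversible patches, and
the project-area polygon filter.

Coordinate corrections are never written into source catalogues. They are
held in a :class:`GeoPatchTable` — one row per record, with a mandatory
justification note — that is applied after private/obscured coordinates
have been promoted into the principal Darwin Core fields. The patch is a
true lens: :func:`invert_geo_patches` restores the pre-patch catalogue
exactly, and re-applying the same patch table is a no-op.

The project-area membership test is planar on raw WGS84 decimal degrees
(no projection): at the scale of a single island the distortion is
negligible and the test stays deterministic and easily audited. Boundary
points count as inside — excluding shoreline records from a coastal
biodiversity survey would discard exactly the habitat of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from shapely.geometry import Point, Polygon, shape
from shapely.prepared import prep

from .datamodel import (
    Catalogue,
    CurationError,
    OccurrenceRecord,
    _read_dict_csv,
    _write_dict_csv,
)

__all__ = [
    "GeoError",
    "GeoPatch",
    "GeoPatchTable",
    "GeoPatchLogEntry",
    "ProjectArea",
    "promote_private_coordinates",
    "apply_geo_patches",
    "invert_geo_patches",
    "point_in_area",
    "filter_by_area",
]

PATCH_STAGE = "geo_patch"
PROMOTE_STAGE = "private_promotion"


class GeoError(CurationError):
    """A georeferencing table, polygon or operation is invalid."""


@dataclass(frozen=True)
class GeoPatch:
    """One reversible coordinate correction with its justification."""

    datasetID: str
    occurrenceID: str
    newLatitude: float
    newLongitude: float
    note: str


PATCH_COLUMNS = ["datasetID", "occurrenceID", "newLatitude", "newLongitude", "note"]


class GeoPatchTable:
    """Record-keyed coordinate corrections; one row per record, notes
    mandatory, coordinates range-checked at load."""

    def __init__(self, patches: Iterable[GeoPatch] = ()):
        self.patches: list[GeoPatch] = list(patches)
        seen: set[tuple[str, str]] = set()
        for p in self.patches:
            key = (p.datasetID, p.occurrenceID)
            if key in seen:
                raise GeoError(f"duplicate patch for record {key}")
            seen.add(key)
            if not -90.0 <= p.newLatitude <= 90.0:
                raise GeoError(f"patch {key}: latitude {p.newLatitude} out of range")
            if not -180.0 <= p.newLongitude <= 180.0:
                raise GeoError(f"patch {key}: longitude {p.newLongitude} out of range")
            if not p.note.strip():
                raise GeoError(f"patch {key}: justification note is mandatory")

    def __len__(self) -> int:
        return len(self.patches)

    def to_csv(self, path_or_buf) -> None:
        _write_dict_csv(
            path_or_buf,
            PATCH_COLUMNS,
            (
                {
                    "datasetID": p.datasetID,
                    "occurrenceID": p.occurrenceID,
                    "newLatitude": repr(p.newLatitude),
                    "newLongitude": repr(p.newLongitude),
                    "note": p.note,
                }
                for p in self.patches
            ),
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "GeoPatchTable":
        rows = _read_dict_csv(path_or_buf)
        return cls(
            GeoPatch(
                datasetID=row["datasetID"],
                occurrenceID=row["occurrenceID"],
                newLatitude=float(row["newLatitude"]),
                newLongitude=float(row["newLongitude"]),
                note=row.get("note", ""),
            )
            for row in rows
        )


@dataclass(frozen=True)
class GeoPatchLogEntry:
    """Before/after coordinates for one patched record, with the note."""

    datasetID: str
    occurrenceID: str
    oldLatitude: Optional[float]
    oldLongitude: Optional[float]
    newLatitude: float
    newLongitude: float
    note: str


# --------------------------------------------------------------------------
# Step 5 — private-coordinate promotion
# --------------------------------------------------------------------------


def promote_private_coordinates(record: OccurrenceRecord) -> OccurrenceRecord:
    """Copy obscured/private coordinates into the principal fields.

    Crowd-sourcing platforms obscure the coordinates of sensitive
    observations in the public export while supplying the true position
    in project-specific private fields; those private values, when
    present, overwrite ``decimalLatitude``/``decimalLongitude`` and the
    change is logged. Records without private fields pass through
    unchanged (the same object, untouched).
    """
    if record.privateLatitude is None and record.privateLongitude is None:
        return record
    if record.privateLatitude is None or record.privateLongitude is None:
        raise GeoError(
            f"record {record.occurrenceID}: private coordinates must be a pair"
        )
    if not -90.0 <= record.privateLatitude <= 90.0 or not (
        -180.0 <= record.privateLongitude <= 180.0
    ):
        raise GeoError(
            f"record {record.occurrenceID}: private coordinates "
            f"({record.privateLatitude}, {record.privateLongitude}) out of range"
        )
    new = record.copy()
    new.log_change(
        PROMOTE_STAGE,
        "decimalLatitude/decimalLongitude",
        f"{new.decimalLatitude},{new.decimalLongitude}",
        f"{new.privateLatitude},{new.privateLongitude}",
        "private coordinates promoted to principal fields",
    )
    new.decimalLatitude = new.privateLatitude
    new.decimalLongitude = new.privateLongitude
    return new


# --------------------------------------------------------------------------
# Step 6 — reversible coordinate patches
# --------------------------------------------------------------------------


def apply_geo_patches(
    master: Catalogue, patches: GeoPatchTable
) -> tuple[Catalogue, list[GeoPatchLogEntry]]:
    """Apply the georeferencing patch lens to the master catalogue.

    Every patch row must target an existing record — an orphan patch
    signals upstream drift (a source renumbered or dropped records) and
    fails loudly, listing the orphans. Idempotent: a record already at
    the patched coordinates is left untouched and unlogged.
    """
    index = {(r.datasetID, r.occurrenceID) for r in master}
    orphans = [
        (p.datasetID, p.occurrenceID)
        for p in patches.patches
        if (p.datasetID, p.occurrenceID) not in index
    ]
    if orphans:
        raise GeoError(f"patches target records absent from the catalogue: {orphans}")

    by_target = {(p.datasetID, p.occurrenceID): p for p in patches.patches}
    out: list[OccurrenceRecord] = []
    log: list[GeoPatchLogEntry] = []
    for rec in master:
        patch = by_target.get((rec.datasetID, rec.occurrenceID))
        if patch is None or (
            rec.decimalLatitude == patch.newLatitude
            and rec.decimalLongitude == patch.newLongitude
        ):
            out.append(rec.copy())
            continue
        new = rec.copy()
        log.append(
            GeoPatchLogEntry(
                datasetID=rec.datasetID,
                occurrenceID=rec.occurrenceID,
                oldLatitude=rec.decimalLatitude,
                oldLongitude=rec.decimalLongitude,
                newLatitude=patch.newLatitude,
                newLongitude=patch.newLongitude,
                note=patch.note,
            )
        )
        new.log_change(
            PATCH_STAGE,
            "decimalLatitude/decimalLongitude",
            f"{rec.decimalLatitude},{rec.decimalLongitude}",
            f"{patch.newLatitude},{patch.newLongitude}",
            patch.note,
        )
        new.decimalLatitude = patch.newLatitude
        new.decimalLongitude = patch.newLongitude
        out.append(new)
    return Catalogue(out), log


def invert_geo_patches(
    patched: Catalogue, log: list[GeoPatchLogEntry]
) -> Catalogue:
    """Undo a patch application exactly: ``invert ∘ apply = identity``.

    Restores each logged record's pre-patch coordinates and removes the
    patch-stage provenance entries the application added, so the result
    is byte-for-byte the pre-patch catalogue. Fails if the log does not
    match the catalogue (wrong catalogue, or coordinates changed since).
    """
    by_target = {(e.datasetID, e.occurrenceID): e for e in log}
    out: list[OccurrenceRecord] = []
    for rec in patched:
        entry = by_target.pop((rec.datasetID, rec.occurrenceID), None)
        if entry is None:
            out.append(rec.copy())
            continue
        if (
            rec.decimalLatitude != entry.newLatitude
            or rec.decimalLongitude != entry.newLongitude
        ):
            raise GeoError(
                f"record {rec.occurrenceID}: coordinates "
                f"({rec.decimalLatitude}, {rec.decimalLongitude}) do not match "
                f"the patch log; cannot invert"
            )
        new = rec.copy()
        new.decimalLatitude = entry.oldLatitude
        new.decimalLongitude = entry.oldLongitude
        # drop the provenance entry added by apply_geo_patches so the
        # round trip is exact
        for i in range(len(new.modificationLog) - 1, -1, -1):
            if new.modificationLog[i].stage == PATCH_STAGE:
                del new.modificationLog[i]
                break
        out.append(new)
    if by_target:
        raise GeoError(
            f"patch log entries target records absent from the catalogue: "
            f"{sorted(by_target)}"
        )
    return Catalogue(out)


# --------------------------------------------------------------------------
# Step 7 — project-area polygon filter
# --------------------------------------------------------------------------


class ProjectArea:
    """One or more WGS84 polygons delimiting the project area.

    Membership is planar (longitude, latitude treated as x, y) and
    boundary-inclusive. Rings with fewer than three distinct vertices are
    rejected at load.
    """

    def __init__(self, polygons: Iterable[Polygon], name: str = "project area"):
        self.polygons: list[Polygon] = list(polygons)
        self.name = name
        if not self.polygons:
            raise GeoError("project area has no polygons")
        for poly in self.polygons:
            ring = list(poly.exterior.coords)
            # shapely closes rings; distinct vertices exclude the closure
            if len(set(ring[:-1])) < 3:
                raise GeoError(
                    f"area {name!r}: degenerate ring with fewer than 3 distinct vertices"
                )
        self._prepared = [prep(p) for p in self.polygons]

    @classmethod
    def from_rings(
        cls, rings: Iterable[Iterable[tuple[float, float]]], name: str = "project area"
    ) -> "ProjectArea":
        """Build from ordered (longitude, latitude) vertex lists."""
        polys = []
        for ring in rings:
            pts = list(ring)
            if len(set(pts if pts[0] != pts[-1] else pts[:-1])) < 3:
                raise GeoError(
                    f"area {name!r}: degenerate ring with fewer than 3 distinct vertices"
                )
            polys.append(Polygon(pts))
        return cls(polys, name)

    @classmethod
    def from_geojson(cls, path_or_obj, name: str = "") -> "ProjectArea":
        """Load a GeoJSON Polygon, MultiPolygon, Feature or FeatureCollection."""
        if isinstance(path_or_obj, dict):
            obj = path_or_obj
        else:
            with open(path_or_obj, encoding="utf-8") as fh:
                obj = json.load(fh)
        geoms = []
        label = name
        if obj.get("type") == "FeatureCollection":
            features = obj["features"]
        elif obj.get("type") == "Feature":
            features = [obj]
        else:
            features = [{"geometry": obj, "properties": {}}]
        for feat in features:
            geom = shape(feat["geometry"])
            label = label or (feat.get("properties") or {}).get("name", "")
            if geom.geom_type == "Polygon":
                geoms.append(geom)
            elif geom.geom_type == "MultiPolygon":
                geoms.extend(geom.geoms)
            else:
                raise GeoError(f"unsupported geometry type {geom.geom_type!r}")
        return cls(geoms, label or "project area")

    def to_geojson(self, path) -> None:
        obj = {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": {
                "type": "MultiPolygon",
                "coordinates": [
                    [list(map(list, p.exterior.coords))] for p in self.polygons
                ],
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)

    def contains(self, lat: float, lon: float) -> bool:
        point = Point(lon, lat)
        # prepared geometries accelerate the common interior case; fall
        # back to covers() for boundary inclusiveness
        for prepared, poly in zip(self._prepared, self.polygons):
            if prepared.contains(point) or poly.covers(point):
                return True
        return False

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min lon, min lat, max lon, max lat) over all polygons."""
        bs = [p.bounds for p in self.polygons]
        return (
            min(b[0] for b in bs),
            min(b[1] for b in bs),
            max(b[2] for b in bs),
            max(b[3] for b in bs),
        )


def point_in_area(lat: float, lon: float, area: ProjectArea) -> bool:
    """Planar membership test: inside any area polygon, boundary included."""
    if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
        raise GeoError(f"coordinates ({lat}, {lon}) out of range")
    return area.contains(lat, lon)


def filter_by_area(
    master: Catalogue, area: ProjectArea
) -> tuple[Catalogue, Catalogue, Catalogue]:
    """Three-way partition: (inside, outside, noCoordinates).

    Records lacking coordinates are routed to a review bucket rather than
    silently dropped — historical specimens with poor spatial resolution
    still contribute taxa and deserve curator attention. The three parts
    always sum to the input.
    """
    inside: list[OccurrenceRecord] = []
    outside: list[OccurrenceRecord] = []
    nocoords: list[OccurrenceRecord] = []
    for rec in master:
        if rec.decimalLatitude is None or rec.decimalLongitude is None:
            nocoords.append(rec.copy())
        elif point_in_area(rec.decimalLatitude, rec.decimalLongitude, area):
            inside.append(rec.copy())
        else:
            out = rec.copy()
            out.log_change(
                "area_filter",
                "excluded",
                "",
                "outside project area",
                f"point outside {area.name}",
            )
            outside.append(out)
    return Catalogue(inside), Catalogue(outside), Catalogue(nocoords)
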