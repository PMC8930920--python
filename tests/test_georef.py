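"""Coordinate promotion, reversible patches, and the polygon filter."""

import numpy as np
import pytest

from dwclens import (
    Catalogue,
    GeoError,
    GeoPatch,
    GeoPatchTable,
    ProjectArea,
    apply_geo_patches,
    filter_by_area,
    invert_geo_patches,
    point_in_area,
    promote_private_coordinates,
)
from conftest import make_record

UNIT_SQUARE = ProjectArea.from_rings([[(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]])


# -- private coordinate promotion -----------------------------------------


def test_promotion_overwrites_public_coordinates():
    rec = make_record("r1", lat=48.90, lon=-123.40)
    rec.privateLatitude, rec.privateLongitude = 48.9236, -123.4415
    out = promote_private_coordinates(rec)
    assert (out.decimalLatitude, out.decimalLongitude) == (48.9236, -123.4415)
    assert out.modificationLog[-1].stage == "private_promotion"
    # original untouched
    assert rec.decimalLatitude == 48.90


def test_promotion_identity_without_private_fields():
    rec = make_record("r1", lat=48.90, lon=-123.40)
    assert promote_private_coordinates(rec) is rec


def test_promotion_rejects_out_of_range():
    rec = make_record("r9", lat=0.0, lon=0.0)
    rec.privateLatitude, rec.privateLongitude = 95.0, 10.0
    with pytest.raises(GeoError, match="r9"):
        promote_private_coordinates(rec)


# -- patches ----------------------------------------------------------------


def test_patch_apply_and_log():
    master = Catalogue([make_record("r1", lat=49.00, lon=-123.00)])
    patches = GeoPatchTable(
        [GeoPatch("ds1", "r1", 48.92, -123.44, "historical locality refined")]
    )
    patched, log = apply_geo_patches(master, patches)
    rec = patched.records[0]
    assert (rec.decimalLatitude, rec.decimalLongitude) == (48.92, -123.44)
    assert rec.modificationLog[-1].justification == "historical locality refined"
    assert "49.0" in rec.modificationLog[-1].old_value
    assert log[0].oldLatitude == 49.00


def test_empty_patch_table_is_identity(coord_catalogue):
    patched, log = apply_geo_patches(coord_catalogue, GeoPatchTable())
    assert patched.to_csv_string() == coord_catalogue.to_csv_string()
    assert log == []


def test_patch_orphan_fails():
    master = Catalogue([make_record("r1", lat=0.0, lon=0.0)])
    patches = GeoPatchTable([GeoPatch("ds1", "ghost", 1.0, 1.0, "n")])
    with pytest.raises(GeoError, match="ghost"):
        apply_geo_patches(master, patches)


def test_patch_table_invariants():
    with pytest.raises(GeoError, match="duplicate"):
        GeoPatchTable([GeoPatch("d", "r", 0, 0, "x"), GeoPatch("d", "r", 1, 1, "y")])
    with pytest.raises(GeoError, match="latitude"):
        GeoPatchTable([GeoPatch("d", "r", 95.0, 0, "x")])
    with pytest.raises(GeoError, match="note"):
        GeoPatchTable([GeoPatch("d", "r", 0, 0, "  ")])


def test_patch_idempotence(coord_catalogue):
    rng = np.random.default_rng(3)
    targets = [coord_catalogue.records[i] for i in rng.choice(500, 50, replace=False)]
    patches = GeoPatchTable(
        [GeoPatch(r.datasetID, r.occurrenceID,
                  float(rng.uniform(-89, 89)), float(rng.uniform(-179, 179)),
                  "review") for r in targets]
    )
    once, log1 = apply_geo_patches(coord_catalogue, patches)
    twice, log2 = apply_geo_patches(once, patches)
    assert twice.to_csv_string() == once.to_csv_string()
    assert len(log1) == 50 and len(log2) == 0


@pytest.mark.parametrize("seed", range(20))
def test_patch_reversibility_random(coord_catalogue, seed):
    """invert ∘ apply = identity: 100 random patches, byte-identical result."""
    rng = np.random.default_rng(seed)
    targets = [coord_catalogue.records[i] for i in rng.choice(500, 100, replace=False)]
    patches = GeoPatchTable(
        [GeoPatch(r.datasetID, r.occurrenceID,
                  float(rng.uniform(-89, 89)), float(rng.uniform(-179, 179)),
                  "random audit") for r in targets]
    )
    patched, log = apply_geo_patches(coord_catalogue, patches)
    restored = invert_geo_patches(patched, log)
    assert restored.to_csv_string() == coord_catalogue.to_csv_string()
    assert [r.modificationLog for r in restored] == [
        r.modificationLog for r in coord_catalogue
    ]


def test_invert_empty_log_is_identity(coord_catalogue):
    restored = invert_geo_patches(coord_catalogue, [])
    assert restored.to_csv_string() == coord_catalogue.to_csv_string()


def test_invert_mismatched_log_fails(coord_catalogue):
    patches = GeoPatchTable([GeoPatch("ds1", "r0", 10.0, 10.0, "move")])
    _, log = apply_geo_patches(coord_catalogue, patches)
    with pytest.raises(GeoError, match="cannot invert"):
        invert_geo_patches(coord_catalogue, log)  # pre-patch catalogue


# -- polygon membership -----------------------------------------------------


@pytest.mark.parametrize(
    "lat, lon, inside",
    [
        (0.5, 0.5, True),
        (2.0, 2.0, False),
        (0.0, 0.5, True),   # boundary counts as inside
        (1.0, 1.0, True),   # vertex counts as inside
        (-0.001, 0.5, False),
    ],
)
def test_point_in_unit_square(lat, lon, inside):
    assert point_in_area(lat, lon, UNIT_SQUARE) is inside


def test_point_rejects_invalid_coordinates():
    with pytest.raises(GeoError):
        point_in_area(95.0, 0.0, UNIT_SQUARE)


def test_degenerate_ring_rejected():
    with pytest.raises(GeoError, match="degenerate"):
        ProjectArea.from_rings([[(0, 0), (1, 1), (0, 0)]])


def _winding_number(lat, lon, ring):
    """Independent winding-number membership oracle (non-boundary points)."""
    wn = 0
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if y1 <= lat:
            if y2 > lat and _is_left(x1, y1, x2, y2, lon, lat) > 0:
                wn += 1
        elif y2 <= lat and _is_left(x1, y1, x2, y2, lon, lat) < 0:
            wn -= 1
    return wn != 0


def _is_left(x1, y1, x2, y2, px, py):
    return (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)


def _random_simple_polygon(rng, n_vertices=12):
    """Star-shaped (hence simple) polygon: vertices sorted by angle."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.5, 1.5, n_vertices)
    return [(float(r * np.cos(a)), float(r * np.sin(a))) for a, r in zip(angles, radii)]


def test_point_in_area_matches_winding_oracle():
    rng = np.random.default_rng(11)
    total = 0
    while total < 10_000:
        ring = _random_simple_polygon(rng)
        area = ProjectArea.from_rings([ring + ring[:1]])
        pts = rng.uniform(-2, 2, size=(500, 2))
        for lon, lat in pts:
            # skip near-boundary points: the oracle comparison is defined
            # away from the edge
            if min(
                abs(_is_left(x1, y1, x2, y2, lon, lat))
                for (x1, y1), (x2, y2) in zip(ring, ring[1:] + ring[:1])
            ) < 1e-9:
                continue
            assert point_in_area(float(lat), float(lon), area) == _winding_number(
                lat, lon, ring
            )
            total += 1


# -- area filter ------------------------------------------------------------


def test_filter_by_area_three_way_partition():
    records = (
        [make_record(f"in{i}", lat=0.2 + 0.03 * i, lon=0.5) for i in range(15)]
        + [make_record(f"out{i}", lat=5.0, lon=5.0 + i) for i in range(3)]
        + [make_record(f"nc{i}") for i in range(2)]
    )
    inside, outside, nocoords = filter_by_area(Catalogue(records), UNIT_SQUARE)
    assert (len(inside), len(outside), len(nocoords)) == (15, 3, 2)
    assert len(inside) + len(outside) + len(nocoords) == len(records)


def test_filter_by_area_all_inside_and_empty():
    all_in = Catalogue([make_record("a", lat=0.5, lon=0.5)])
    inside, outside, nocoords = filter_by_area(all_in, UNIT_SQUARE)
    assert (len(inside), len(outside), len(nocoords)) == (1, 0, 0)
    inside, outside, nocoords = filter_by_area(Catalogue(), UNIT_SQUARE)
    assert (len(inside), len(outside), len(nocoords)) == (0, 0, 0)


def test_geojson_roundtrip(tmp_path, default_bundle):
    path = tmp_path / "area.geojson"
    default_bundle.area.to_geojson(path)
    again = ProjectArea.from_geojson(path)
    assert again.bounds == default_bundle.area.bounds
    assert point_in_area(48.9236, -123.4415, again)
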