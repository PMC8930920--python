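"""Synthetic multi-source occurrence data with recorded ground truth.

Real multi-source curation projects cannot ship their raw inputs, so this
module manufactures them: five source catalogues (dive surveys, museum
vouchers, crowd-sourced observations, an ecological survey and a small
literature dataset) with a controlled taxon-overlap structure, injected
single-character name typos exactly matched by a known taxon-resolution
table, injected coordinate errors exactly matched by a known
georeferencing patch table, obscured coordinates held in private fields,
out-of-area records, records without coordinates — and, crucially, the
ground truth for every downstream statistic, computed by direct
enumeration at generation time.

The default configuration mirrors the structure of a community-integrated
island survey at one-tenth scale: per-category exclusive-taxon targets
(24, 8, 7, 1, 1) with 26 taxa shared between categories (every shared
taxon involving the dive surveys, which dominate sampling effort), and
per-category record counts (1615, 27, 275, 84, 1) totalling 2002.

Taxon names are drawn from a Latin-like CV-syllable grammar, so no real
nomenclature is shipped; the classification hangs off a small set of real
phylum labels to keep per-phylum sheet splitting realistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .contribution import (
    ContributionStats,
    PAPER_GROUPING,
    SourceTally,
    novelty_percentages,
    records_per_novel_ratio,
)
from .datamodel import BackboneEntry, CurationError, TaxonomicBackbone
from .georef import GeoPatch, GeoPatchTable, ProjectArea
from .ingest import ColumnMapping, SourceCatalogue, map_columns
from .taxonomy import ResolutionRule, TaxonResolutionTable

__all__ = [
    "FixtureConfig",
    "GroundTruth",
    "FixtureBundle",
    "generate_fixture",
    "oracle_stats",
    "DEFAULT_AREA_RINGS",
]


class FixtureError(CurationError):
    """The fixture configuration is infeasible."""


#: Hexagonal project area around a small island (planar degrees).
DEFAULT_AREA_RINGS = [
    [
        (-123.5415, 48.9236),
        (-123.4915, 49.0102),
        (-123.3915, 49.0102),
        (-123.3415, 48.9236),
        (-123.3915, 48.8370),
        (-123.4915, 48.8370),
        (-123.5415, 48.9236),
    ]
]

_PHYLA = [
    "Porifera",
    "Cnidaria",
    "Mollusca",
    "Annelida",
    "Arthropoda",
    "Echinodermata",
    "Bryozoa",
    "Chordata",
]

_CONSONANTS = list("bcdglmnprstv")
_VOWELS = list("aeiou")

_DATASET_OF_CATEGORY = {
    "pmls": "dive-surveys",
    "collection": "museum-vouchers",
    "crowd": "crowd-observations",
    "ecological": "rov-survey",
    "literature": "literature-records",
}

# heterogeneous per-source column vocabularies, to exercise the crosswalk
_SOURCE_SCHEMAS = {
    "pmls": {
        "Species": "reportedName",
        "Lat": "decimalLatitude",
        "Long": "decimalLongitude",
        "Date": "eventDate",
        "Observer": "recordedBy",
    },
    "collection": {
        "scientificName": "reportedName",
        "decimalLatitude": "decimalLatitude",
        "decimalLongitude": "decimalLongitude",
        "eventDate": "eventDate",
        "catalogNumber": "occurrenceID",
        "recordedBy": "recordedBy",
    },
    "crowd": {
        "taxon_name": "reportedName",
        "latitude": "decimalLatitude",
        "longitude": "decimalLongitude",
        "observed_on": "eventDate",
        "user_login": "recordedBy",
        "id": "occurrenceID",
    },
    "ecological": {
        "taxon": "reportedName",
        "lat_dd": "decimalLatitude",
        "lon_dd": "decimalLongitude",
        "survey_date": "eventDate",
    },
    "literature": {
        "name": "reportedName",
        "lat": "decimalLatitude",
        "lon": "decimalLongitude",
        "year": "eventDate",
        "reference": "recordedBy",
    },
}

_PRIVATE_COLUMNS = {"crowd": ("private_latitude", "private_longitude")}


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic multi-source survey.

    ``exclusiveTargets`` and ``sharedCount`` fix the overlap structure
    exactly (the generator fails rather than fudge an infeasible target);
    ``sharedExtraMemberships`` says how many shared taxa each non-anchor
    category joins, every shared taxon always involving ``sharedAnchor``.
    Rates are per-record probabilities of the corresponding injected
    artefact. A fixed seed yields byte-identical catalogues.
    """

    seed: int = 0
    exclusiveTargets: dict[str, int] = field(
        default_factory=lambda: {
            "pmls": 24,
            "collection": 8,
            "crowd": 7,
            "ecological": 1,
            "literature": 1,
        }
    )
    sharedCount: int = 26
    sharedAnchor: str = "pmls"
    sharedExtraMemberships: dict[str, int] = field(
        default_factory=lambda: {"collection": 10, "crowd": 24, "ecological": 2}
    )
    recordsPerSource: dict[str, int] = field(
        default_factory=lambda: {
            "pmls": 1615,
            "collection": 27,
            "crowd": 275,
            "ecological": 84,
            "literature": 1,
        }
    )
    typoRate: float = 0.05
    coordErrorRate: float = 0.02
    outOfAreaRate: float = 0.03
    missingCoordRate: float = 0.04
    privateCoordRate: float = 0.10  # applies to crowd-sourced records
    qualifierRate: float = 0.06  # cf. / sp. / complex names in the taxon pool
    synonymRate: float = 0.10  # backbone entries carrying a synonym
    nonMarineTaxa: int = 3  # backbone-only out-of-scope entries
    areaRings: list = field(default_factory=lambda: [list(r) for r in DEFAULT_AREA_RINGS])

    def validate(self) -> None:
        for name, rate in (
            ("typoRate", self.typoRate),
            ("coordErrorRate", self.coordErrorRate),
            ("outOfAreaRate", self.outOfAreaRate),
            ("missingCoordRate", self.missingCoordRate),
            ("privateCoordRate", self.privateCoordRate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise FixtureError(f"{name} must be a probability, got {rate}")
        if self.sharedAnchor not in self.exclusiveTargets:
            raise FixtureError(
                f"shared anchor {self.sharedAnchor!r} is not a source category"
            )
        extras = dict(self.sharedExtraMemberships)
        if any(cat not in self.exclusiveTargets for cat in extras):
            raise FixtureError("sharedExtraMemberships names an unknown category")
        if self.sharedCount > 0:
            if sum(extras.values()) < self.sharedCount:
                raise FixtureError(
                    "infeasible overlap targets: every shared taxon needs at "
                    "least one category besides the anchor "
                    f"({sum(extras.values())} extra memberships < "
                    f"{self.sharedCount} shared taxa)"
                )
            if any(n > self.sharedCount for n in extras.values()):
                raise FixtureError(
                    "infeasible overlap targets: a category cannot join more "
                    "shared taxa than exist"
                )
        taxa_per_cat = self._taxa_per_category()
        for cat, n_records in self.recordsPerSource.items():
            if n_records < taxa_per_cat.get(cat, 0):
                raise FixtureError(
                    f"category {cat!r}: {n_records} records cannot cover "
                    f"{taxa_per_cat[cat]} taxa (every taxon needs a record)"
                )

    def _taxa_per_category(self) -> dict[str, int]:
        out = dict(self.exclusiveTargets)
        out[self.sharedAnchor] += self.sharedCount
        for cat, n in self.sharedExtraMemberships.items():
            out[cat] = out.get(cat, 0) + n
        return out

    @property
    def nTaxa(self) -> int:
        return sum(self.exclusiveTargets.values()) + self.sharedCount


@dataclass
class GroundTruth:
    """Everything a perfect pipeline run must recover."""

    taxa: list[dict]  # name, authority, rank, classification, categories
    trueResolutionTable: TaxonResolutionTable
    truePatchTable: GeoPatchTable
    expectedStats: ContributionStats
    expectedPartition: tuple[int, int, int]  # (inside, outside, noCoordinates)
    expectedTaxonNames: list[str]
    categoryTaxa: dict[str, list[str]]

    def to_json(self, path) -> None:
        obj = {
            "taxa": self.taxa,
            "expectedPartition": list(self.expectedPartition),
            "expectedTaxonNames": self.expectedTaxonNames,
            "categoryTaxa": self.categoryTaxa,
            "expectedStats": {
                "perSource": {
                    c: vars(t) for c, t in sorted(self.expectedStats.perSource.items())
                },
                "sharedCount": self.expectedStats.sharedCount,
                "totalTaxa": self.expectedStats.totalTaxa,
                "totalRecords": self.expectedStats.totalRecords,
                "groupedPercentages": self.expectedStats.groupedPercentages,
                "ratios": self.expectedStats.ratios,
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class FixtureBundle:
    """A generated study: raw tables, crosswalks, mapped sources, the
    reference tables a curator would maintain, and the ground truth."""

    rawTables: dict[str, pd.DataFrame]
    mappings: dict[str, ColumnMapping]
    sources: list[SourceCatalogue]
    backbone: TaxonomicBackbone
    resolutionTable: TaxonResolutionTable
    patchTable: GeoPatchTable
    area: ProjectArea
    truth: GroundTruth


# --------------------------------------------------------------------------
# name grammar
# --------------------------------------------------------------------------


def _syllable(rng: np.random.Generator) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def _latin_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def _genus_name(rng: np.random.Generator) -> str:
    stem = _latin_word(rng, int(rng.integers(2, 4)))
    suffix = rng.choice(["us", "a", "ia", "ella", "on"])
    return (stem + suffix).capitalize()


def _epithet(rng: np.random.Generator) -> str:
    stem = _latin_word(rng, int(rng.integers(2, 4)))
    return stem + rng.choice(["us", "a", "um", "ensis", "i"])


def _surname(rng: np.random.Generator) -> str:
    return _latin_word(rng, int(rng.integers(2, 4))).capitalize()


def _authority(rng: np.random.Generator) -> str:
    text = f"{_surname(rng)}, {int(rng.integers(1758, 2021))}"
    return f"({text})" if rng.random() < 0.5 else text


def _typo(rng: np.random.Generator, name: str) -> str:
    """Single-character edit in the epithet part of a name."""
    chars = list(name)
    # pick a lowercase letter position past the genus to perturb
    positions = [i for i, c in enumerate(chars) if c.islower() and i > name.find(" ")]
    if not positions:
        positions = [len(chars) - 1]
    pos = int(rng.choice(positions))
    old = chars[pos]
    alphabet = [c for c in "abcdefghijklmnopqrstuvwxyz" if c != old]
    chars[pos] = alphabet[int(rng.integers(0, len(alphabet)))]
    return "".join(chars)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_fixture(config: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Manufacture a full synthetic study under ``config``.

    Deterministic under ``config.seed``. The injected typos are exactly
    the domain of the returned resolution table; the injected coordinate
    errors exactly the domain of the patch table; the expected statistics
    are computed here by direct enumeration, independent of the pipeline.
    """
    config = config or FixtureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    categories = list(config.exclusiveTargets)

    area = ProjectArea.from_rings(config.areaRings, name="synthetic project area")

    # ---- taxon pool with classification --------------------------------
    taxa: list[dict] = []
    used_names: set[str] = set()
    hierarchy: dict[str, dict] = {}
    for _ in range(config.nTaxa):
        while True:
            genus = _genus_name(rng)
            qual = ""
            if rng.random() < config.qualifierRate:
                qual = str(rng.choice(["cf. ", "sp.", "complex"]))
            if qual == "sp.":
                name = f"{genus} sp."
            elif qual == "cf. ":
                name = f"{genus} cf. {_epithet(rng)}"
            elif qual == "complex":
                name = f"{genus} {_epithet(rng)} complex"
            else:
                name = f"{genus} {_epithet(rng)}"
            if name not in used_names:
                used_names.add(name)
                break
        phylum = str(rng.choice(_PHYLA))
        levels = hierarchy.setdefault(phylum, {"classes": []})
        if not levels["classes"] or rng.random() < 0.3:
            levels["classes"].append(
                {
                    "class": _latin_word(rng, 3).capitalize() + "ea",
                    "order": _latin_word(rng, 3).capitalize() + "ida",
                    "family": _latin_word(rng, 3).capitalize() + "idae",
                }
            )
        lineage = levels["classes"][int(rng.integers(0, len(levels["classes"])))]
        taxa.append(
            {
                "name": name,
                "authority": _authority(rng),
                "rank": "species",
                "phylum": phylum,
                "class": lineage["class"],
                "order": lineage["order"],
                "family": lineage["family"],
                "genus": genus,
            }
        )

    # ---- overlap structure ---------------------------------------------
    order = list(range(config.nTaxa))
    rng.shuffle(order)
    cursor = 0
    category_taxa: dict[str, list[str]] = {c: [] for c in categories}
    for cat in categories:
        for _ in range(config.exclusiveTargets[cat]):
            category_taxa[cat].append(taxa[order[cursor]]["name"])
            cursor += 1
    shared_names = [taxa[order[cursor + i]]["name"] for i in range(config.sharedCount)]

    # every shared taxon involves the anchor; extra memberships are dealt
    # out so each shared taxon gets at least one extra category
    membership: dict[str, set[str]] = {
        n: {config.sharedAnchor} for n in shared_names
    }
    slots: list[str] = []
    for cat, n in sorted(config.sharedExtraMemberships.items()):
        slots.extend([cat] * n)
    rng.shuffle(slots)
    # first pass: guarantee >= 2 categories per shared taxon
    pending = list(shared_names)
    leftovers: list[str] = []
    for cat in slots:
        placed = False
        for i, name in enumerate(pending):
            if cat not in membership[name]:
                membership[name].add(cat)
                pending.pop(i)
                placed = True
                break
        if not placed:
            leftovers.append(cat)
    if pending:
        raise FixtureError(
            "infeasible overlap targets: could not give every shared taxon a "
            "second category"
        )
    for cat in leftovers:
        candidates = [n for n in shared_names if cat not in membership[n]]
        if not candidates:
            raise FixtureError(
                f"infeasible overlap targets: category {cat!r} cannot join "
                "more shared taxa"
            )
        membership[candidates[int(rng.integers(0, len(candidates)))]].add(cat)
    for name, cats in membership.items():
        for cat in sorted(cats):
            category_taxa[cat].append(name)

    taxon_by_name = {t["name"]: t for t in taxa}

    # ---- backbone -------------------------------------------------------
    entries = []
    for t in taxa:
        synonyms: tuple[str, ...] = ()
        if rng.random() < config.synonymRate:
            syn_genus = _genus_name(rng)
            synonyms = (f"{syn_genus} {_epithet(rng)}",)
        entries.append(
            BackboneEntry(
                acceptedName=t["name"],
                authority=t["authority"],
                rank=t["rank"],
                phylum=t["phylum"],
                taxonClass=t["class"],
                order=t["order"],
                family=t["family"],
                genus=t["genus"],
                isMarine=True,
                synonyms=synonyms,
            )
        )
    for _ in range(config.nonMarineTaxa):
        while True:
            name = f"{_genus_name(rng)} {_epithet(rng)}"
            if name not in used_names:
                used_names.add(name)
                break
        entries.append(
            BackboneEntry(
                acceptedName=name,
                authority=_authority(rng),
                phylum="Chordata",
                taxonClass="Actinopteri",
                order="Salmoniformes",
                family="Salmonidae",
                genus=name.split()[0],
                isMarine=False,
            )
        )
    backbone = TaxonomicBackbone(entries)

    # ---- typo variants (one per taxon, used on demand) ------------------
    typo_of: dict[str, str] = {}
    for t in taxa:
        while True:
            variant = _typo(rng, t["name"])
            if variant not in used_names and variant not in typo_of.values():
                break
        typo_of[t["name"]] = variant

    # ---- records --------------------------------------------------------
    lon_min, lat_min, lon_max, lat_max = area.bounds

    def point_inside() -> tuple[float, float]:
        while True:
            lat = float(rng.uniform(lat_min, lat_max))
            lon = float(rng.uniform(lon_min, lon_max))
            if area.contains(lat, lon):
                return round(lat, 6), round(lon, 6)

    def point_outside() -> tuple[float, float]:
        while True:
            lat = float(rng.uniform(lat_min - 0.5, lat_max + 0.5))
            lon = float(rng.uniform(lon_min - 0.5, lon_max + 0.5))
            if not area.contains(lat, lon):
                return round(lat, 6), round(lon, 6)

    def random_date() -> str:
        year = int(rng.integers(1967, 2022))
        if rng.random() < 0.1:
            return str(year)  # year-precision
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        return f"{year:04d}-{month:02d}-{day:02d}"

    raw_tables: dict[str, pd.DataFrame] = {}
    mappings: dict[str, ColumnMapping] = {}
    sources: list[SourceCatalogue] = []
    used_typos: set[str] = set()
    patch_rows: list[GeoPatch] = []
    n_inside = n_outside = n_missing = 0
    out_of_area_per_source: dict[str, int] = {}

    for cat in categories:
        dataset_id = _DATASET_OF_CATEGORY[cat]
        schema = _SOURCE_SCHEMAS[cat]
        inv = {core: src for src, core in schema.items()}
        taxa_here = category_taxa[cat]
        n_records = config.recordsPerSource[cat]
        # every taxon of the source gets one record; the rest multinomial
        extra = n_records - len(taxa_here)
        counts = np.ones(len(taxa_here), dtype=int)
        if extra > 0:
            counts += rng.multinomial(extra, np.full(len(taxa_here), 1.0 / len(taxa_here)))
        rows: list[dict] = []
        ordinal = 0
        for taxon_name, n in zip(taxa_here, counts):
            for k in range(int(n)):
                if "occurrenceID" in inv:
                    rec_id = f"{dataset_id}-{ordinal:05d}"
                else:
                    # mirrors the ID map_columns synthesises for sources
                    # whose schema carries no identifier column
                    rec_id = f"{dataset_id}:{ordinal}"
                ordinal += 1
                draw = rng.random()
                if draw < config.outOfAreaRate:
                    disposition = "outOfArea"
                elif draw < config.outOfAreaRate + config.missingCoordRate:
                    disposition = "missing"
                elif draw < (
                    config.outOfAreaRate
                    + config.missingCoordRate
                    + config.coordErrorRate
                ):
                    disposition = "coordError"
                elif cat in _PRIVATE_COLUMNS and draw < (
                    config.outOfAreaRate
                    + config.missingCoordRate
                    + config.coordErrorRate
                    + config.privateCoordRate
                ):
                    disposition = "private"
                else:
                    disposition = "normal"
                # the first record of each (category, taxon) must survive
                # the area filter so the designed overlap structure is
                # exactly recoverable from the curated catalogue
                if k == 0 and disposition == "outOfArea":
                    disposition = "normal"

                reported = taxon_name
                if rng.random() < config.typoRate:
                    reported = typo_of[taxon_name]
                    used_typos.add(taxon_name)

                row: dict = {
                    inv["reportedName"]: reported,
                    inv["eventDate"]: random_date(),
                    "_trueTaxon": taxon_name,
                    "_disposition": disposition,
                }
                if "occurrenceID" in inv:
                    row[inv["occurrenceID"]] = rec_id
                if "recordedBy" in inv:
                    row[inv["recordedBy"]] = f"{_surname(rng)} {_surname(rng)}"
                if disposition == "missing":
                    row[inv["decimalLatitude"]] = None
                    row[inv["decimalLongitude"]] = None
                    n_missing += 1
                elif disposition == "outOfArea":
                    lat, lon = point_outside()
                    row[inv["decimalLatitude"]] = lat
                    row[inv["decimalLongitude"]] = lon
                    n_outside += 1
                    out_of_area_per_source[cat] = (
                        out_of_area_per_source.get(cat, 0) + 1
                    )
                elif disposition == "coordError":
                    true_lat, true_lon = point_inside()
                    bad_lat, bad_lon = point_outside()
                    row[inv["decimalLatitude"]] = bad_lat
                    row[inv["decimalLongitude"]] = bad_lon
                    patch_rows.append(
                        GeoPatch(
                            datasetID=dataset_id,
                            occurrenceID=rec_id,
                            newLatitude=true_lat,
                            newLongitude=true_lon,
                            note="verified locality; transcription error in source",
                        )
                    )
                    n_inside += 1
                elif disposition == "private":
                    true_lat, true_lon = point_inside()
                    obsc_lat = round(true_lat + float(rng.uniform(-0.2, 0.2)), 6)
                    obsc_lon = round(true_lon + float(rng.uniform(-0.2, 0.2)), 6)
                    row[inv["decimalLatitude"]] = obsc_lat
                    row[inv["decimalLongitude"]] = obsc_lon
                    priv_lat_col, priv_lon_col = _PRIVATE_COLUMNS[cat]
                    row[priv_lat_col] = true_lat
                    row[priv_lon_col] = true_lon
                    n_inside += 1
                else:
                    lat, lon = point_inside()
                    row[inv["decimalLatitude"]] = lat
                    row[inv["decimalLongitude"]] = lon
                    n_inside += 1
                if cat in _PRIVATE_COLUMNS:
                    priv_lat_col, priv_lon_col = _PRIVATE_COLUMNS[cat]
                    row.setdefault(priv_lat_col, None)
                    row.setdefault(priv_lon_col, None)
                rows.append(row)

        columns = list(schema) + (
            list(_PRIVATE_COLUMNS.get(cat, ())) + ["_trueTaxon", "_disposition"]
        )
        frame = pd.DataFrame(rows, columns=columns)
        mapping = ColumnMapping(
            datasetID=dataset_id,
            sourceCategory=cat,
            columnMap=tuple(schema.items()),
            privateCoordinateColumns=_PRIVATE_COLUMNS.get(cat),
        )
        raw_tables[dataset_id] = frame
        mappings[dataset_id] = mapping
        sources.append(map_columns(frame, mapping))

    resolution_table = TaxonResolutionTable(
        ResolutionRule(
            reportedName=typo_of[true_name],
            preferredName=true_name,
            reason="typo",
            note="injected single-character error",
            addedBy="generator",
            dateAdded="2021-01-01",
        )
        for true_name in sorted(used_typos)
    )
    patch_table = GeoPatchTable(patch_rows)

    # ---- expected statistics, by direct enumeration ---------------------
    curated_records = {
        cat: config.recordsPerSource[cat] - out_of_area_per_source.get(cat, 0)
        for cat in categories
    }
    expected = _enumerate_stats(category_taxa, curated_records)

    truth = GroundTruth(
        taxa=taxa,
        trueResolutionTable=resolution_table,
        truePatchTable=patch_table,
        expectedStats=expected,
        expectedPartition=(n_inside, n_outside, n_missing),
        expectedTaxonNames=sorted(taxon_by_name),
        categoryTaxa={c: sorted(v) for c, v in category_taxa.items()},
    )
    return FixtureBundle(
        rawTables=raw_tables,
        mappings=mappings,
        sources=sources,
        backbone=backbone,
        resolutionTable=resolution_table,
        patchTable=patch_table,
        area=area,
        truth=truth,
    )


def _enumerate_stats(
    category_taxa: dict[str, list[str]],
    curated_records: dict[str, int],
) -> ContributionStats:
    """Expected contribution stats by naive enumeration over the design.

    Record counts are those of the curated catalogue (out-of-area records
    do not survive the polygon filter and are excluded here too).
    """
    cats_of: dict[str, set[str]] = {}
    for cat, names in category_taxa.items():
        for name in names:
            cats_of.setdefault(name, set()).add(cat)
    per_source: dict[str, SourceTally] = {}
    shared = 0
    for cat in category_taxa:
        per_source[cat] = SourceTally(
            recordCount=curated_records[cat],
            taxonCount=len(category_taxa[cat]),
        )
    for name, cats in cats_of.items():
        if len(cats) == 1:
            per_source[next(iter(cats))].exclusiveCount += 1
        else:
            shared += 1
    exclusives = {c: t.exclusiveCount for c, t in per_source.items()}
    stats = ContributionStats(
        perSource=per_source,
        sharedCount=shared,
        totalTaxa=len(cats_of),
        totalRecords=sum(curated_records.values()),
        groupedPercentages=novelty_percentages(exclusives, PAPER_GROUPING),
    )
    gmap = PAPER_GROUPING.as_dict()
    for grp in PAPER_GROUPING.display_groups:
        cats = [c for c, g in gmap.items() if g == grp]
        records = sum(curated_records.get(c, 0) for c in cats)
        excl = sum(exclusives.get(c, 0) for c in cats)
        if excl > 0:
            stats.ratios[grp] = records_per_novel_ratio(records, excl)
    stats.check_invariants()
    return stats


def oracle_stats(
    sources: list[SourceCatalogue], truth: GroundTruth
) -> ContributionStats:
    """Brute-force contribution stats from the generator's own labels.

    Uses the auxiliary ``_trueTaxon``/``_disposition`` columns the
    generator plants on every record — no pipeline code path (no name
    resolution, no polygon test) is involved, so this is an independent
    cross-check. Out-of-area records are excluded, mirroring what survives
    curation.
    """
    cats_of: dict[str, set[str]] = {}
    per_source: dict[str, SourceTally] = {}
    total_records = 0
    for source in sources:
        cat = source.mapping.sourceCategory
        tally = per_source.setdefault(cat, SourceTally())
        for rec in source.records:
            if rec.verbatim.get("_disposition") == "outOfArea":
                continue
            name = rec.verbatim["_trueTaxon"]
            cats_of.setdefault(name, set()).add(cat)
            tally.recordCount += 1
            total_records += 1
    shared = 0
    for name, cats in sorted(cats_of.items()):
        for cat in cats:
            per_source[cat].taxonCount += 1
        if len(cats) == 1:
            per_source[next(iter(cats))].exclusiveCount += 1
        else:
            shared += 1
    exclusives = {c: t.exclusiveCount for c, t in per_source.items()}
    stats = ContributionStats(
        perSource=per_source,
        sharedCount=shared,
        totalTaxa=len(cats_of),
        totalRecords=total_records,
        groupedPercentages=novelty_percentages(exclusives, PAPER_GROUPING),
    )
    gmap = PAPER_GROUPING.as_dict()
    for grp in PAPER_GROUPING.display_groups:
        cats = [c for c, g in gmap.items() if g == grp]
        records = sum(per_source[c].recordCount for c in cats if c in per_source)
        excl = sum(exclusives.get(c, 0) for c in cats)
        if excl > 0:
            stats.ratios[grp] = records_per_novel_ratio(records, excl)
    stats.check_invariants()
    return stats
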