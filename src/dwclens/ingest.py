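"""Catalogue ingestion: column mapping, merging and scope filtering.

Each source catalogue arrives as a CSV table with its own column
vocabulary (dive logs, museum voucher exports, crowd-sourced observation
exports, survey tables). A declarative :class:`ColumnMapping` crosswalks
each source's columns onto the common Darwin Core field subset; a dataset
ID is stamped on every record; catalogues are merged into a single master
catalogue; and the master is partitioned into taxa of interest versus
out-of-scope records using positive evidence from the taxonomic backbone.

Column matching is case-sensitive and exact by design: silent case-folding
would hide upstream schema drift, and surfacing drift is the point of the
lens architecture. Unmapped source columns are preserved verbatim on each
record, never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    Catalogue,
    CurationError,
    OccurrenceRecord,
    TaxonomicBackbone,
)

__all__ = [
    "MappingError",
    "ColumnMapping",
    "SourceCatalogue",
    "ScopeConfig",
    "map_columns",
    "merge_catalogues",
    "filter_taxa_of_interest",
]

#: Core fields a mapping may target. ``reportedName`` is mandatory.
CORE_FIELDS = (
    "occurrenceID",
    "reportedName",
    "taxonRank",
    "phylum",
    "taxonClass",
    "order",
    "family",
    "genus",
    "authority",
    "eventDate",
    "decimalLatitude",
    "decimalLongitude",
    "coordinateNote",
    "recordedBy",
    "basisOfRecord",
)

_FLOAT_FIELDS = {"decimalLatitude", "decimalLongitude"}


class MappingError(CurationError):
    """A column mapping is inconsistent with itself or with its table."""


@dataclass(frozen=True)
class ColumnMapping:
    """Declarative crosswalk from one source's columns to the core fields.

    Parameters
    ----------
    datasetID:
        Identifier stamped on every record of this source.
    sourceCategory:
        One of ``pmls``, ``collection``, ``crowd``, ``ecological``,
        ``literature``.
    columnMap:
        Pairs ``sourceColumn -> coreField``. Every core field may be
        targeted at most once; a ``reportedName`` target is mandatory.
    privateCoordinateColumns:
        Optional ``(latitudeColumn, longitudeColumn)`` pair holding
        obscured/private coordinates in project-specific fields.
    constants:
        Fixed core-field values applied to every record (e.g. a
        ``basisOfRecord`` shared by the whole catalogue).
    """

    datasetID: str
    sourceCategory: str
    columnMap: tuple[tuple[str, str], ...]
    privateCoordinateColumns: Optional[tuple[str, str]] = None
    constants: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        targets = [t for _, t in self.columnMap]
        dupes = {t for t in targets if targets.count(t) > 1}
        if dupes:
            raise MappingError(
                f"mapping {self.datasetID!r}: core fields targeted more than once: "
                f"{sorted(dupes)}"
            )
        if "reportedName" not in targets:
            raise MappingError(
                f"mapping {self.datasetID!r}: a reportedName target is mandatory"
            )
        unknown = [t for t in targets if t not in CORE_FIELDS]
        if unknown:
            raise MappingError(
                f"mapping {self.datasetID!r}: unknown core fields {unknown}"
            )

    @classmethod
    def from_dict(cls, cfg: dict) -> "ColumnMapping":
        priv = cfg.get("privateCoordinateColumns")
        return cls(
            datasetID=cfg["datasetID"],
            sourceCategory=cfg["sourceCategory"],
            columnMap=tuple((k, v) for k, v in cfg["columnMap"].items()),
            privateCoordinateColumns=tuple(priv) if priv else None,
            constants=tuple((cfg.get("constants") or {}).items()),
        )

    @classmethod
    def from_json(cls, path) -> "ColumnMapping":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SourceCatalogue:
    """One mapped source: its crosswalk plus its normalised records."""

    mapping: ColumnMapping
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def map_columns(raw_table: pd.DataFrame, mapping: ColumnMapping) -> SourceCatalogue:
    """Normalise one raw source table onto the Darwin Core field subset.

    One record per input row, row order preserved. Columns not named in
    the mapping are kept verbatim in each record's auxiliary store. A
    missing ``occurrenceID`` is synthesised as ``datasetID:ordinal``.

    Raises
    ------
    MappingError
        If the mapping names a column absent from the table (matching is
        exact and case-sensitive), or if the mapped ``occurrenceID``
        column contains duplicates (listed in the message).
    """
    missing = [src for src, _ in mapping.columnMap if src not in raw_table.columns]
    if mapping.privateCoordinateColumns:
        missing += [
            c for c in mapping.privateCoordinateColumns if c not in raw_table.columns
        ]
    if missing:
        raise MappingError(
            f"mapping {mapping.datasetID!r} names columns absent from the table: "
            f"{missing}"
        )

    mapped_sources = {src for src, _ in mapping.columnMap}
    if mapping.privateCoordinateColumns:
        mapped_sources.update(mapping.privateCoordinateColumns)
    unmapped = [c for c in raw_table.columns if c not in mapped_sources]

    constants = dict(mapping.constants)
    records: list[OccurrenceRecord] = []
    for ordinal, (_, row) in enumerate(raw_table.iterrows()):
        rec = OccurrenceRecord(
            occurrenceID=f"{mapping.datasetID}:{ordinal}",
            datasetID=mapping.datasetID,
            sourceCategory=mapping.sourceCategory,
        )
        for core_field, value in constants.items():
            _assign(rec, core_field, value)
        for src, core_field in mapping.columnMap:
            _assign(rec, core_field, row[src])
        if mapping.privateCoordinateColumns:
            lat_col, lon_col = mapping.privateCoordinateColumns
            rec.privateLatitude = _to_float(row[lat_col])
            rec.privateLongitude = _to_float(row[lon_col])
        rec.verbatim = {c: _cell_str(row[c]) for c in unmapped}
        rec.validate()
        records.append(rec)

    dupes = _duplicates(r.occurrenceID for r in records)
    if dupes:
        raise MappingError(
            f"catalogue {mapping.datasetID!r}: duplicate occurrenceIDs {sorted(dupes)}"
        )
    return SourceCatalogue(mapping=mapping, records=records)


def _assign(rec: OccurrenceRecord, core_field: str, value) -> None:
    if core_field in _FLOAT_FIELDS:
        setattr(rec, core_field, _to_float(value))
    else:
        setattr(rec, core_field, _cell_str(value))


def _cell_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def _to_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    return float(value)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


def merge_catalogues(catalogues: Sequence[SourceCatalogue]) -> Catalogue:
    """Combine mapped sources into a single master catalogue.

    Record count is conserved; order is stable by (input catalogue order,
    source row order); ``(datasetID, occurrenceID)`` is unique in the
    result. Duplicate dataset IDs across catalogues are an error — two
    sources must never masquerade as one.
    """
    ids = [c.mapping.datasetID for c in catalogues]
    dupes = _duplicates(ids)
    if dupes:
        raise CurationError(f"duplicate datasetIDs across catalogues: {sorted(dupes)}")
    master = Catalogue(r for cat in catalogues for r in cat.records)
    master.check_unique_ids()
    return master


@dataclass(frozen=True)
class ScopeConfig:
    """Predicate configuration for the taxa-of-interest filter.

    The filter is positive-evidence-based: a record is excluded only when
    the backbone affirmatively places its taxon out of scope (non-marine
    when ``requireMarine``, or a phylum outside ``phyla`` when ``phyla``
    is non-empty). Names the backbone does not know are kept and flagged
    ``unresolved`` for curator review.
    """

    requireMarine: bool = True
    phyla: tuple[str, ...] = ()


def filter_taxa_of_interest(
    master: Catalogue,
    backbone: TaxonomicBackbone,
    scope: ScopeConfig = ScopeConfig(),
) -> tuple[Catalogue, Catalogue]:
    """Partition the master catalogue into (kept, excluded) by scope.

    The partition is lossless: every input record lands in exactly one
    side. Each excluded record logs the rule that excluded it.
    """
    kept: list[OccurrenceRecord] = []
    excluded: list[OccurrenceRecord] = []
    for rec in master:
        name = rec.resolvedName or rec.reportedName
        entry = backbone.lookup(name)
        if entry is None:
            out = rec.copy()
            if "unresolved" not in out.flags:
                out.flags.append("unresolved")
            kept.append(out)
            continue
        rule = None
        if scope.requireMarine and not entry.isMarine:
            rule = "not marine"
        elif scope.phyla and entry.phylum not in scope.phyla:
            rule = f"phylum {entry.phylum!r} out of scope"
        out = rec.copy()
        if rule is None:
            kept.append(out)
        else:
            out.log_change("scope_filter", "excluded", "", rule, rule)
            excluded.append(out)
    return Catalogue(kept), Catalogue(excluded)
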