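"""Source-contribution analysis of the curated dataset.

Quantifies what each kind of sampling effort adds to the cumulative
species list: per-source record and taxon tallies, *exclusive* ("novel"
or "unique") reports — taxa reported by exactly one source category —
versus taxa shared between two or more categories, grouped novelty
percentages, and record-to-novel-report ratios (how many occurrence
records a source contributes per novel taxon it adds, the ``n`` in
``1:n``).

Exclusivity is defined at the source-category level: the five categories
are systematic dive surveys, museum voucher collections, crowd-sourced
observations, ecological surveys and literature records, with the last
two combined into an "Other" display group for percentages and ratios.
All rounding is half away from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .datamodel import Catalogue, CurationError, _write_dict_csv
from .curation import TaxonSummary

__all__ = [
    "DisplayGrouping",
    "PAPER_GROUPING",
    "SourceTally",
    "ContributionStats",
    "tally_sources",
    "classify_exclusive_shared",
    "novelty_percentages",
    "records_per_novel_ratio",
    "classification_counts",
    "compute_contribution_stats",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (65.5 → 66, −65.5 → −66).

    Python's built-in ``round`` is banker's rounding; checklist arithmetic
    follows the everyday convention instead.
    """
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class DisplayGrouping:
    """Total mapping from source category to display group."""

    groups: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.groups:
            raise CurationError("display grouping is empty")

    def group_of(self, category: str) -> str:
        for cat, grp in self.groups:
            if cat == category:
                return grp
        raise CurationError(f"source category {category!r} has no display group")

    def as_dict(self) -> dict[str, str]:
        return dict(self.groups)

    @property
    def display_groups(self) -> list[str]:
        seen: list[str] = []
        for _, grp in self.groups:
            if grp not in seen:
                seen.append(grp)
        return seen


#: Standard display grouping: dive surveys, collections and crowd-sourced
#: data stand alone; ecological-survey and literature records are combined
#: into "Other".
PAPER_GROUPING = DisplayGrouping(
    (
        ("pmls", "PMLS"),
        ("collection", "Collections"),
        ("crowd", "Crowd"),
        ("ecological", "Other"),
        ("literature", "Other"),
    )
)


@dataclass
class SourceTally:
    recordCount: int = 0
    taxonCount: int = 0
    exclusiveCount: int = 0


@dataclass
class ContributionStats:
    """The full per-source novelty picture of a curated dataset."""

    perSource: dict[str, SourceTally] = field(default_factory=dict)
    perDataset: dict[str, SourceTally] = field(default_factory=dict)
    sharedCount: int = 0
    totalTaxa: int = 0
    totalRecords: int = 0
    groupedPercentages: dict[str, int] = field(default_factory=dict)
    ratios: dict[str, int] = field(default_factory=dict)

    def check_invariants(self) -> None:
        total_excl = sum(t.exclusiveCount for t in self.perSource.values())
        if total_excl + self.sharedCount != self.totalTaxa:
            raise CurationError(
                f"exclusive ({total_excl}) + shared ({self.sharedCount}) "
                f"!= total taxa ({self.totalTaxa})"
            )
        if sum(t.recordCount for t in self.perSource.values()) != self.totalRecords:
            raise CurationError("per-source record counts do not sum to the total")
        for cat, t in self.perSource.items():
            if t.exclusiveCount > t.taxonCount:
                raise CurationError(f"{cat}: exclusive count exceeds taxon count")

    def to_json(self, path_or_buf) -> None:
        obj = {
            "perSource": {
                c: vars(t) for c, t in sorted(self.perSource.items())
            },
            "perDataset": {
                d: vars(t) for d, t in sorted(self.perDataset.items())
            },
            "sharedCount": self.sharedCount,
            "totalTaxa": self.totalTaxa,
            "totalRecords": self.totalRecords,
            "groupedPercentages": self.groupedPercentages,
            "ratios": self.ratios,
        }
        if hasattr(path_or_buf, "write"):
            json.dump(obj, path_or_buf, indent=2)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                json.dump(obj, fh, indent=2)

    def to_csv(self, path_or_buf, grouping: DisplayGrouping = PAPER_GROUPING) -> None:
        rows = []
        gmap = grouping.as_dict()
        for grp in grouping.display_groups:
            cats = [c for c, g in gmap.items() if g == grp]
            rows.append(
                {
                    "displayGroup": grp,
                    "recordCount": sum(
                        self.perSource.get(c, SourceTally()).recordCount for c in cats
                    ),
                    "exclusiveCount": sum(
                        self.perSource.get(c, SourceTally()).exclusiveCount
                        for c in cats
                    ),
                    "noveltyPercent": self.groupedPercentages.get(grp, ""),
                    "recordsPerNovelReport": self.ratios.get(grp, ""),
                }
            )
        _write_dict_csv(
            path_or_buf,
            [
                "displayGroup",
                "recordCount",
                "exclusiveCount",
                "noveltyPercent",
                "recordsPerNovelReport",
            ],
            rows,
        )


def tally_sources(
    summaries: Sequence[TaxonSummary], master: Catalogue
) -> dict[str, SourceTally]:
    """Per-category record and taxon tallies.

    A taxon reported by two categories counts in both taxon tallies —
    taxon counts are per-category presence, not a partition.
    """
    tallies: dict[str, SourceTally] = {}
    for rec in master:
        tallies.setdefault(rec.sourceCategory, SourceTally()).recordCount += 1
    for s in summaries:
        for cat in s.reportingCategories:
            tallies.setdefault(cat, SourceTally()).taxonCount += 1
    return tallies


def classify_exclusive_shared(
    summaries: Sequence[TaxonSummary],
) -> tuple[dict[str, int], int, int]:
    """Split taxa into per-category exclusives and the shared pool.

    A taxon is exclusive to category *c* iff its reporting categories are
    exactly ``{c}``; it is shared iff two or more categories report it.
    Exclusives plus shared always sum to the total distinct taxa.
    """
    exclusives: dict[str, int] = {}
    shared = 0
    for s in summaries:
        cats = s.reportingCategories
        if not cats:
            raise CurationError(
                f"summary {s.resolvedName!r} has no reporting categories"
            )
        if len(cats) == 1:
            (only,) = cats
            exclusives[only] = exclusives.get(only, 0) + 1
        else:
            shared += 1
    return exclusives, shared, sum(exclusives.values()) + shared


def novelty_percentages(
    exclusive_per_source: Mapping[str, int],
    grouping: DisplayGrouping = PAPER_GROUPING,
) -> dict[str, int]:
    """Share of novel reports per display group, as integer percent.

    Percent = group exclusives / total exclusives × 100, rounded half
    away from zero. Raises on a zero total (no novelty to apportion).
    """
    gmap = grouping.as_dict()
    by_group: dict[str, int] = {g: 0 for g in grouping.display_groups}
    for cat, count in exclusive_per_source.items():
        if cat not in gmap:
            raise CurationError(f"source category {cat!r} has no display group")
        by_group[gmap[cat]] += count
    total = sum(by_group.values())
    if total == 0:
        raise CurationError("no exclusive reports: percentages undefined")
    return {g: round_half_away(100.0 * n / total) for g, n in by_group.items()}


def records_per_novel_ratio(record_count: int, exclusive_count: int) -> int:
    """The ``n`` in a ``1:n`` novel-reports-to-records ratio.

    ``record_count / exclusive_count`` rounded half away from zero. A
    source with no exclusive reports has no defined ratio.
    """
    if exclusive_count <= 0:
        raise CurationError("ratio undefined: no exclusive reports")
    return round_half_away(record_count / exclusive_count)


def classification_counts(
    summaries: Sequence[TaxonSummary], phylum: str
) -> tuple[int, int, int, int, int]:
    """(classes, orders, families, genera, species) within one phylum.

    Distinct non-empty values at each rank among the phylum's
    species-rank summaries — the counts printed at the head of each
    checklist section.
    """
    in_phylum = [
        s
        for s in summaries
        if s.phylum == phylum and (s.taxonRank in ("", "species"))
    ]
    classes = {s.taxonClass for s in in_phylum if s.taxonClass}
    orders = {s.order for s in in_phylum if s.order}
    families = {s.family for s in in_phylum if s.family}
    genera = {s.genus for s in in_phylum if s.genus}
    return (len(classes), len(orders), len(families), len(genera), len(in_phylum))


def compute_contribution_stats(
    summaries: Sequence[TaxonSummary],
    master: Catalogue,
    grouping: DisplayGrouping = PAPER_GROUPING,
) -> ContributionStats:
    """Assemble the full :class:`ContributionStats` for a curated dataset.

    Combines per-category tallies, the exclusive/shared classification,
    grouped novelty percentages and per-group record-to-novelty ratios
    (a group without exclusives simply has no ratio entry). A
    per-dataset breakdown is reported alongside the per-category one.
    """
    tallies = tally_sources(summaries, master)
    exclusives, shared, total = classify_exclusive_shared(summaries)
    for cat, n in exclusives.items():
        tallies.setdefault(cat, SourceTally()).exclusiveCount = n

    per_dataset: dict[str, SourceTally] = {}
    for rec in master:
        per_dataset.setdefault(rec.datasetID, SourceTally()).recordCount += 1
    for s in summaries:
        for ds in s.reportingDatasetIDs:
            per_dataset.setdefault(ds, SourceTally()).taxonCount += 1
        if len(s.reportingDatasetIDs) == 1:
            (only,) = s.reportingDatasetIDs
            per_dataset.setdefault(only, SourceTally()).exclusiveCount += 1

    stats = ContributionStats(
        perSource=tallies,
        perDataset=per_dataset,
        sharedCount=shared,
        totalTaxa=total,
        totalRecords=len(master),
        groupedPercentages=novelty_percentages(exclusives, grouping),
    )
    gmap = grouping.as_dict()
    for grp in grouping.display_groups:
        cats = [c for c, g in gmap.items() if g == grp]
        records = sum(tallies.get(c, SourceTally()).recordCount for c in cats)
        excl = sum(exclusives.get(c, 0) for c in cats)
        if excl > 0:
            stats.ratios[grp] = records_per_novel_ratio(records, excl)
    stats.check_invariants()
    return stats
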