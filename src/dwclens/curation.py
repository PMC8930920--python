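"""Summary building, expert-sheet round-trip, diffing, and the
fixed-point curation loop.

After resolution and spatial filtering, the master catalogue is condensed
into one :class:`TaxonSummary` per distinct taxon and split into
per-phylum expert sheets. Experts edit a small set of columns
(``preferredName``, ``authority``, ``curationNote``); everything else on
a sheet is computed and ignored on re-import. Re-integration turns name
edits into *proposed* resolution rules — they are appended to the taxon
swaps lens rather than applied in place, preserving the lens
architecture — and the re-integrated summaries are diffed against the
pre-curation ones. The whole pipeline is then re-run with the grown lens
until a pass produces no further discrepancies: the curated checklist is
a fixed point of the ingest–resolve–summarise–review loop.

The expert-curation stage is a pluggable function (an interactive CSV
edit in real use, a scripted editor in tests); the Sheets/CSV transport
is a detail, the diff/reconcile semantics are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    Catalogue,
    CurationError,
    NameParseError,
    ParsedName,
    TaxonomicBackbone,
    _write_dict_csv,
    normalize_key_text,
    name_key,
    parse_scientific_name,
)
from .georef import (
    GeoPatchTable,
    ProjectArea,
    apply_geo_patches,
    filter_by_area,
    promote_private_coordinates,
)
from .ingest import ScopeConfig, SourceCatalogue, filter_taxa_of_interest, merge_catalogues
from .taxonomy import (
    RESOLUTION_REASONS,
    ResolutionError,
    ResolutionRule,
    TaxonResolutionTable,
    apply_taxon_resolution,
    validate_against_backbone,
)

__all__ = [
    "TaxonSummary",
    "summarize_taxa",
    "split_by_phylum",
    "sheets_from_summaries",
    "write_sheets",
    "read_sheets",
    "reintegrate_sheets",
    "DiffEntry",
    "DiffReport",
    "diff_summaries",
    "PipelineConfig",
    "PipelineResult",
    "ConvergenceError",
    "run_to_fixed_point",
    "SHEET_EDITABLE_COLUMNS",
    "SHEET_COMPUTED_COLUMNS",
]


def summary_key(name: str) -> str:
    """Grouping key for a resolved name; unparseable strings fall back to
    plain text normalisation rather than being dropped."""
    try:
        return name_key(name)
    except NameParseError:
        return normalize_key_text(name)


# --------------------------------------------------------------------------
# TaxonSummary
# --------------------------------------------------------------------------


@dataclass
class TaxonSummary:
    """One curated row per distinct taxon in the master catalogue."""

    resolvedName: str
    parsed: Optional[ParsedName]
    authority: str = ""
    taxonRank: str = ""
    phylum: str = ""
    taxonClass: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    reportingDatasetIDs: frozenset[str] = frozenset()
    reportingCategories: frozenset[str] = frozenset()
    recordCount: int = 0
    firstDate: str = ""
    lastDate: str = ""
    curationNote: str = ""
    validationStatus: str = ""

    @property
    def key(self) -> str:
        return summary_key(self.resolvedName)


def summarize_taxa(
    master: Catalogue, backbone: Optional[TaxonomicBackbone] = None
) -> list[TaxonSummary]:
    """Condense the catalogue into one summary per distinct taxon.

    Taxa are identified by the canonical key of the resolved name, so a
    qualified name (``Nereis cf. zonata``) is a separate row from its
    unqualified binomial. Record counts over all summaries sum to the
    catalogue size. Classification and authority come from the records,
    back-filled from the backbone when supplied; ``validationStatus`` is
    attached from :func:`validate_against_backbone` when a backbone is
    given. Output order is classification-then-name.
    """
    groups: dict[str, list] = {}
    order_of_appearance: dict[str, int] = {}
    for rec in master:
        name = rec.resolvedName or rec.reportedName
        k = summary_key(name)
        groups.setdefault(k, []).append(rec)
        order_of_appearance.setdefault(k, len(order_of_appearance))

    validation: dict[str, str] = {}
    if backbone is not None:
        report = validate_against_backbone(master, backbone)
        validation = {summary_key(r.resolvedName): r.status for r in report.results}

    summaries: list[TaxonSummary] = []
    for k, recs in groups.items():
        name = recs[0].resolvedName or recs[0].reportedName
        try:
            parsed = parse_scientific_name(name)
        except NameParseError:
            parsed = None
        entry = backbone.lookup(name) if backbone is not None else None
        dates = sorted(r.eventDate for r in recs if r.eventDate)
        summaries.append(
            TaxonSummary(
                resolvedName=name,
                parsed=parsed,
                authority=_first(
                    [r.authority for r in recs],
                    entry.authority if entry else "",
                    parsed.authority if parsed else "",
                ),
                taxonRank=_first(
                    [r.taxonRank for r in recs], entry.rank if entry else ""
                ),
                phylum=_first([r.phylum for r in recs], entry.phylum if entry else ""),
                taxonClass=_first(
                    [r.taxonClass for r in recs], entry.taxonClass if entry else ""
                ),
                order=_first([r.order for r in recs], entry.order if entry else ""),
                family=_first([r.family for r in recs], entry.family if entry else ""),
                genus=_first(
                    [r.genus for r in recs],
                    entry.genus if entry else (parsed.genus if parsed else ""),
                ),
                reportingDatasetIDs=frozenset(r.datasetID for r in recs),
                reportingCategories=frozenset(
                    r.sourceCategory for r in recs if r.sourceCategory
                ),
                recordCount=len(recs),
                firstDate=dates[0] if dates else "",
                lastDate=dates[-1] if dates else "",
                validationStatus=validation.get(k, ""),
            )
        )
    summaries.sort(
        key=lambda s: (s.phylum, s.taxonClass, s.order, s.family, s.genus, s.resolvedName)
    )
    return summaries


def _first(values: Iterable[str], *fallbacks: str) -> str:
    for v in values:
        if v:
            return v
    for v in fallbacks:
        if v:
            return v
    return ""


# --------------------------------------------------------------------------
# Expert sheets
# --------------------------------------------------------------------------

#: Columns an expert may edit on a phylum sheet.
SHEET_EDITABLE_COLUMNS = ["preferredName", "editReason", "authority", "curationNote"]
#: Computed columns; edits to these are ignored on re-import.
SHEET_COMPUTED_COLUMNS = [
    "taxonRank",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "recordCount",
    "firstDate",
    "lastDate",
    "reportingDatasetIDs",
    "reportingCategories",
    "validationStatus",
]
SHEET_COLUMNS = ["key"] + SHEET_EDITABLE_COLUMNS + SHEET_COMPUTED_COLUMNS


def split_by_phylum(summaries: Sequence[TaxonSummary]) -> dict[str, list[TaxonSummary]]:
    """Partition summaries into per-phylum groups for expert curation.

    Summaries without a phylum go to the ``incertae`` sheet. Within each
    sheet the order is classification-then-name. Concatenating all sheets
    recovers the full summary set.
    """
    sheets: dict[str, list[TaxonSummary]] = {}
    for s in summaries:
        sheets.setdefault(s.phylum or "incertae", []).append(s)
    for group in sheets.values():
        group.sort(
            key=lambda s: (s.taxonClass, s.order, s.family, s.genus, s.resolvedName)
        )
    return dict(sorted(sheets.items()))


def sheets_from_summaries(
    summaries: Sequence[TaxonSummary],
) -> dict[str, pd.DataFrame]:
    """Render per-phylum expert sheets as data frames.

    The ``key`` column (the pre-curation resolved name) identifies each
    row and must never be edited; ``preferredName`` starts equal to the
    key's name and is where an expert records a rename, together with a
    reason code in ``editReason``.
    """
    out: dict[str, pd.DataFrame] = {}
    for phylum, group in split_by_phylum(summaries).items():
        rows = []
        for s in group:
            rows.append(
                {
                    "key": s.resolvedName,
                    "preferredName": s.resolvedName,
                    "editReason": "",
                    "authority": s.authority,
                    "curationNote": s.curationNote,
                    "taxonRank": s.taxonRank,
                    "phylum": s.phylum,
                    "class": s.taxonClass,
                    "order": s.order,
                    "family": s.family,
                    "genus": s.genus,
                    "recordCount": s.recordCount,
                    "firstDate": s.firstDate,
                    "lastDate": s.lastDate,
                    "reportingDatasetIDs": "|".join(sorted(s.reportingDatasetIDs)),
                    "reportingCategories": "|".join(sorted(s.reportingCategories)),
                    "validationStatus": s.validationStatus,
                }
            )
        out[phylum] = pd.DataFrame(rows, columns=SHEET_COLUMNS)
    return out


def write_sheets(sheets: dict[str, pd.DataFrame], out_dir) -> None:
    """Write each sheet as UTF-8 RFC 4180 CSV named ``sheet_<phylum>.csv``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for phylum, frame in sheets.items():
        safe = normalize_key_text(phylum).replace(" ", "_") or "incertae"
        frame.to_csv(
            os.path.join(out_dir, f"sheet_{safe}.csv"), index=False, lineterminator="\n"
        )


def read_sheets(paths: Iterable) -> dict[str, pd.DataFrame]:
    """Read edited sheet CSVs back; the sheet name is taken from the
    ``phylum`` column (falling back to the file name)."""
    import os

    out: dict[str, pd.DataFrame] = {}
    for path in paths:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "phylum" in frame.columns and len(frame) and frame["phylum"].iloc[0]:
            name = frame["phylum"].iloc[0]
        else:
            name = os.path.basename(str(path)).removeprefix("sheet_").removesuffix(".csv")
        out[name] = frame
    return out


def reintegrate_sheets(
    sheets: dict[str, pd.DataFrame],
    original_summaries: Sequence[TaxonSummary],
) -> tuple[list[TaxonSummary], list[ResolutionRule]]:
    """Fold edited expert sheets back into the summary set.

    Renames (``preferredName`` differing from ``key``) are applied to the
    returned summaries *and* emitted as proposed resolution rules so the
    lens file — not the summaries — remains the durable memory of the
    change; a rename without a reason code is an error. ``authority`` and
    ``curationNote`` edits update summaries directly. Computed columns
    are ignored. Deleting or duplicating a key row fails, naming the
    sheet and the row.
    """
    by_key = {s.key: s for s in original_summaries}
    expected_sheets = {
        phylum: {s.key for s in group}
        for phylum, group in split_by_phylum(original_summaries).items()
    }

    seen_keys: set[str] = set()
    edited: dict[str, TaxonSummary] = {}
    proposals: list[ResolutionRule] = []

    for sheet_name, frame in sheets.items():
        if "key" not in frame.columns:
            raise CurationError(f"sheet {sheet_name!r}: key column missing")
        for pos, row in frame.iterrows():
            raw_key = str(row["key"])
            k = summary_key(raw_key)
            if k not in by_key:
                raise CurationError(
                    f"sheet {sheet_name!r} row {pos}: unknown key {raw_key!r}"
                )
            if k in seen_keys:
                raise CurationError(
                    f"sheet {sheet_name!r} row {pos}: duplicated key {raw_key!r}"
                )
            seen_keys.add(k)
            original = by_key[k]
            summary = replace(original)

            preferred = str(row.get("preferredName", raw_key)) or raw_key
            if preferred != original.resolvedName:
                reason = str(row.get("editReason", "")).strip()
                if reason not in RESOLUTION_REASONS:
                    raise CurationError(
                        f"sheet {sheet_name!r} row {pos}: rename "
                        f"{original.resolvedName!r} -> {preferred!r} requires a "
                        f"reason code from {RESOLUTION_REASONS}"
                    )
                proposals.append(
                    ResolutionRule(
                        reportedName=original.resolvedName,
                        preferredName=preferred,
                        reason=reason,
                        note=f"expert edit on sheet {sheet_name}",
                        addedBy="expert",
                    )
                )
                summary.resolvedName = preferred
                try:
                    summary.parsed = parse_scientific_name(preferred)
                    summary.genus = summary.parsed.genus
                except NameParseError:
                    summary.parsed = None
            if "authority" in frame.columns:
                summary.authority = str(row["authority"])
            if "curationNote" in frame.columns:
                summary.curationNote = str(row["curationNote"])
            edited[k] = summary

    missing = set(by_key) - seen_keys
    if missing:
        names = []
        for k in sorted(missing):
            sheet = next(
                (ph for ph, keys in expected_sheets.items() if k in keys), "?"
            )
            names.append(f"{by_key[k].resolvedName!r} (sheet {sheet!r})")
        raise CurationError(f"key rows deleted from sheets: {', '.join(names)}")

    # preserve the original summary order
    return [edited[s.key] for s in original_summaries], proposals


# --------------------------------------------------------------------------
# Diffing
# --------------------------------------------------------------------------

DIFF_KINDS = (
    "addedTaxon",
    "removedTaxon",
    "renamedTaxon",
    "changedAuthority",
    "changedNote",
)


@dataclass(frozen=True)
class DiffEntry:
    kind: str
    key: str
    before: str = ""
    after: str = ""
    sheet: str = ""


@dataclass
class DiffReport:
    """Semantic differences between two summary sets.

    Empty iff the two sets are semantically identical — row order and
    computed columns are ignored, so expert reordering never registers as
    a discrepancy.
    """

    entries: list[DiffEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def empty(self) -> bool:
        return not self.entries

    def to_csv(self, path_or_buf) -> None:
        _write_dict_csv(
            path_or_buf,
            ["kind", "key", "before", "after", "sheet"],
            (
                {
                    "kind": e.kind,
                    "key": e.key,
                    "before": e.before,
                    "after": e.after,
                    "sheet": e.sheet,
                }
                for e in self.entries
            ),
        )


def _fingerprint(s: TaxonSummary) -> tuple:
    return (
        tuple(sorted(s.reportingDatasetIDs)),
        s.recordCount,
        s.firstDate,
        s.lastDate,
    )


def diff_summaries(
    a: Sequence[TaxonSummary], b: Sequence[TaxonSummary]
) -> DiffReport:
    """Classify the semantic differences from summary set ``a`` to ``b``.

    Taxa present on only one side are first pair-matched by their record
    fingerprint (reporting datasets, count, date span): a unique mutual
    match is reported as one ``renamedTaxon``; the rest become
    ``addedTaxon``/``removedTaxon``. Taxa on both sides are compared on
    authority and curation note.
    """
    a_by_key = {s.key: s for s in a}
    b_by_key = {s.key: s for s in b}
    report = DiffReport()

    for k in a_by_key.keys() & b_by_key.keys():
        sa, sb = a_by_key[k], b_by_key[k]
        if sa.authority != sb.authority:
            report.entries.append(
                DiffEntry(
                    "changedAuthority", k, sa.authority, sb.authority,
                    sheet=sb.phylum or "incertae",
                )
            )
        if sa.curationNote != sb.curationNote:
            report.entries.append(
                DiffEntry(
                    "changedNote", k, sa.curationNote, sb.curationNote,
                    sheet=sb.phylum or "incertae",
                )
            )

    removed = [a_by_key[k] for k in sorted(a_by_key.keys() - b_by_key.keys())]
    added = [b_by_key[k] for k in sorted(b_by_key.keys() - a_by_key.keys())]

    removed_by_fp: dict[tuple, list[TaxonSummary]] = {}
    for s in removed:
        removed_by_fp.setdefault(_fingerprint(s), []).append(s)
    added_by_fp: dict[tuple, list[TaxonSummary]] = {}
    for s in added:
        added_by_fp.setdefault(_fingerprint(s), []).append(s)

    paired: set[str] = set()
    for fp, rem_group in removed_by_fp.items():
        add_group = added_by_fp.get(fp, [])
        if len(rem_group) == 1 and len(add_group) == 1:
            old, new = rem_group[0], add_group[0]
            report.entries.append(
                DiffEntry(
                    "renamedTaxon",
                    old.key,
                    old.resolvedName,
                    new.resolvedName,
                    sheet=new.phylum or "incertae",
                )
            )
            paired.update((old.key, new.key))

    for s in removed:
        if s.key not in paired:
            report.entries.append(
                DiffEntry(
                    "removedTaxon", s.key, s.resolvedName, "",
                    sheet=s.phylum or "incertae",
                )
            )
    for s in added:
        if s.key not in paired:
            report.entries.append(
                DiffEntry(
                    "addedTaxon", s.key, "", s.resolvedName,
                    sheet=s.phylum or "incertae",
                )
            )
    return report


# --------------------------------------------------------------------------
# Fixed-point driver
# --------------------------------------------------------------------------


class ConvergenceError(CurationError):
    """The curation loop cannot reach a fixed point.

    Raised when the iteration bound is exhausted with outstanding
    discrepancies, or when folding proposed resolutions would create a
    cycle in the lens table (an oscillating editor). Carries the residual
    diff so nothing fails silently.
    """

    def __init__(self, message: str, residual: DiffReport, history: list[DiffReport]):
        super().__init__(message)
        self.residual = residual
        self.history = history


@dataclass
class PipelineConfig:
    """Knobs of the fixed-point curation loop."""

    maxIterations: int = 10
    scope: ScopeConfig = field(default_factory=ScopeConfig)
    #: include coordinate-free records in the curated catalogue and
    #: summaries (historical specimens contribute taxa despite poor
    #: spatial resolution)
    includeCoordinateFree: bool = True

    def __post_init__(self):
        if self.maxIterations < 1:
            raise CurationError("maxIterations must be >= 1")


@dataclass
class PipelineResult:
    catalogue: Catalogue
    summaries: list[TaxonSummary]
    iterations: int
    history: list[DiffReport]
    resolutionTable: TaxonResolutionTable
    partition: tuple[int, int, int]  # (inside, outside, noCoordinates)
    excludedByScope: int


CurationFn = Callable[[dict[str, pd.DataFrame]], dict[str, pd.DataFrame]]


def _identity_curation(sheets: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    return sheets


def run_pipeline_once(
    master: Catalogue,
    table: TaxonResolutionTable,
    patches: GeoPatchTable,
    area: ProjectArea,
    backbone: TaxonomicBackbone,
    config: PipelineConfig,
) -> tuple[Catalogue, list[TaxonSummary], tuple[int, int, int], int]:
    """One resolve→filter→georef→summarise pass over the master catalogue."""
    resolved, _ = apply_taxon_resolution(master, table)
    kept, excluded = filter_taxa_of_interest(resolved, backbone, config.scope)
    promoted = Catalogue(promote_private_coordinates(r) for r in kept)
    patched, _ = apply_geo_patches(promoted, patches)
    inside, outside, nocoords = filter_by_area(patched, area)
    records = list(inside)
    if config.includeCoordinateFree:
        records.extend(nocoords)
    curated = Catalogue(records)
    summaries = summarize_taxa(curated, backbone)
    return curated, summaries, (len(inside), len(outside), len(nocoords)), len(excluded)


def run_to_fixed_point(
    sources: Sequence[SourceCatalogue],
    resolution_table: TaxonResolutionTable,
    patches: GeoPatchTable,
    area: ProjectArea,
    backbone: TaxonomicBackbone,
    config: Optional[PipelineConfig] = None,
    curation_fn: CurationFn = _identity_curation,
) -> PipelineResult:
    """Iterate the full pipeline until curation raises no discrepancies.

    Each pass re-runs resolution with the current lens table, rebuilds
    the summaries, hands the per-phylum sheets to ``curation_fn``,
    re-integrates the edits and diffs against the pass's own pre-curation
    summaries. Proposed resolutions are folded (appended) into the lens
    table — which only ever grows — and the loop repeats until a pass
    yields an empty diff and no proposals. Deterministic given fixed
    inputs and a deterministic curation function.

    Raises
    ------
    ConvergenceError
        If ``maxIterations`` passes still disagree, or folding proposals
        would create a cycle (an editor oscillating between two names).
    """
    config = config or PipelineConfig()
    master = merge_catalogues(sources)
    table = resolution_table
    history: list[DiffReport] = []
    # expert authority/note edits persist in the summary file between
    # passes; renames travel through the lens table instead
    overrides: dict[str, tuple[str, str]] = {}

    for iteration in range(1, config.maxIterations + 1):
        curated, summaries, partition, n_excluded = run_pipeline_once(
            master, table, patches, area, backbone, config
        )
        for s in summaries:
            if s.key in overrides:
                s.authority, s.curationNote = overrides[s.key]
        sheets = sheets_from_summaries(summaries)
        edited = curation_fn(sheets)
        summaries2, proposals = reintegrate_sheets(edited, summaries)
        diff = diff_summaries(summaries, summaries2)
        history.append(diff)
        for s in summaries2:
            overrides[s.key] = (s.authority, s.curationNote)

        if diff.empty and not proposals:
            return PipelineResult(
                catalogue=curated,
                summaries=summaries,
                iterations=iteration,
                history=history,
                resolutionTable=table,
                partition=partition,
                excludedByScope=n_excluded,
            )

        # fold proposals into the lens; skip rules it already contains
        existing = {(r.reportedName, r.preferredName) for r in table.rules}
        fresh = [
            p for p in proposals if (p.reportedName, p.preferredName) not in existing
        ]
        try:
            table = table.extend(fresh)
        except ResolutionError as exc:
            raise ConvergenceError(
                f"curation edits oscillate and cannot converge: {exc}",
                residual=diff,
                history=history,
            ) from exc

    raise ConvergenceError(
        f"no fixed point after {config.maxIterations} iterations; "
        f"{len(history[-1])} residual discrepancies",
        residual=history[-1],
        history=history,
    )


def summaries_to_csv(summaries: Sequence[TaxonSummary], path_or_buf) -> None:
    """Master summary file: one CSV row per curated taxon."""
    _write_dict_csv(
        path_or_buf,
        [
            "scientificName",
            "scientificNameAuthorship",
            "taxonRank",
            "phylum",
            "class",
            "order",
            "family",
            "genus",
            "reportingDatasetIDs",
            "reportingCategories",
            "recordCount",
            "firstDate",
            "lastDate",
            "curationNote",
            "validationStatus",
        ],
        (
            {
                "scientificName": s.resolvedName,
                "scientificNameAuthorship": s.authority,
                "taxonRank": s.taxonRank,
                "phylum": s.phylum,
                "class": s.taxonClass,
                "order": s.order,
                "family": s.family,
                "genus": s.genus,
                "reportingDatasetIDs": "|".join(sorted(s.reportingDatasetIDs)),
                "reportingCategories": "|".join(sorted(s.reportingCategories)),
                "recordCount": s.recordCount,
                "firstDate": s.firstDate,
                "lastDate": s.lastDate,
                "curationNote": s.curationNote,
                "validationStatus": s.validationStatus,
            }
            for s in summaries
        ),
    )
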