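"""Taxon resolution: the "swaps" lens file and backbone validation.

The taxon resolution table is the institutional memory of curation: a
human-authored mapping from reported names (typos, outdated concepts,
misidentifications) to preferred names, stored separately from the source
catalogues and re-applied whenever a source is refreshed. Rules match the
verbatim reported string first; if no verbatim rule fires, matching falls
back to the canonical key, so a rule written for ``Cuthona pustulata``
also resolves ``Cuthona  pustulata`` with stray whitespace. Chains of
rules (A→B plus B→C) are followed transitively to their terminal name; a
cycle is always a data error and is rejected when the table is loaded.

Applying the resolution is idempotent — resolution always recomputes from
the immutable ``reportedName``, so a second application changes nothing —
and fully logged: the :class:`ResolutionLog` can replay the exact same
changes onto a fresh copy of the master catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .datamodel import (
    AuthorityMatch,
    Catalogue,
    CurationError,
    NameParseError,
    TaxonomicBackbone,
    _read_dict_csv,
    _write_dict_csv,
    match_authority,
    name_key,
)

__all__ = [
    "ResolutionError",
    "RESOLUTION_REASONS",
    "ResolutionRule",
    "TaxonResolutionTable",
    "ResolutionLogEntry",
    "ResolutionLog",
    "apply_taxon_resolution",
    "replay_resolution_log",
    "ValidationReport",
    "validate_against_backbone",
]

RESOLUTION_REASONS = ("typo", "synonym", "conceptChange", "misidentification")

#: Longest rule chain followed before the table is presumed corrupt.
MAX_CHAIN_LENGTH = 20


class ResolutionError(CurationError):
    """The resolution table violates an invariant (cycle, self-map …)."""


@dataclass(frozen=True)
class ResolutionRule:
    """One curated name swap, with its reason code and provenance.

    ``datasetID`` optionally scopes the rule to a single source: a
    misidentification found in one catalogue is not evidence against
    another source's usage of the same name.
    """

    reportedName: str
    preferredName: str
    reason: str = "typo"
    note: str = ""
    addedBy: str = ""
    dateAdded: str = ""
    datasetID: str = ""


RESOLUTION_COLUMNS = [
    "reportedName",
    "preferredName",
    "reason",
    "note",
    "addedBy",
    "dateAdded",
    "datasetID",
]


class TaxonResolutionTable:
    """The taxon swaps lens: reported name → preferred name with reasons.

    Structural invariants are enforced at construction: reported names are
    unique per (table, datasetID scope), no rule maps a name to itself,
    and the directed graph reportedName→preferredName is acyclic. A cycle
    is reported with the offending name sequence.
    """

    def __init__(self, rules: Iterable[ResolutionRule] = ()):
        self.rules: list[ResolutionRule] = list(rules)
        # match indices: verbatim reported name and canonical key, each
        # holding the first applicable rule per datasetID scope
        self._verbatim: dict[tuple[str, str], ResolutionRule] = {}
        self._by_key: dict[tuple[str, str], ResolutionRule] = {}
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rule in self.rules:
            if rule.reason not in RESOLUTION_REASONS:
                raise ResolutionError(
                    f"rule {rule.reportedName!r}: unknown reason {rule.reason!r}"
                )
            pair = (rule.reportedName, rule.datasetID)
            if pair in seen:
                raise ResolutionError(
                    f"duplicate rule for reported name {rule.reportedName!r}"
                    + (f" scoped to {rule.datasetID!r}" if rule.datasetID else "")
                )
            seen.add(pair)
            if rule.reportedName == rule.preferredName:
                raise ResolutionError(
                    f"rule maps {rule.reportedName!r} to itself"
                )
            self._verbatim[pair] = rule
            try:
                self._by_key.setdefault((name_key(rule.reportedName), rule.datasetID), rule)
            except NameParseError:
                pass
        for rule in self.rules:
            self._walk(rule.reportedName, rule.datasetID)  # raises on a cycle

    def __len__(self) -> int:
        return len(self.rules)

    def extend(self, new_rules: Iterable[ResolutionRule]) -> "TaxonResolutionTable":
        """Return a new table with ``new_rules`` appended (lens grows, never
        shrinks)."""
        return TaxonResolutionTable([*self.rules, *new_rules])

    def _find_rule(self, name: str, datasetID: str) -> Optional[ResolutionRule]:
        # verbatim match first (dataset-scoped rules take precedence),
        # then canonical-key match
        for scope in (datasetID, "") if datasetID else ("",):
            rule = self._verbatim.get((name, scope))
            if rule is not None:
                return rule
        try:
            key = name_key(name)
        except NameParseError:
            return None
        for scope in (datasetID, "") if datasetID else ("",):
            rule = self._by_key.get((key, scope))
            if rule is not None:
                return rule
        return None

    def _walk(self, name: str, datasetID: str) -> tuple[str, list[ResolutionRule]]:
        """Follow the rule chain from ``name`` to its terminal name."""
        chain: list[str] = [name]
        fired: list[ResolutionRule] = []
        current = name
        while True:
            rule = self._find_rule(current, datasetID)
            if rule is None:
                return current, fired
            nxt = rule.preferredName
            if nxt in chain:
                cycle = chain[chain.index(nxt):] + [nxt]
                raise ResolutionError(
                    "cycle in taxon resolution table: " + " -> ".join(cycle)
                )
            chain.append(nxt)
            fired.append(rule)
            if len(fired) > MAX_CHAIN_LENGTH:
                raise ResolutionError(
                    f"resolution chain from {name!r} exceeds {MAX_CHAIN_LENGTH} "
                    "rules; suspected data error"
                )
            current = nxt

    def resolve(self, name: str, datasetID: str = "") -> tuple[str, list[ResolutionRule]]:
        """Terminal preferred name for ``name`` and the rules that fired."""
        return self._walk(name, datasetID)

    # -- CSV serialisation -------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        rows = [
            {
                "reportedName": r.reportedName,
                "preferredName": r.preferredName,
                "reason": r.reason,
                "note": r.note,
                "addedBy": r.addedBy,
                "dateAdded": r.dateAdded,
                "datasetID": r.datasetID,
            }
            for r in self.rules
        ]
        _write_dict_csv(path_or_buf, RESOLUTION_COLUMNS, rows)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TaxonResolutionTable":
        rows = _read_dict_csv(path_or_buf)
        return cls(
            ResolutionRule(
                reportedName=row["reportedName"],
                preferredName=row["preferredName"],
                reason=row.get("reason", "typo"),
                note=row.get("note", ""),
                addedBy=row.get("addedBy", ""),
                dateAdded=row.get("dateAdded", ""),
                datasetID=row.get("datasetID", "") or "",
            )
            for row in rows
        )


@dataclass(frozen=True)
class ResolutionLogEntry:
    occurrenceID: str
    datasetID: str
    reportedName: str
    resolvedName: str
    reason: str
    ruleRow: int


@dataclass
class ResolutionLog:
    """Ordered record of every name change one resolution pass made."""

    entries: list[ResolutionLogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def apply_taxon_resolution(
    master: Catalogue, table: TaxonResolutionTable
) -> tuple[Catalogue, ResolutionLog]:
    """Resolve every record's name through the lens table.

    Each record's ``resolvedName`` becomes the terminal name of the rule
    chain starting from its (immutable) ``reportedName``; records no rule
    touches get ``resolvedName = reportedName``. Idempotent: applying the
    operation to its own output changes nothing, because resolution always
    restarts from ``reportedName``. No record is ever added or dropped.
    """
    rule_index = {id(r): i for i, r in enumerate(table.rules)}
    out: list = []
    log = ResolutionLog()
    cache: dict[tuple[str, str], tuple[str, list[ResolutionRule]]] = {}
    for rec in master:
        new = rec.copy()
        cache_key = (rec.reportedName, rec.datasetID)
        if cache_key not in cache:
            cache[cache_key] = table.resolve(rec.reportedName, rec.datasetID)
        terminal, fired = cache[cache_key]
        if new.resolvedName != terminal:
            old = new.resolvedName
            new.resolvedName = terminal
            if terminal != rec.reportedName:
                last = fired[-1]
                new.log_change(
                    "taxon_resolution",
                    "resolvedName",
                    old or rec.reportedName,
                    terminal,
                    f"{last.reason}: {last.note}" if last.note else last.reason,
                )
                log.entries.append(
                    ResolutionLogEntry(
                        occurrenceID=rec.occurrenceID,
                        datasetID=rec.datasetID,
                        reportedName=rec.reportedName,
                        resolvedName=terminal,
                        reason=last.reason,
                        ruleRow=rule_index[id(last)],
                    )
                )
        out.append(new)
    return Catalogue(out), log


def replay_resolution_log(master: Catalogue, log: ResolutionLog) -> Catalogue:
    """Re-enact a recorded resolution pass on a fresh master copy.

    Reproduces ``apply_taxon_resolution``'s output exactly — the log is
    itself a re-applicable lens.
    """
    by_id = {(e.datasetID, e.occurrenceID): e for e in log.entries}
    out = []
    for rec in master:
        new = rec.copy()
        entry = by_id.get((rec.datasetID, rec.occurrenceID))
        if entry is not None:
            old = new.resolvedName
            new.resolvedName = entry.resolvedName
            new.log_change(
                "taxon_resolution",
                "resolvedName",
                old or rec.reportedName,
                entry.resolvedName,
                entry.reason,
            )
        elif not new.resolvedName:
            new.resolvedName = new.reportedName
        out.append(new)
    return Catalogue(out)


# --------------------------------------------------------------------------
# Backbone validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonValidation:
    resolvedName: str
    status: str  # accepted | synonymOfAccepted | unknown
    acceptedName: str = ""
    authorityCheck: AuthorityMatch = AuthorityMatch.MISSING


@dataclass
class ValidationReport:
    """Per-taxon classification against the backbone, for curator review.

    Unknown names are listed for action; nothing is auto-corrected.
    """

    results: list[TaxonValidation] = field(default_factory=list)

    @property
    def unknowns(self) -> list[TaxonValidation]:
        return [r for r in self.results if r.status == "unknown"]

    def to_csv(self, path_or_buf) -> None:
        _write_dict_csv(
            path_or_buf,
            ["resolvedName", "status", "acceptedName", "authorityCheck"],
            (
                {
                    "resolvedName": r.resolvedName,
                    "status": r.status,
                    "acceptedName": r.acceptedName,
                    "authorityCheck": r.authorityCheck.value,
                }
                for r in self.results
            ),
        )


def validate_against_backbone(
    names_with_authorities: Sequence[tuple[str, str]] | Catalogue,
    backbone: TaxonomicBackbone,
) -> ValidationReport:
    """Classify each resolved name as accepted, synonym or unknown.

    Accepts either a catalogue (distinct resolved names and their claimed
    authorities are extracted) or an explicit sequence of
    ``(resolvedName, claimedAuthority)`` pairs. The authority check uses
    :func:`dwclens.datamodel.match_authority` against the backbone entry.
    """
    if isinstance(names_with_authorities, Catalogue):
        pairs: dict[str, str] = {}
        for rec in names_with_authorities:
            name = rec.resolvedName or rec.reportedName
            pairs.setdefault(name, rec.authority)
        items = list(pairs.items())
    else:
        items = list(names_with_authorities)

    report = ValidationReport()
    for name, claimed in items:
        entry = backbone.lookup_accepted(name)
        if entry is not None:
            report.results.append(
                TaxonValidation(
                    resolvedName=name,
                    status="accepted",
                    acceptedName=entry.acceptedName,
                    authorityCheck=match_authority(claimed, entry.authority),
                )
            )
            continue
        syn = backbone.lookup_synonym(name)
        if syn is not None:
            report.results.append(
                TaxonValidation(
                    resolvedName=name,
                    status="synonymOfAccepted",
                    acceptedName=syn.acceptedName,
                    authorityCheck=match_authority(claimed, syn.authority),
                )
            )
            continue
        report.results.append(TaxonValidation(resolvedName=name, status="unknown"))
    return report
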