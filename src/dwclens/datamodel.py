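"""Core domain types shared by every pipeline stage.

This module defines the occurrence record (a Darwin Core field subset
carrying both the as-reported and the resolved scientific name plus a
provenance log of every modification), the parsed scientific name with its
identification qualifier, the taxonomic backbone (a local, WoRMS-like
reference table of accepted names, synonyms, authorities and
classification), and the three name-level primitives the rest of the
pipeline is built on:

* :func:`parse_scientific_name` — deterministic parsing of verbatim name
  strings, including qualifiers (``cf.``, ``aff.``, ``s. lat.``, ``sp.``,
  ``complex``), parenthesised subgenera and trailing authorships;
* :func:`canonical_key` — the normalised matching key used for all taxon
  identity decisions (authority excluded, qualifier retained: a qualified
  name is a distinct taxon);
* :func:`match_authority` — semi-automated validation of expert-supplied
  authorship strings against the backbone.

Verbatim strings are never mutated; normalisation applies to matching keys
only.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "CurationError",
    "NameParseError",
    "BackboneError",
    "Qualifier",
    "AuthorityMatch",
    "ParsedName",
    "parse_scientific_name",
    "render_name",
    "canonical_key",
    "normalize_key_text",
    "match_authority",
    "ModificationEntry",
    "OccurrenceRecord",
    "Catalogue",
    "BackboneEntry",
    "TaxonomicBackbone",
    "SOURCE_CATEGORIES",
]

#: The five source categories of occurrence data the pipeline integrates:
#: systematic dive surveys (``pmls``), museum voucher collections
#: (``collection``), crowd-sourced observations (``crowd``), ecological
#: survey data (``ecological``) and grey/scientific literature
#: (``literature``).
SOURCE_CATEGORIES = ("pmls", "collection", "crowd", "ecological", "literature")


class CurationError(Exception):
    """Base class for every error raised by this package."""


class NameParseError(CurationError):
    """A scientific-name string could not be parsed deterministically."""


class BackboneError(CurationError):
    """The taxonomic backbone violates one of its structural invariants."""


class Qualifier(str, Enum):
    """Identification hedges that make a name a distinct taxon.

    Qualified names (``Nereis cf. zonata``, ``Aequorea victoria s. lat.``)
    are counted as separate checklist entries from their unqualified
    binomials, so the qualifier participates in the canonical key.
    """

    NONE = "none"
    CF = "cf."
    AFF = "aff."
    S_LAT = "s. lat."
    SP = "sp."
    COMPLEX = "complex"


class AuthorityMatch(str, Enum):
    """Outcome of validating a claimed authorship against the backbone."""

    EXACT = "exact"
    NORMALIZED = "normalizedMatch"
    MISMATCH = "mismatch"
    MISSING = "missing"


# --------------------------------------------------------------------------
# Name normalisation
# --------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize_key_text(text: str) -> str:
    """Lowercase, strip diacritics via NFKD decomposition, collapse spaces."""
    return _WS_RE.sub(" ", _strip_diacritics(text).lower()).strip()


# --------------------------------------------------------------------------
# ParsedName
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParsedName:
    """Structured form of a scientific name string.

    ``subgenus`` preserves a parenthesised subgenus verbatim (as in
    ``Golfingia (Golfingia) vulgaris``); it is excluded from the canonical
    key. For informal provisional names (``Myxicola sp. A``) the designator
    is held in ``epithet`` alongside ``qualifier == Qualifier.SP``.
    """

    genus: str
    epithet: str = ""
    infraspecific_epithet: str = ""
    qualifier: Qualifier = Qualifier.NONE
    authority: str = ""
    subgenus: str = ""

    @property
    def canonical_key(self) -> str:
        return canonical_key(self)


_QUALIFIER_TOKENS = {
    "cf": Qualifier.CF,
    "cf.": Qualifier.CF,
    "aff": Qualifier.AFF,
    "aff.": Qualifier.AFF,
    "sp": Qualifier.SP,
    "sp.": Qualifier.SP,
    "complex": Qualifier.COMPLEX,
}

# rank markers preceding an infraspecific epithet; consumed, not stored
_RANK_MARKERS = {"var.", "var", "ssp.", "ssp", "subsp.", "subsp", "f.", "forma"}

_SUBGENUS_RE = re.compile(r"^\(([A-Z][^\s(),\d]+)\)$")
_DESIGNATOR_RE = re.compile(r"^[A-Z0-9]{1,3},?$")
_YEAR_RE = re.compile(r"\d{4}")


def parse_scientific_name(raw: str) -> ParsedName:
    """Parse a verbatim scientific-name string into its parts.

    Deterministic: the same input always yields the same ``ParsedName``.
    Qualifier tokens are recognised between genus and epithet and in
    trailing position. Parenthesised or trailing author-year strings are
    captured into ``authority`` untouched.

    Raises
    ------
    NameParseError
        If the string is empty after trimming or does not begin with a
        capitalised word. The parser never silently guesses.
    """
    text = _WS_RE.sub(" ", raw).strip()
    if not text:
        raise NameParseError("empty scientific name string")
    tokens = text.split(" ")
    genus = tokens[0]
    if not genus[0].isupper() or not genus.replace("-", "").isalpha():
        raise NameParseError(
            f"cannot parse {raw!r}: expected a leading capitalised genus word"
        )

    subgenus = ""
    epithet = ""
    infra = ""
    qualifier = Qualifier.NONE
    authority_tokens: list[str] = []

    i = 1
    # optional parenthesised subgenus immediately after the genus
    if i < len(tokens):
        m = _SUBGENUS_RE.match(tokens[i])
        if m:
            subgenus = m.group(1)
            i += 1

    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if authority_tokens:
            authority_tokens.append(tok)
        elif low in _QUALIFIER_TOKENS:
            qualifier = _QUALIFIER_TOKENS[low]
            if qualifier is Qualifier.SP and i + 1 < len(tokens):
                nxt = tokens[i + 1]
                if _DESIGNATOR_RE.match(nxt):
                    epithet = nxt.rstrip(",")
                    i += 1
        elif low == "s." and i + 1 < len(tokens) and tokens[i + 1].lower() in (
            "lat.",
            "lat",
            "l.",
        ):
            qualifier = Qualifier.S_LAT
            i += 1
        elif low == "s.l." or low == "s.lat.":
            qualifier = Qualifier.S_LAT
        elif low in _RANK_MARKERS:
            pass  # marker itself carries no identity; next token is the infra
        elif tok.startswith("("):
            authority_tokens.append(tok)
        elif tok[0].isupper() or _YEAR_RE.search(tok):
            # a capitalised word (or year) after the genus begins authorship
            authority_tokens.append(tok)
        elif tok.islower() or tok.replace("-", "").isalpha():
            if not epithet:
                epithet = tok
            elif not infra:
                infra = tok
            else:
                authority_tokens.append(tok)
        else:
            authority_tokens.append(tok)
        i += 1

    return ParsedName(
        genus=genus,
        epithet=epithet,
        infraspecific_epithet=infra,
        qualifier=qualifier,
        authority=" ".join(authority_tokens),
        subgenus=subgenus,
    )


def render_name(p: ParsedName, include_authority: bool = True) -> str:
    """Render a :class:`ParsedName` back to a conventional string.

    ``parse_scientific_name(render_name(p))`` reproduces ``p`` for every
    name the parser accepts (round-trip property).
    """
    parts = [p.genus]
    if p.subgenus:
        parts.append(f"({p.subgenus})")
    if p.qualifier in (Qualifier.CF, Qualifier.AFF):
        parts.append(p.qualifier.value)
    if p.qualifier is Qualifier.SP:
        parts.append("sp.")
        if p.epithet:
            parts.append(p.epithet)
    elif p.epithet:
        parts.append(p.epithet)
    if p.infraspecific_epithet:
        parts.append(p.infraspecific_epithet)
    if p.qualifier is Qualifier.S_LAT:
        parts.append("s. lat.")
    elif p.qualifier is Qualifier.COMPLEX:
        parts.append("complex")
    if include_authority and p.authority:
        parts.append(p.authority)
    return " ".join(parts)


_QUALIFIER_KEY_SUFFIX = {
    Qualifier.CF: "cf",
    Qualifier.AFF: "aff",
    Qualifier.S_LAT: "slat",
    Qualifier.SP: "sp",
    Qualifier.COMPLEX: "complex",
}


def canonical_key(p: ParsedName) -> str:
    """Normalised identity key for a parsed name.

    Lowercased, diacritics stripped, whitespace collapsed. The authority
    and any subgenus are excluded; the qualifier is retained as a trailing
    ``?token`` suffix so that qualified and unqualified forms of the same
    binomial key differently. Informal provisional designators key as
    ``genus sp-a``.
    """
    if p.qualifier is Qualifier.SP and p.epithet:
        base = f"{p.genus} sp-{p.epithet}"
        return normalize_key_text(base)
    parts = [p.genus]
    if p.epithet:
        parts.append(p.epithet)
    if p.infraspecific_epithet:
        parts.append(p.infraspecific_epithet)
    key = normalize_key_text(" ".join(parts))
    if p.qualifier is not Qualifier.NONE:
        key += "?" + _QUALIFIER_KEY_SUFFIX[p.qualifier]
    return key


def name_key(raw: str) -> str:
    """Canonical key straight from a verbatim name string."""
    return canonical_key(parse_scientific_name(raw))


# --------------------------------------------------------------------------
# Authority validation
# --------------------------------------------------------------------------

_PARENS_RE = re.compile(r"[()]")


def _normalize_authority(text: str) -> str:
    text = _PARENS_RE.sub("", _strip_diacritics(text))
    return re.sub(r"\s+", "", text)


def match_authority(claimed: str, backbone_authority: str) -> AuthorityMatch:
    """Validate a claimed authorship string against the backbone's.

    ``exact`` means byte-identical; ``normalizedMatch`` means identical
    once parentheses, diacritics and spacing differences are removed;
    an empty claim is ``missing``; anything else is a ``mismatch`` for a
    curator to review. Symmetric in whitespace on both sides.
    """
    if not claimed.strip():
        return AuthorityMatch.MISSING
    if claimed == backbone_authority:
        return AuthorityMatch.EXACT
    if _normalize_authority(claimed) == _normalize_authority(backbone_authority):
        return AuthorityMatch.NORMALIZED
    return AuthorityMatch.MISMATCH


# --------------------------------------------------------------------------
# Occurrence records and catalogues
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModificationEntry:
    """One provenance entry: which stage changed which field, and why."""

    stage: str
    field: str
    old_value: str
    new_value: str
    justification: str = ""


@dataclass
class OccurrenceRecord:
    """One observation or specimen in a Darwin Core field subset.

    Field names follow Darwin Core terms where one exists
    (``occurrenceID``, ``decimalLatitude`` …). ``reportedName`` is the
    verbatim name from the source catalogue and is never modified;
    ``resolvedName`` holds the preferred name once taxon resolution has
    run. Every change to the record after ingest is appended to
    ``modificationLog`` — the log is append-only within the forward
    pipeline and every ``reportedName``/``resolvedName`` difference has a
    corresponding entry.
    """

    occurrenceID: str
    datasetID: str
    sourceCategory: str = ""
    reportedName: str = ""
    resolvedName: str = ""
    taxonRank: str = ""
    phylum: str = ""
    taxonClass: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    authority: str = ""
    eventDate: str = ""
    decimalLatitude: Optional[float] = None
    decimalLongitude: Optional[float] = None
    privateLatitude: Optional[float] = None
    privateLongitude: Optional[float] = None
    coordinateNote: str = ""
    recordedBy: str = ""
    basisOfRecord: str = ""
    flags: list[str] = field(default_factory=list)
    verbatim: dict[str, str] = field(default_factory=dict)
    modificationLog: list[ModificationEntry] = field(default_factory=list)

    def log_change(
        self, stage: str, fieldname: str, old, new, justification: str = ""
    ) -> None:
        self.modificationLog.append(
            ModificationEntry(stage, fieldname, _fmt(old), _fmt(new), justification)
        )

    def validate(self) -> None:
        """Check coordinate-range invariants; raise naming the record."""
        for lat, lon, kind in (
            (self.decimalLatitude, self.decimalLongitude, "decimal"),
            (self.privateLatitude, self.privateLongitude, "private"),
        ):
            if lat is not None and not -90.0 <= lat <= 90.0:
                raise CurationError(
                    f"record {self.occurrenceID}: {kind} latitude {lat} out of [-90, 90]"
                )
            if lon is not None and not -180.0 <= lon <= 180.0:
                raise CurationError(
                    f"record {self.occurrenceID}: {kind} longitude {lon} out of [-180, 180]"
                )

    def copy(self) -> "OccurrenceRecord":
        new = replace(self)
        new.flags = list(self.flags)
        new.verbatim = dict(self.verbatim)
        new.modificationLog = list(self.modificationLog)
        return new


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


#: Column order of catalogue CSV exports; Darwin Core terms where defined.
CATALOGUE_COLUMNS = [
    "occurrenceID",
    "datasetID",
    "sourceCategory",
    "verbatimIdentification",  # reportedName
    "scientificName",  # resolvedName
    "taxonRank",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "scientificNameAuthorship",
    "eventDate",
    "decimalLatitude",
    "decimalLongitude",
    "coordinateNote",
    "recordedBy",
    "basisOfRecord",
    "flags",
]


class Catalogue:
    """An ordered collection of occurrence records.

    ``(datasetID, occurrenceID)`` is unique within a catalogue; record
    order is stable and meaningful (source row order within each dataset).
    """

    def __init__(self, records: Iterable[OccurrenceRecord] = ()):
        self.records: list[OccurrenceRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def copy(self) -> "Catalogue":
        return Catalogue(r.copy() for r in self.records)

    def index(self) -> dict[tuple[str, str], OccurrenceRecord]:
        return {(r.datasetID, r.occurrenceID): r for r in self.records}

    def check_unique_ids(self) -> None:
        seen: set[tuple[str, str]] = set()
        dupes: list[tuple[str, str]] = []
        for r in self.records:
            key = (r.datasetID, r.occurrenceID)
            if key in seen:
                dupes.append(key)
            seen.add(key)
        if dupes:
            raise CurationError(f"duplicate (datasetID, occurrenceID) pairs: {dupes}")

    # -- CSV serialisation -------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write the catalogue as UTF-8 RFC 4180 CSV with DwC term headers."""
        if hasattr(path_or_buf, "write"):
            self._write(path_or_buf)
        else:
            with open(path_or_buf, "w", newline="", encoding="utf-8") as fh:
                self._write(fh)

    def _write(self, fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CATALOGUE_COLUMNS)
        for r in self.records:
            writer.writerow(
                [
                    r.occurrenceID,
                    r.datasetID,
                    r.sourceCategory,
                    r.reportedName,
                    r.resolvedName,
                    r.taxonRank,
                    r.phylum,
                    r.taxonClass,
                    r.order,
                    r.family,
                    r.genus,
                    r.authority,
                    r.eventDate,
                    _fmt(r.decimalLatitude),
                    _fmt(r.decimalLongitude),
                    r.coordinateNote,
                    r.recordedBy,
                    r.basisOfRecord,
                    "|".join(r.flags),
                ]
            )

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self._write(buf)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path_or_buf) -> "Catalogue":
        if hasattr(path_or_buf, "read"):
            return cls._read(path_or_buf)
        with open(path_or_buf, newline="", encoding="utf-8") as fh:
            return cls._read(fh)

    @classmethod
    def _read(cls, fh) -> "Catalogue":
        reader = csv.DictReader(fh)
        records = []
        for row in reader:
            records.append(
                OccurrenceRecord(
                    occurrenceID=row.get("occurrenceID", ""),
                    datasetID=row.get("datasetID", ""),
                    sourceCategory=row.get("sourceCategory", ""),
                    reportedName=row.get("verbatimIdentification", ""),
                    resolvedName=row.get("scientificName", ""),
                    taxonRank=row.get("taxonRank", ""),
                    phylum=row.get("phylum", ""),
                    taxonClass=row.get("class", ""),
                    order=row.get("order", ""),
                    family=row.get("family", ""),
                    genus=row.get("genus", ""),
                    authority=row.get("scientificNameAuthorship", ""),
                    eventDate=row.get("eventDate", ""),
                    decimalLatitude=_parse_float(row.get("decimalLatitude", "")),
                    decimalLongitude=_parse_float(row.get("decimalLongitude", "")),
                    coordinateNote=row.get("coordinateNote", ""),
                    recordedBy=row.get("recordedBy", ""),
                    basisOfRecord=row.get("basisOfRecord", ""),
                    flags=[f for f in row.get("flags", "").split("|") if f],
                )
            )
        return cls(records)


def _parse_float(text: str) -> Optional[float]:
    text = (text or "").strip()
    return float(text) if text else None


# --------------------------------------------------------------------------
# Taxonomic backbone
# --------------------------------------------------------------------------

BACKBONE_COLUMNS = [
    "acceptedName",
    "authority",
    "rank",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "isMarine",
    "synonyms",
]


@dataclass(frozen=True)
class BackboneEntry:
    acceptedName: str
    authority: str = ""
    rank: str = "species"
    phylum: str = ""
    taxonClass: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    isMarine: bool = True
    synonyms: tuple[str, ...] = ()


class TaxonomicBackbone:
    """Local reference table of accepted names, synonyms and authorities.

    Plays the role WoRMS plays in practice: the authority against which
    resolved names and expert-supplied authorships are checked. Lookups
    match on the verbatim accepted name first, then on its canonical key,
    then on synonyms (verbatim, then canonical key).
    """

    def __init__(self, entries: Iterable[BackboneEntry]):
        self.entries: list[BackboneEntry] = list(entries)
        self._by_accepted: dict[str, BackboneEntry] = {}
        self._by_accepted_key: dict[str, BackboneEntry] = {}
        self._by_synonym: dict[str, BackboneEntry] = {}
        self._by_synonym_key: dict[str, BackboneEntry] = {}
        for e in self.entries:
            if e.acceptedName in self._by_accepted:
                raise BackboneError(f"duplicate accepted name: {e.acceptedName!r}")
            self._by_accepted[e.acceptedName] = e
            self._by_accepted_key.setdefault(name_key(e.acceptedName), e)
        for e in self.entries:
            for syn in e.synonyms:
                prev = self._by_synonym.get(syn)
                if prev is not None and prev is not e:
                    raise BackboneError(
                        f"synonym {syn!r} maps to both {prev.acceptedName!r} "
                        f"and {e.acceptedName!r}"
                    )
                self._by_synonym[syn] = e
                self._by_synonym_key.setdefault(name_key(syn), e)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_accepted(self, name: str) -> Optional[BackboneEntry]:
        entry = self._by_accepted.get(name)
        if entry is None:
            try:
                entry = self._by_accepted_key.get(name_key(name))
            except NameParseError:
                entry = None
        return entry

    def lookup_synonym(self, name: str) -> Optional[BackboneEntry]:
        entry = self._by_synonym.get(name)
        if entry is None:
            try:
                entry = self._by_synonym_key.get(name_key(name))
            except NameParseError:
                entry = None
        return entry

    def lookup(self, name: str) -> Optional[BackboneEntry]:
        """Accepted-name match first, falling back to synonym match."""
        return self.lookup_accepted(name) or self.lookup_synonym(name)

    # -- CSV serialisation -------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        rows = [
            {
                "acceptedName": e.acceptedName,
                "authority": e.authority,
                "rank": e.rank,
                "phylum": e.phylum,
                "class": e.taxonClass,
                "order": e.order,
                "family": e.family,
                "genus": e.genus,
                "isMarine": "true" if e.isMarine else "false",
                "synonyms": "|".join(e.synonyms),
            }
            for e in self.entries
        ]
        _write_dict_csv(path_or_buf, BACKBONE_COLUMNS, rows)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TaxonomicBackbone":
        rows = _read_dict_csv(path_or_buf)
        entries = [
            BackboneEntry(
                acceptedName=row["acceptedName"],
                authority=row.get("authority", ""),
                rank=row.get("rank", "species"),
                phylum=row.get("phylum", ""),
                taxonClass=row.get("class", ""),
                order=row.get("order", ""),
                family=row.get("family", ""),
                genus=row.get("genus", ""),
                isMarine=row.get("isMarine", "true").strip().lower()
                in ("true", "1", "yes"),
                synonyms=tuple(s for s in row.get("synonyms", "").split("|") if s),
            )
            for row in rows
        ]
        return cls(entries)


# --------------------------------------------------------------------------
# small CSV helpers used by several modules
# --------------------------------------------------------------------------


def _write_dict_csv(path_or_buf, columns: Sequence[str], rows: Iterable[dict]) -> None:
    def write(fh):
        writer = csv.DictWriter(fh, fieldnames=list(columns), lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)

    if hasattr(path_or_buf, "write"):
        write(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="", encoding="utf-8") as fh:
            write(fh)


def _read_dict_csv(path_or_buf) -> list[dict]:
    if hasattr(path_or_buf, "read"):
        return list(csv.DictReader(path_or_buf))
    with open(path_or_buf, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))
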