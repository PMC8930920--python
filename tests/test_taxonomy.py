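"""Taxon-resolution lens: chains, idempotence, logging, validation."""

import numpy as np
import pytest

from dwclens import (
    Catalogue,
    ResolutionError,
    ResolutionRule,
    TaxonResolutionTable,
    apply_taxon_resolution,
    replay_resolution_log,
    validate_against_backbone,
)
from dwclens.taxonomy import MAX_CHAIN_LENGTH
from conftest import make_record


def table_of(*pairs, **kw):
    return TaxonResolutionTable(
        ResolutionRule(reportedName=a, preferredName=b, reason=kw.get("reason", "typo"))
        for a, b in pairs
    )


@pytest.mark.parametrize(
    "reported, rule, expected",
    [
        ("Cuthona pustulata", ("Cuthona pustulata", "Zelentia pustulata"),
         "Zelentia pustulata"),
        ("Urticina crassicornis", ("Urticina crassicornis", "Urticina grebelnyi"),
         "Urticina grebelnyi"),
    ],
)
def test_single_rule_resolution(reported, rule, expected):
    master = Catalogue([make_record("r1", name=reported)])
    resolved, log = apply_taxon_resolution(master, table_of(rule))
    assert resolved.records[0].resolvedName == expected
    assert resolved.records[0].reportedName == reported  # verbatim preserved
    assert len(log) == 1
    assert resolved.records[0].modificationLog[-1].field == "resolvedName"


def test_transitive_chain_and_idempotence():
    table = table_of(("A a", "B b"), ("B b", "C c"))
    master = Catalogue([make_record("r1", name="A a")])
    once, log1 = apply_taxon_resolution(master, table)
    assert once.records[0].resolvedName == "C c"
    twice, log2 = apply_taxon_resolution(once, table)
    assert twice.records[0].resolvedName == "C c"
    assert len(log2) == 0  # second application is a no-op
    assert [r.modificationLog for r in twice] == [r.modificationLog for r in once]


def test_untouched_records_get_reported_name():
    master = Catalogue([make_record("r1", name="Zelentia punicea")])
    resolved, log = apply_taxon_resolution(master, table_of(("X x", "Y y")))
    assert resolved.records[0].resolvedName == "Zelentia punicea"
    assert len(log) == 0 and not resolved.records[0].modificationLog


def test_cycle_rejected_at_load():
    with pytest.raises(ResolutionError, match="cycle"):
        table_of(("A a", "B b"), ("B b", "A a"))
    with pytest.raises(ResolutionError, match="itself"):
        table_of(("A a", "A a"))


def test_chain_length_bound():
    names = [f"Genus sp{i}a" for i in range(MAX_CHAIN_LENGTH + 3)]
    with pytest.raises(ResolutionError, match="exceeds"):
        table_of(*zip(names[:-1], names[1:]))


def test_canonical_key_fallback_matching():
    """A rule written with odd spacing still fires on the key level."""
    table = table_of(("Cuthona  pustulata", "Zelentia pustulata"))
    master = Catalogue([make_record("r1", name="Cuthona pustulata")])
    resolved, _ = apply_taxon_resolution(master, table)
    assert resolved.records[0].resolvedName == "Zelentia pustulata"


def test_dataset_scoped_misidentification_rule():
    table = TaxonResolutionTable(
        [ResolutionRule("Urticina crassicornis", "Urticina grebelnyi",
                        reason="misidentification", datasetID="dives")]
    )
    master = Catalogue(
        [make_record("r1", dataset="dives", name="Urticina crassicornis"),
         make_record("r2", dataset="museum", name="Urticina crassicornis")]
    )
    resolved, _ = apply_taxon_resolution(master, table)
    assert resolved.records[0].resolvedName == "Urticina grebelnyi"
    assert resolved.records[1].resolvedName == "Urticina crassicornis"


def test_resolution_log_replay_reproduces_output():
    table = table_of(("A a", "B b"), ("B b", "C c"), ("D d", "E e"))
    master = Catalogue(
        [make_record("r1", name="A a"), make_record("r2", name="D d"),
         make_record("r3", name="F f")]
    )
    resolved, log = apply_taxon_resolution(master, table)
    replayed = replay_resolution_log(master, log)
    assert [r.resolvedName for r in replayed] == [r.resolvedName for r in resolved]
    assert replayed.to_csv_string() == resolved.to_csv_string()


def _brute_force_resolve(name, rules):
    """Exhaustive chain walking, independent of the table implementation."""
    mapping = {r.reportedName: r.preferredName for r in rules}
    seen = set()
    while name in mapping and name not in seen:
        seen.add(name)
        name = mapping[name]
    return name


@pytest.mark.parametrize("seed", range(5))
def test_agrees_with_brute_force_oracle_on_random_acyclic_tables(seed):
    rng = np.random.default_rng(seed)
    n_names = 300
    names = [f"Genus{i} sp{i}a" for i in range(n_names)]
    # acyclic by construction: rules always point to a later name
    sources = rng.choice(n_names - 1, size=200, replace=False)
    rules = []
    for i in sorted(sources):
        j = int(rng.integers(i + 1, n_names))
        rules.append(ResolutionRule(names[i], names[j], reason="synonym"))
    table = TaxonResolutionTable(rules)
    master = Catalogue(
        [make_record(f"r{k}", name=names[int(rng.integers(0, n_names))])
         for k in range(150)]
    )
    resolved, _ = apply_taxon_resolution(master, table)
    for before, after in zip(master, resolved):
        assert after.resolvedName == _brute_force_resolve(before.reportedName, rules)


def test_no_record_loss(default_bundle):
    from dwclens import merge_catalogues

    master = merge_catalogues(default_bundle.sources)
    resolved, _ = apply_taxon_resolution(master, default_bundle.resolutionTable)
    assert len(resolved) == len(master)
    assert [r.occurrenceID for r in resolved] == [r.occurrenceID for r in master]


def test_validate_against_backbone(small_backbone):
    report = validate_against_backbone(
        [
            ("Zelentia punicea", "(Korshunova, Fletcher, Lodin, Picton & Martynov, 2018)"),
            ("Cuthona punicea", ""),
            ("Ignotus ignotus", "Nobody, 1900"),
        ],
        small_backbone,
    )
    by_name = {r.resolvedName: r for r in report.results}
    assert by_name["Zelentia punicea"].status == "accepted"
    assert by_name["Zelentia punicea"].authorityCheck.value == "exact"
    assert by_name["Cuthona punicea"].status == "synonymOfAccepted"
    assert by_name["Cuthona punicea"].acceptedName == "Zelentia punicea"
    assert by_name["Ignotus ignotus"].status == "unknown"
    assert [r.resolvedName for r in report.unknowns] == ["Ignotus ignotus"]


def test_table_csv_roundtrip(tmp_path):
    table = TaxonResolutionTable(
        [ResolutionRule("Cuthona pustulata", "Zelentia pustulata", reason="conceptChange",
                        note="genus split, see review", addedBy="curator",
                        dateAdded="2020-01-01", datasetID="dives")]
    )
    path = tmp_path / "resolution.csv"
    table.to_csv(path)
    again = TaxonResolutionTable.from_csv(path)
    assert again.rules == table.rules
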