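"""Summaries, expert-sheet round-trip, diffing, and the fixed-point loop."""

import numpy as np
import pytest

from dwclens import (
    Catalogue,
    ConvergenceError,
    CurationError,
    PipelineConfig,
    diff_summaries,
    reintegrate_sheets,
    run_to_fixed_point,
    sheets_from_summaries,
    split_by_phylum,
    summarize_taxa,
)
from dwclens.curation import read_sheets, write_sheets
from conftest import make_record


def _catalogue_10_records_4_taxa():
    spec = [
        ("Aequorea victoria", "ds1", "pmls", "2001-05-04", 4),
        ("Nereis zonata", "ds1", "pmls", "2003-07-01", 3),
        ("Nereis zonata", "ds2", "crowd", "2019-08-15", 1),
        ("Barentsia sp.", "ds2", "crowd", "1998", 1),
        ("Zelentia punicea", "ds1", "pmls", "2010-01-02", 1),
    ]
    records, i = [], 0
    for name, ds, cat, date, n in spec:
        for _ in range(n):
            records.append(
                make_record(f"r{i}", dataset=ds, category=cat, name=name,
                            eventDate=date)
            )
            i += 1
    cat = Catalogue(records)
    for r in cat:
        r.resolvedName = r.reportedName
    return cat


def test_summarize_counts_and_grouping():
    master = _catalogue_10_records_4_taxa()
    summaries = summarize_taxa(master)
    assert len(summaries) == 4
    assert sum(s.recordCount for s in summaries) == len(master) == 10
    nereis = next(s for s in summaries if s.resolvedName == "Nereis zonata")
    assert nereis.reportingDatasetIDs == {"ds1", "ds2"}
    assert nereis.reportingCategories == {"pmls", "crowd"}
    assert nereis.firstDate == "2003-07-01" and nereis.lastDate == "2019-08-15"


def test_summarize_single_record():
    master = Catalogue([make_record("r1", name="Aequorea victoria",
                                    eventDate="2020-01-01")])
    master.records[0].resolvedName = master.records[0].reportedName
    (s,) = summarize_taxa(master)
    assert s.firstDate == s.lastDate == "2020-01-01"
    assert s.recordCount == 1


def _summaries_with_phyla(phyla):
    records = [
        make_record(f"r{i}", name=f"Genus{'abcdefghijklmnopqrst'[i]} species",
                    phylum=ph)
        for i, ph in enumerate(phyla)
    ]
    master = Catalogue(records)
    for r in master:
        r.resolvedName = r.reportedName
    return summarize_taxa(master)


def test_split_by_phylum_partition():
    summaries = _summaries_with_phyla(["Porifera", "Cnidaria", "Mollusca",
                                       "Mollusca", ""])
    sheets = split_by_phylum(summaries)
    assert set(sheets) == {"Porifera", "Cnidaria", "Mollusca", "incertae"}
    assert sum(len(v) for v in sheets.values()) == len(summaries)


def test_split_nineteen_groups_in_miniature():
    phyla = [f"Phylum{chr(65 + i)}" for i in range(19)]
    sheets = split_by_phylum(_summaries_with_phyla(phyla))
    assert len(sheets) == 19
    assert all(len(v) == 1 for v in sheets.values())


def test_sheet_roundtrip_identity_with_utf8_and_commas(tmp_path):
    master = Catalogue(
        [make_record("r1", name="Sérpula columbiana", phylum="Annelida"),
         make_record("r2", name="Aequorea victoria", phylum="Cnidaria")]
    )
    for r in master:
        r.resolvedName = r.reportedName
    summaries = summarize_taxa(master)
    summaries[0].curationNote = 'split from "S. vermicularis", see Kupriyanova, 1999'
    summaries[0].authority = "Møller, 1776"
    sheets = sheets_from_summaries(summaries)
    write_sheets(sheets, tmp_path)
    back = read_sheets(sorted(tmp_path.glob("sheet_*.csv")))
    summaries2, proposals = reintegrate_sheets(back, summaries)
    assert proposals == []
    assert diff_summaries(summaries, summaries2).empty
    assert summaries2[0].curationNote == summaries[0].curationNote
    assert summaries2[0].authority == "Møller, 1776"


def test_reintegrate_rename_produces_proposal():
    summaries = _summaries_with_phyla(["Mollusca"])
    summaries[0].resolvedName = "Cadlina luteomarginata"
    sheets = sheets_from_summaries(summaries)
    frame = sheets["Mollusca"]
    frame.loc[0, "key"] = "Cadlina luteomarginata"
    frame.loc[0, "preferredName"] = "Cadlina klasmalmbergi"
    frame.loc[0, "editReason"] = "conceptChange"
    summaries2, proposals = reintegrate_sheets(sheets, summaries)
    assert len(proposals) == 1
    assert proposals[0].reportedName == "Cadlina luteomarginata"
    assert proposals[0].preferredName == "Cadlina klasmalmbergi"
    assert proposals[0].reason == "conceptChange"
    assert summaries2[0].resolvedName == "Cadlina klasmalmbergi"


def test_reintegrate_rename_without_reason_fails():
    summaries = _summaries_with_phyla(["Mollusca"])
    sheets = sheets_from_summaries(summaries)
    sheets["Mollusca"].loc[0, "preferredName"] = "Other thing"
    with pytest.raises(CurationError, match="reason"):
        reintegrate_sheets(sheets, summaries)


def test_reintegrate_detects_deleted_and_duplicated_keys():
    summaries = _summaries_with_phyla(["Mollusca", "Mollusca"])
    sheets = sheets_from_summaries(summaries)
    dropped = {"Mollusca": sheets["Mollusca"].iloc[:1]}
    with pytest.raises(CurationError, match="deleted"):
        reintegrate_sheets(dropped, summaries)
    import pandas as pd

    doubled = {"Mollusca": pd.concat([sheets["Mollusca"]] * 2, ignore_index=True)}
    with pytest.raises(CurationError, match="duplicated"):
        reintegrate_sheets(doubled, summaries)


def test_reintegrate_ignores_computed_column_edits():
    summaries = _summaries_with_phyla(["Mollusca"])
    sheets = sheets_from_summaries(summaries)
    sheets["Mollusca"].loc[0, "recordCount"] = 999
    summaries2, proposals = reintegrate_sheets(sheets, summaries)
    assert proposals == []
    assert diff_summaries(summaries, summaries2).empty
    assert summaries2[0].recordCount == summaries[0].recordCount


def test_diff_identity_and_rename():
    a = _summaries_with_phyla(["Mollusca", "Cnidaria", "Porifera"])
    assert diff_summaries(a, a).empty
    import copy

    b = copy.deepcopy(a)
    b[1].resolvedName = "Renamed thing"
    report = diff_summaries(a, b)
    assert len(report) == 1
    assert report.entries[0].kind == "renamedTaxon"
    assert report.entries[0].after == "Renamed thing"


def test_diff_matches_edit_script():
    """k known edits produce exactly k diff entries of the right kinds."""
    import copy

    rng = np.random.default_rng(5)
    names = [f"Genus{chr(97 + i)} thing{chr(97 + i)}" for i in range(12)]
    records = [
        make_record(f"r{i}", name=n, phylum="Mollusca",
                    eventDate=f"20{10 + i:02d}-01-01")
        for i, n in enumerate(names)
    ]
    master = Catalogue(records)
    for r in master:
        r.resolvedName = r.reportedName
    a = summarize_taxa(master)
    b = copy.deepcopy(a)
    edits = []
    idx = rng.permutation(len(b))
    b[idx[0]].resolvedName = "Novus nominus"
    edits.append("renamedTaxon")
    b[idx[1]].authority = "Someone, 1901"
    edits.append("changedAuthority")
    b[idx[2]].curationNote = "checked against type material"
    edits.append("changedNote")
    del b[int(idx[3])]
    edits.append("removedTaxon")
    report = diff_summaries(a, b)
    assert sorted(e.kind for e in report.entries) == sorted(edits)


# -- fixed point ------------------------------------------------------------


def test_fixed_point_converges_immediately_without_edits(default_bundle):
    result = run_to_fixed_point(
        default_bundle.sources,
        default_bundle.resolutionTable,
        default_bundle.patchTable,
        default_bundle.area,
        default_bundle.backbone,
    )
    assert result.iterations == 1
    assert len(result.history) == 1 and result.history[0].empty


def test_fixed_point_single_rename_converges_in_two(default_bundle):
    target = default_bundle.truth.expectedTaxonNames[0]

    def editor(sheets):
        for frame in sheets.values():
            hit = frame["key"] == target
            if hit.any():
                frame.loc[hit, "preferredName"] = "Correctus nominus"
                frame.loc[hit, "editReason"] = "conceptChange"
        return sheets

    result = run_to_fixed_point(
        default_bundle.sources,
        default_bundle.resolutionTable,
        default_bundle.patchTable,
        default_bundle.area,
        default_bundle.backbone,
        curation_fn=editor,
    )
    assert result.iterations == 2
    assert not result.history[0].empty and result.history[1].empty
    names = {s.resolvedName for s in result.summaries}
    assert "Correctus nominus" in names and target not in names
    # the lens grew: the proposal is now a durable rule
    assert any(
        r.reportedName == target and r.preferredName == "Correctus nominus"
        for r in result.resolutionTable.rules
    )
    # one extra pass after convergence stays converged
    again = run_to_fixed_point(
        default_bundle.sources,
        result.resolutionTable,
        default_bundle.patchTable,
        default_bundle.area,
        default_bundle.backbone,
    )
    assert again.iterations == 1


def test_fixed_point_alternating_editor_fails_loudly(default_bundle):
    target = default_bundle.truth.expectedTaxonNames[0]

    def oscillator(sheets):
        for frame in sheets.values():
            for name, other in ((target, "Alternatus nominus"),
                                ("Alternatus nominus", target)):
                hit = frame["key"] == name
                if hit.any():
                    frame.loc[hit, "preferredName"] = other
                    frame.loc[hit, "editReason"] = "conceptChange"
        return sheets

    with pytest.raises(ConvergenceError) as exc:
        run_to_fixed_point(
            default_bundle.sources,
            default_bundle.resolutionTable,
            default_bundle.patchTable,
            default_bundle.area,
            default_bundle.backbone,
            PipelineConfig(maxIterations=6),
            curation_fn=oscillator,
        )
    assert not exc.value.residual.empty


def test_fixed_point_respects_iteration_bound(default_bundle):
    """An editor inventing a new name every pass exhausts maxIterations."""
    counter = {"n": 0}

    def restless(sheets):
        counter["n"] += 1
        for frame in sheets.values():
            if len(frame):
                frame.loc[0, "preferredName"] = f"Novus nominus{counter['n']}a"
                frame.loc[0, "editReason"] = "conceptChange"
                break
        return sheets

    with pytest.raises(ConvergenceError, match="no fixed point"):
        run_to_fixed_point(
            default_bundle.sources,
            default_bundle.resolutionTable,
            default_bundle.patchTable,
            default_bundle.area,
            default_bundle.backbone,
            PipelineConfig(maxIterations=3),
            curation_fn=restless,
        )


def test_record_counts_conserved_every_pass(default_bundle):
    result = run_to_fixed_point(
        default_bundle.sources,
        default_bundle.resolutionTable,
        default_bundle.patchTable,
        default_bundle.area,
        default_bundle.backbone,
    )
    assert sum(s.recordCount for s in result.summaries) == len(result.catalogue)
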