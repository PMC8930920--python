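# dwclens

Reversible, lens-based curation of multi-source Darwin Core occurrence
catalogues — for biodiversity informaticians and community-science
projects that integrate heterogeneous species-occurrence data (dive logs,
museum voucher exports, crowd-sourced observations, ecological surveys,
literature records) into a single expert-curated checklist.

## The problem and the approach

Merging occurrence catalogues from many contributors is mostly a
data-cleaning problem: every source has its own column vocabulary, its
own typos and outdated taxon concepts, and its own georeferencing
quirks — and most sources (museum databases, third-party platforms)
cannot be edited in place. `dwclens` therefore never modifies a source
catalogue. Every correction lives in a separate, re-applicable *lens*:

* a **taxon resolution table** ("swaps file") mapping reported names to
  preferred names with a reason code (`typo`, `synonym`, `conceptChange`,
  `misidentification`) — the institutional memory of curation, followed
  transitively (A→B plus B→C resolves A to C) and rejected if cyclic;
* a **georeferencing patch table** of record-keyed coordinate corrections
  with mandatory justification notes, which can be applied, re-applied
  (idempotently) and inverted exactly.

The pipeline maps each source's columns onto a Darwin Core field subset,
stamps dataset IDs, merges everything into a master catalogue, filters to
the taxa of interest against a local WoRMS-like taxonomic backbone,
promotes private/obscured coordinates, applies the patch lens, filters
records to the project-area polygon, and condenses the result into one
summary row per taxon. Summaries are split into per-phylum CSV sheets for
subject-matter experts; edited sheets are re-integrated, name edits
become *proposed* resolution rules, and the whole pipeline re-runs with
the grown lens until a pass produces no further discrepancies — the
curated checklist is a fixed point of the loop.

Taxon identity uses a canonical key: lowercase, diacritics stripped,
authority excluded, identification qualifiers retained (`Nereis cf.
zonata` is a distinct checklist entry from `Nereis zonata`).

A contribution analysis then quantifies what each source category adds:
per-category records and taxa, *exclusive* (novel) reports — taxa
reported by exactly one category — versus shared taxa, grouped novelty
percentages, and records-per-novel-report ratios (the `n` in `1:n`),
all rounded half away from zero.

## Worked example

The built-in generator manufactures a realistic five-source study
(~2,000 records, 67 taxa, injected typos and coordinate errors matched
by known lens tables) and the CLI runs it end to end:

```bash
curator fixtures --out fx --seed 7
# wrote 5 source catalogues (2002 records, 67 taxa) to fx

curator run --sources fx --resolution fx/resolution.csv \
    --patches fx/patches.csv --area fx/area.geojson \
    --backbone fx/backbone.csv --out out
# converged in 1 iteration(s): 1962 records, 67 taxa
#   (partition inside=1885 outside=40 noCoordinates=77)

curator stats --summaries out/summary.csv --catalogue out/catalogue.csv
# {"PMLS": 59, "Collections": 20, "Crowd": 17, "Other": 5}
# {"PMLS": 66, "Collections": 3, "Crowd": 39, "Other": 41}
# taxa=67 shared=26 records=1962
```

Reading the output: the loop converged in one pass (the supplied lens
tables already resolve every injected error); 40 records fell outside
the project polygon and 77 lacked coordinates (kept in a review bucket);
of the 67 taxa, 26 are shared between source categories; dive surveys
(PMLS) contribute 59 % of the novel taxon reports but need 66 records
per novel report, while museum collections contribute 20 % of novelty at
only 3 records per novel report — the complementarity the analysis is
designed to expose.

The same workflow is available as a library; see `dwclens.run_to_fixed_point`,
`dwclens.compute_contribution_stats` and `dwclens.generate_fixture`.

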