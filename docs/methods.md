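# Methods

## Pipeline model

`dwclens` treats multi-source occurrence curation as a fixed-point
computation over immutable sources. Let `S₁…Sₖ` be source catalogues,
`R` the taxon-resolution table and `P` the georeferencing patch table.
One pass computes

```
master   = merge(map_columns(S₁)…map_columns(Sₖ))
resolved = R*(master)                  # transitive closure of the lens
kept     = scope_filter(resolved, B)   # backbone B, positive evidence
geo      = area_filter(patch_P(promote_private(kept)))
summary  = summarize(geo)              # one row per canonical key
```

and the curation loop is `summaryₙ → expert edits → proposals → R ← R ∪
proposals`, iterated until a pass yields an empty semantic diff and no
proposals. Because `R` only grows and every pass recomputes from the
unmodified sources, the loop is deterministic given fixed inputs and a
deterministic curation function, and a converged state stays converged
(an extra pass is a no-op).

Key modelling assumptions:

* **Sources are read-only.** All corrections are lenses stored beside
  the data; re-running the pipeline on refreshed sources re-applies
  them. A patch targeting a record that no longer exists fails loudly —
  surfacing upstream drift is the point of the design.
* **Taxon identity is the canonical key**: NFKD-decomposed,
  diacritic-stripped, lowercased, whitespace-collapsed; authorship and
  parenthesised subgenera excluded; identification qualifiers (`cf.`,
  `aff.`, `s. lat.`, `sp.`, `complex`) retained as a `?qualifier`
  suffix, so qualified names are distinct taxa for all counting.
  Informal provisional names (`Myxicola sp. A`) key as `myxicola sp-a`;
  a bare `Genus sp.` keys as `genus?sp`. Verbatim strings are preserved
  everywhere; normalisation exists only in keys.
* **Authorities are validated, never matched on.** The check against the
  backbone yields exact / normalizedMatch (parentheses, diacritics and
  spacing ignored) / mismatch / missing, for curator review.
* **Exclusivity is category-level.** A "novel report" is a taxon whose
  reporting source categories are exactly one of {pmls, collection,
  crowd, ecological, literature}; taxa in ≥ 2 categories are shared. A
  per-dataset breakdown is reported alongside, since the two readings
  can differ when a category contains several catalogues.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `PipelineConfig.maxIterations` | 10 | curation-loop bound; exhaustion raises with the residual diff, never loops silently |
| `PipelineConfig.includeCoordinateFree` | true | coordinate-free records stay in the curated catalogue: historical specimens contribute taxa despite poor spatial resolution |
| `ScopeConfig.requireMarine` | true | scope filter excludes only on positive backbone evidence; unknown names are kept and flagged `unresolved` |
| `MAX_CHAIN_LENGTH` (taxonomy) | 20 | resolution chains longer than this indicate a corrupt table |
| rounding | half away from zero | used for novelty percentages and `1:n` ratios; reproduces half-way cases such as 852/13 = 65.5 → 66 |

Display grouping for percentages and ratios: dive surveys (PMLS),
collections and crowd-sourced data stand alone; ecological-survey and
literature records are combined into "Other" — only that combination
makes the small-source numbers meaningful as a group.

## Geometry

The project-area test is planar on raw WGS84 decimal degrees via
shapely (`covers`, so boundary points — shorelines — count as inside).
At island scale (~0.2° extent) the planar approximation is far below
coordinate uncertainty; no projection keeps the test deterministic and
auditable. Geodesic membership and uncertainty buffering are out of
scope. Degenerate rings (< 3 distinct vertices) are rejected at load.

## Reversibility and provenance

Every record carries an append-only modification log through the
forward pipeline (resolution, promotion, patching, filtering each add
entries). `invert_geo_patches` is the exact inverse of
`apply_geo_patches`: it restores pre-patch coordinates *and* removes the
patch-stage log entries it reverts, so apply-then-invert is
byte-identical — the patch log, not the record, is the durable memory of
the change. Applying the same patch table twice equals applying it once
(already-patched records are skipped unlogged).

Resolution always recomputes from the immutable `reportedName`, which
makes it idempotent by construction; the resolution log can replay a
pass onto a fresh catalogue copy exactly. Rules match the verbatim
reported string first and fall back to the canonical key, so one rule
corrects both a specific typo and trivially-variant spellings; a rule
may be scoped to a dataset (a misidentification in one source is not
evidence against another source's usage).

## Convergence and its failure modes

Convergence requires an empty semantic diff (row order and computed
sheet columns ignored) *and* no outstanding rename proposals. Expert
authority/note edits persist in the summary store between passes;
renames travel only through the lens table. Two failure modes raise
`ConvergenceError` carrying the residual diff and full history: the
iteration bound is exhausted, or folding proposals would create a cycle
in the resolution table — the signature of an editor oscillating between
two names, detected as early as possible since the table itself never
accepts a cyclic state. Rename detection in the diff pairs
removed/added taxa by their record fingerprint (reporting datasets,
record count, date span) when the pairing is unique; ambiguous cases
degrade to separate removed/added entries rather than guessing.

Expert sheets hold one taxon in exactly one (phylum) sheet, so
conflicting edits to the same taxon across sheets cannot arise by
construction; duplicated or deleted key rows fail naming the sheet and
row.

## The synthetic-data generator

`generate_fixture` emulates a five-source community study at one-tenth
of the scale of a multi-decade island survey: per-category exclusive
targets (24, 8, 7, 1, 1), 26 shared taxa — every shared taxon involving
the dominant dive-survey category, matching the observed structure where
the dive surveys' taxon list contains the entire shared pool — and
per-category record counts (1615, 27, 275, 84, 1), about 2,000 records
over 67 taxa. Default injection rates: 5 % typo records (single-character
edits, so verbatim rules are unambiguous), 2 % coordinate errors
(patched back by the true patch table), 3 % out-of-area records, 4 %
missing coordinates, 10 % obscured-coordinate records on the
crowd-sourced catalogue only. Names come from a Latin-like CV-syllable
grammar; no real nomenclature is shipped beyond a handful of literal
example names in tests.

The generator records ground truth by direct enumeration at generation
time — expected taxon list, partition sizes and contribution statistics
— and plants auxiliary true-taxon/disposition labels on every record so
that `oracle_stats` can recompute the statistics by naive set
enumeration without touching any pipeline code path. The first record of
each (category, taxon) pair is guaranteed to survive the area filter so
the designed overlap structure is exactly recoverable; expected record
counts are those of the curated catalogue (out-of-area records
excluded).

What the generator does **not** emulate: realistic species-abundance
distributions (records are spread near-uniformly over a source's taxa),
temporal autocorrelation of survey effort, spatial clustering of
sampling, multi-catalogue source categories, and messy date/coordinate
formats beyond year-precision dates. Passing the end-to-end recovery
test therefore demonstrates the pipeline's bookkeeping is exact under
controlled corruption — not that any particular real dataset is clean.

## Numerical and degenerate-input choices

* Dates are ISO-8601 strings compared lexicographically; year- and
  month-precision dates sort as prefixes, which is exact for first-date
  and a documented approximation for last-date spans.
* Unparseable name strings are rejected with a diagnostic at parse time;
  where a name must still be grouped (summaries), the fallback key is
  plain text normalisation, never a silent guess.
* Coordinate-free records partition into a review bucket; empty
  catalogues, empty patch tables and empty resolution tables are all
  valid identities.
* CSV I/O is UTF-8 RFC 4180 throughout (stdlib `csv`/pandas), with
  `\n` line terminators for byte-reproducible output.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on generated data:
the full-size synthetic study (~2,000 records), 20 × 100 random-patch
reversibility trials on a 500-record catalogue, 200-rule random acyclic
resolution tables against a brute-force chain walker, and 10,000
random points against a hand-written winding-number membership oracle.
The complete suite runs in well under a minute on one CPU.
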