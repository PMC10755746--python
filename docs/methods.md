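# Methods

## The problem

Regional DNA-barcode reference libraries are useful only insofar as they
cover the fauna one wants to identify. `barcodegap` audits that coverage for
a region: given a species checklist and offline dumps of COI records from
the two global libraries (BOLD and GenBank), it answers (i) how similar the
regional faunas under comparison are, (ii) what fraction of a fauna has at
least one — or many — reference barcodes, and (iii) how many of those
barcodes were actually sequenced from specimens collected inside the
region, as opposed to conspecific material from elsewhere. The motivating
use case is the rove-beetle (Staphylinidae) faunas of West Siberia,
Fennoscandia, and Canada + Alaska.

## Pipeline

1. **Taxonomy harmonization** (`taxa`). Names are compared by an
   authorship-free canonical key `Genus epithet`; trinomials collapse to the
   binomial (the audit counts species); junior synonyms are rewritten to
   the valid name through a two-column synonym table whose chains must be
   acyclic. Matching is exact — fuzzy matching would silently change
   counts. Fused renderings (`Athetaallocera`) are a typesetting artifact
   of some journals; the parser rejects them rather than guessing a split.
2. **Record ingestion** (`records_io`). BOLD combined TSV dumps are read
   through a header-alias map (BOLD has shipped several column namings);
   GenBank flat files through Biopython, taking the `VERSION` token as the
   record ID, the source feature's country qualifier (both the historical
   `country` and the current `geo_loc_name` spelling) as the collection
   locality, and `db_xref="BOLD:…"` values as cross-references. Locality
   text is split at the first colon into country and admin-unit detail.
   All downstream statistics are metadata-driven; sequences are never
   interpreted.
3. **Barcode-region restriction** (`harmonize.filter_barcode_region`). Only
   the 5' (Folmer) fragment of COI is a barcode. Removed, in order: records
   whose marker code is explicitly COI-3P; records whose primer notes name
   the Jerry/Pat 3' pair (C1-J-2183 / TL2-N-3014), which amplifies a
   fragment with almost no overlap with the barcode region; records with no
   marker and no recognizable 5'-fragment evidence. Bare `COI`/`COX1`/`CO1`
   codes count as barcode-compatible absent contrary primer evidence,
   because GenBank rarely states the exact gene region.
4. **Cross-library deduplication** (`harmonize.match_duplicates` /
   `merge`). The same barcode often exists in both libraries; pairs are
   declared strictly by mutual IDs (GenBank citing a BOLD process ID, or a
   BOLD row citing a GenBank accession, version-insensitive), greedily and
   deterministically, one pair per record. A matched pair yields one record
   flagged `BOTH`, carrying the BOLD copy's fields — BOLD's taxonomy is
   curated more actively — with the GenBank ID kept among the
   cross-references. Filtering runs **before** dedup so a duplicate of a
   removed record cannot resurrect it; the conservation law
   `|unique| = |BOLD kept| + |GenBank kept| − |pairs|` is asserted.
   No sequence-identity fallback is used: hash-based matching would change
   behaviour on corpora that simply lack cross-references.
5. **Geographic attribution and coverage** (`coverage`). A record's country
   maps to at most one region; sub-country regions (West Siberia within
   Russia, Alaska within the USA, north-western Russia within Fennoscandia)
   are expressed as admin-unit regex overrides, and a bare `Russia`
   deliberately resolves to no region rather than guessing. Coverage is
   defined against the checklist: one row per species including zeros;
   species with barcodes but absent from the checklist go to a separate
   extralimital appendix. Deep coverage uses a strict threshold (more than
   `k` barcodes, default `k = 10`). Percentages are pure functions of the
   integer tallies, rounded half-up (whole numbers by default, two decimals
   on request).
6. **Similarity** (`similarity`). Czekanowski–Sørensen `S = 2c/(a+b)` and
   Jaccard `J = c/(a+b−c)` on species or genus sets, with the identity
   `J = S/(2−S)` used as an internal consistency check. Continent-level
   comparisons pool member checklists by set union before indexing.
   Comparing two empty sets raises rather than returning 0 — 0/0 has no
   faunistic meaning. Full-precision fractions are kept internally;
   reported percentages are rounded half-up to 2 decimals.

## Synthetic data

Two generators make every stage testable offline.

**Paired corpora** (`fixtures.generate_corpus`). Per-species barcode counts
follow a zero-inflated geometric law (default zero-mass 0.3, mean 8): most
species have no or few barcodes while a heavy tail has many, which mirrors
the extreme skew of real libraries (a handful of species carry hundreds of
barcodes). A stated fraction `p_dup` (default 0.25, matching the roughly
one-quarter cross-deposition seen between the real libraries) of barcodes
is deposited in both libraries with consistent mutual references;
contamination (COI-3P records, Jerry/Pat primer products, records with no
gene-region information) is planted at stated rates; synonym conflicts are
planted on cross-deposited pairs (the GenBank copy identified under a
junior synonym). A `truth.json` records every planted quantity, and the
end-to-end tests require exact recovery. All draws flow from one seed;
outputs are byte-identical across runs. What the generator does **not**
emulate: real nucleotide evolution (sequences are random bases), BOLD BINs,
misidentifications other than synonymy, and localities finer than
country + admin unit — so passing tests demonstrate correct accounting, not
robustness to dirty real-world identifications.

**Regional checklists** (`fixtures.synthetic_checklists`). The authentic
three-region species lists are not redistributable here, so the package
ships a generator for
*synthetic* checklists: invented pseudo-Latin names, but cardinalities
(726 / 1399 / 1858 species) and overlap structure solved by integer search
from the published similarity percentages. Chosen design — species-level
pairwise overlaps WS∩FS = 616, WS∩CA = 185, FS∩CA = 287, triple = 175;
genus level 213/300/385 genera with overlaps 191/159/207, triple = 149.
Every genus is seeded with one species spanning exactly the genus's region
set, and remaining species are dealt round-robin to compatible genera, so
genus-level presence equals the design by construction.

### Why some published similarity cells are not reproducible

The published percentage table is internally inconsistent, so no choice of
input sets — synthetic or authentic — can reproduce every cell to 2
decimals:

* For the WS–FS species pair, the rounding windows implied by the printed
  Jaccard (41.06) and Sørensen (58.20) require the intersection/total
  fraction to lie in two *disjoint* intervals; and with fauna sizes 726 and
  1399 fixed, even 58.20 alone has no integer intersection.
* For WS–CA at species level, intersection 185 is the only integer hitting
  the printed Jaccard (7.71); it yields Sørensen 14.32 vs the printed 14.31.
* All three genus-level rows violate `J = S/(2−S)` by 0.09–1.83 points.
  For WS–CA the printed Jaccard 36.22 implies Sørensen 53.18 against a
  printed 51.18 — plausibly a single-digit misprint — so the design matches
  the Jaccard cell there; for the other two genus pairs it matches the
  Sørensen column (the index the accompanying text quotes) and lets Jaccard
  land where the identity puts it.

The design instead makes exactly reproducible: both FS–CA species cells,
WS–CA species Jaccard, the genus cells named above, all three checklist
cardinalities, and the continent-level comparison (union of the two
Eurasian lists vs Canada + Alaska: Sørensen 17.64%, Jaccard 9.67% — which
constrained WS∩FS to 616 rather than the closest-to-print 618). The
acceptance test for the full table asserts every printed cell and lets the
provably unattainable ones fail, rather than relaxing the check.

Absolute barcode counts (totals per library, per-species maxima, overlap
counts) depend on the live contents of the two libraries at download date
and are out of scope for reproduction; the tests verify the accounting
rules on planted corpora instead.

## Numerical and procedural choices

* Rounding is decimal half-up everywhere percentages are printed
  (`similarity.percent`), never binary round-half-even, to match the
  reporting convention of the reproduced tables.
* Ties in the most-barcoded ranking break alphabetically by canonical key;
  all sorts are stable (mergesort) so outputs are byte-deterministic.
* Greedy pair matching processes GenBank-side cross-references first, then
  BOLD-side, each in input order with sorted xref iteration; conflicting
  extra matches are logged and ignored (first wins).
* Report CSVs are written sorted by species key with fixed column order;
  re-running a command with its echoed `run_config.json` inputs reproduces
  outputs byte-identically.
* Checklist loading collapses post-resolution duplicates with a warning
  (cardinality is invariant under row order and duplication); malformed
  rows raise by default, or are logged and skipped with `errors="skip"`.

## Problem sizes

Test corpora use 20 species with mean 8 barcodes per species across a
2 × 3 grid of contamination and cross-deposition rates; the checklist
reconstruction is exercised at full published scale (3 070 species, 490
genera). The whole suite and the acceptance computation run in seconds.

## Known limitations

* Region attribution is only as good as the locality metadata; records
  with a bare country that spans multiple regions (e.g. `Russia`) are
  deliberately unassigned, which undercounts within-region barcodes if real
  admin-unit detail is missing.
* Deduplication finds only pairs the libraries themselves cross-reference;
  uncross-referenced duplicates survive as two records.
* Marker inference for GenBank relies on gene/product/note/primer
  qualifiers; a mislabeled record passes or fails with its labels.
* Synonym handling covers binomial-to-binomial rewrites only; no
  nomenclatural-act validation and nothing above genus level.
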