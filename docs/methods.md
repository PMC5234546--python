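# Methods

This note documents the models and procedures behind each curation stage,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## Geographic validation

**Model.** A record is a point *p* (WGS84 decimal degrees) plus a
documented country *c*. Classification is a decision tree: *p* inside the
polygon of *c* → `Match` (kept); *p* inside a country adjacent to *c* →
`Neighbour`, kept iff the nearest distance from *p* to the border of *c*
is ≤ the tolerance; *p* inside a non-adjacent country → `Error`
(discarded); *p* in no polygon → `Sea`, kept iff within the tolerance of
the coastline of *c*, discarded if no *c* is documented. Records without
coordinates are `NoCoordinates` (discarded); with coordinates but an
unknown country, `NoCountry` (kept by default, configurable — they cannot
be checked, and silently discarding unverifiable data would bias the
result toward well-documented sources).

**Parameters.** `tolerance_km` (default 5 km) is the slack granted to
Neighbour and Sea records; it reflects the combined imprecision of border
maps and coordinate recording near borders, not a biological quantity.
The tie at exactly the tolerance is resolved as *keep* (≤), applied
uniformly to both checks; a point exactly on the documented border counts
as inside (`Match`) — both tie-breaks favour retention.

**Distance.** Great-circle on a sphere of radius 6371.0088 km (WGS84 mean
radius); at a 5 km tolerance the ellipsoidal correction (< 0.5%) cannot
change a verdict. Boundaries are densified to segments of at most ~1 km
and the distance is the minimum over segments of the spherical
point-to-arc (cross-track) distance, falling back to endpoint distances
when the point does not project onto a segment. This agrees with a dense
brute-force sweep of the boundary to well under 0.1%. Adjacency is
precomputed: two countries are adjacent iff their boundaries share a
1-dimensional intersection (a corner touch does not make neighbours).

**Polygon input.** GeoJSON FeatureCollections (RFC 7946, lon/lat order)
with the country code in a configurable property; invalid polygons are
repaired on load. Results near borders inherit the accuracy of whatever
border dataset is supplied — the polygon source is deliberately an
explicit input, not a bundled map.

**Density grid.** Counts per `cell_degrees` square (default 2°), cells
half-open `[lower, upper)` so edge points are assigned uniquely; counts
sum to the number of records with coordinates.

## Precision coding

The eight granularities are, in degrees: 1, 1/4, 1/12, 1/30, 1/60, 1/600,
1/6000, 1/60000 (codes 1–8). From a verbatim sexagesimal string the code
is read off the stated structure: no minute token → 1; decimal minutes
with *k* ≥ 1 decimals → 5 + *k* (capped at 8); integer minutes → the
coarsest of 15′/5′/2′/1′ dividing *both* components (codes 2–5). From
decimal degrees the same joint rule applies over all eight granularities:
the code is the coarsest granularity of which both |lat| and |lon| are
integer multiples, within a tolerance of 1e-9 after rounding to 10
decimals (defeats binary float artifacts). The joint rule is what makes a
(15′, 33′) pair code 5 while (15′, 45′) is code 2: a single component that
happens to be a multiple of a coarse step is still *consistent* with finer
recording, and only the pair reveals the granularity actually used.
Coordinates matching no granularity — true decimal-degree data — are coded
8; the scale has no finer class, and such data are at least as precise as
its finest step. Unparseable verbatim strings fall back to decimal
inference rather than failing. Assignment is deterministic and idempotent,
and refining a coordinate never lowers its code.

## Duplicate merging

**Match key.** Herbarium duplicates are sheets of one gathering, so the
key is the collecting event: normalized collector × collector number ×
collection year, with exact genus agreement required when the number is
absent (collector + year alone over-merges prolific collectors).
Collector normalization case-folds, strips accents and punctuation, and
drops single-letter tokens, so "Harris, D.J." ≡ "D.J. Harris"; remaining
token sets are compared by normalized edit similarity with a configurable
threshold (default 0.85). Collection years must match exactly — dates two
years apart are different gatherings even under the same number.

**Cascades.** Identification: (1) expert-curated (personal-database)
members outrank institutional ones; (2) most recent identification date;
(3) lowest (most specific) taxonomic rank, ordered infraspecific <
species < genus < family; (4) seeded deterministic choice. Coordinates:
(1) the member that passed the country check; (2) personal database; (3)
highest precision code; (4) seeded choice. Each cluster records the first
step that produced a unique winner. A filter step that narrows but does
not decide passes its survivors to the next step.

**Determinism.** "Random" fallbacks are keyed on the caller's seed plus
the sorted member ids, never on input order or Python hashing, so merging
is reproducible and shuffling the input yields byte-identical output. The
consensus record keeps the smallest member id; identification fields come
from the identification winner, coordinate fields from the coordinate
winner, all other fields are the first non-empty value in id order.

## Name standardization

The backbone is a table of (name, rank, status, accepted-link) rows with
validated links: accepted entries self-link, synonyms link to accepted
entries, so resolution terminates in one hop. Matching scores genus and
epithet(s) separately by normalized edit similarity (1 − d/len via
edit distance) and combines them as a length-weighted mean; the overall
score is 1.0 iff the normalized strings are equal (near-misses are capped
just below 1), matching the convention of name-resolution services that
score on [0, 1]. A match is *partial* when the best candidate's genus
equals the submitted genus but the epithet similarity is below 0.75 — the
genus exists, the epithet does not plausibly match anything. The 0.75
threshold separates one-to-two-letter typos (similarity ≥ 0.8 on typical
epithet lengths) from unrelated epithets (typically ≤ 0.5); it is a
package constant, declared rather than fitted.

The review lists implement the two-list workflow exactly: misspelling
candidates are accepted-status matches with score < 1 and no partial
match; synonym candidates are exact matches whose matched name differs
from its accepted name, plus inexact matches whose matched backbone entry
is itself a synonym. The lists feed a decisions table (name → accept /
correct spelling / map to accepted / exclude); nothing is rewritten or
excluded without a decision, mirroring the manual-review step that such
workflows require. Applying decisions is idempotent. The scoring function
is declared an emulation of service-internal scoring: the reproducible
part — the list-construction logic operating on scores — is implemented
exactly, and the scorer is swappable behind the same `NameMatch` surface.

## Cultivated/introduced screening

Ex-situ keywords are case-insensitive substrings (multilingual defaults:
garden/jardin/hortus/arboretum/plantation/...); a keyword hit alone never
discards — only localities in the confirmed list do, and unconfirmed hits
are emitted as the review file. The rare-species screen considers species
with fewer than 11 records (cultivated plants are rarely collected in the
field, so aliens concentrate among the rarely-collected); their global
occurrences are fetched from a pluggable `ExternalOccurrenceSource` and a
species is an introduced candidate when strictly more than 50% of its
external records fall outside the study-region polygon. "Mostly outside"
had to be quantified; >50% is the weakest reading, and raising the
fraction threshold can only shrink the candidate set (monotone). An
unavailable source defers decisions rather than silently dropping
candidates. Confirmed species are then removed wholesale, with one audit
entry per record.

## Habit inference

Keywords are matched per class at word boundaries (regex `\b...\b`), with
the listed case variants matched exactly — "Tree", "tree", "Arbre",
"arbre", "Arbor", "arbor" for the tree class — so "street" never tags
tree and ALL-CAPS text never matches (adding variants is configuration,
not code). A specimen contributes at most one tag per class — presence,
not occurrence count — so a verbose label cannot outvote ten terse ones.
Per species, tags are summed; the argmax class is the primary habit, with
ties broken by the fixed order tree > shrub > liana > herb > epiphyte >
parasitic > mycoheterotroph (frequency order among tropical woody floras;
any fixed order gives determinism, which is the point). A secondary habit
exists iff the primary count is *strictly* less than half the total —
9 shrub of 20 total (< 10) admits a liana secondary; 5 of 10 (exactly
half) does not. Palm-like erect monocots (palms, *Dracaena*, *Pandanus*)
carry tree/shrub vocabulary unreliably and are handled by a species-level
override table following the literature. An optional reference table
cross-checks profiles; mismatches are flagged for manual decision, never
auto-resolved.

## Synthetic fixtures

`occurclean.synth` generates a tessellated block of rectangular 2°×2°
countries (rook adjacency, ocean west of the block), a backbone of
pseudo-Latin binomials (one synonym per accepted name, all generated words
pairwise ≥ 3 edits apart so a planted one-letter typo always resolves to
its own source), and an occurrence table with errors injected per record:
border swaps at 2–3 km (unambiguous keeps), offshore points at 2 km or
40 km (unambiguous keep/discard), non-adjacent-country errors, duplicate
copies with reformatted collector strings, misspellings, synonym usage,
cultivated species with mostly-external synthetic ranges, and ex-situ
localities. Default rates (5% border swaps, 3% sea, 3% far errors, 10%
duplicates, 5% misspellings, 5% synonyms, 8% cultivated species, 2%
ex-situ) are plausible magnitudes for a multi-source compilation; the
generator is deterministic given its seed.

**What passing fixtures shows — and does not.** Fixture geometry is
rectangles with error offsets planted far from the 5 km boundary, names
are well-separated, and collector variants are benign. Recovery of 100%
of planted labels therefore demonstrates the *logic* of each stage
(classification rules, cascade order, list construction), not performance
on real data, where border datasets disagree, epithets differ by one
letter legitimately, collector strings are genuinely ambiguous, and label
vocabulary is unbounded. Stage-by-stage confusion against ground truth is
the supported evaluation; dataset-scale recall on real compilations is
out of scope.

**Problem sizes.** The default test fixtures run at 200–600 records,
20–100 species, 4 countries, and the cascade suite at 1,000 two-member
clusters — sizes at which every planted situation class appears dozens to
hundreds of times while the full suite stays fast enough to run on every
change.

## Known limitations

* Planar rectangles with great-circle distances are consistent only at
  small extents (< 5°); the fixture generator documents, not hides, this.
* Shapefile input is not supported; convert to GeoJSON first.
* The name matcher scores genus and epithet strings only; authorship is
  ignored, and no nomenclatural parsing (hybrids, autonyms) is attempted.
* Family assignment is treated as a genus→family lookup supplied as
  configuration, not a computed step.
* No live web-service access (name resolution, occurrence download):
  both are pluggable interfaces with offline implementations.
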