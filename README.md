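# occurclean

Quality control for georeferenced specimen occurrence records.

Compiled biodiversity datasets — herbarium databases, personal research
datasets, silica collections, plot inventories — are full of quiet errors:
coordinates that fall in the wrong country or in the sea, coordinates far
more precise-looking than the label that produced them, the same gathering
present five times under five identifications, names that are misspellings
or synonyms of each other, botanical-garden specimens masquerading as wild
occurrences, and no structured habit information at all. `occurclean`
implements the curation stages that turn such a compilation into a usable
distribution dataset, for biodiversity informaticians and ecologists
working with Darwin-Core-style CSV exports.

## What it does

* **Geographic validation** (`occurclean.geovalidate`). Each record's point
  is tested against its documented country. Inside → *Match*. Inside an
  adjacent country → *Neighbour*, kept iff the great-circle distance *d* to
  the documented border satisfies *d* ≤ 5 km (border maps and coordinates
  are both imprecise at that scale). Inside a non-adjacent country →
  *Error*, discarded. In the ocean → *Sea*, kept iff within 5 km of the
  documented coastline. Distances are spherical (R = 6371.0088 km),
  computed as point-to-arc cross-track distances over boundaries densified
  to ≤ 1 km segments. A 2°×2° density grid summarises the result.
* **Precision coding** (`occurclean.precision`). An ordinal code 1–8 per
  record: degree-only ≈ 110 km (1), 15′ ≈ 30 km (2), 5′ ≈ 10 km (3),
  2′ ≈ 4 km (4), whole minute ≈ 2 km (5), and 0.1′/0.01′/0.001′ decimal
  minutes ≈ 200 m/20 m/2 m (6/7/8), derived from the verbatim sexagesimal
  string when present, else inferred from the decimal degrees.
* **Duplicate merging** (`occurclean.dedup`). Records sharing normalized
  collector + number + collection year are one gathering. Conflicting
  identifications resolve by the cascade *personal database → most recent
  identification date → lowest (most specific) rank → seeded choice*;
  conflicting coordinates by *passed country check → personal database →
  highest precision code → seeded choice*.
* **Name standardization** (`occurclean.taxonomy`). Names are matched to a
  local backbone by normalized edit similarity (score ∈ [0,1], 1 iff
  exact); a *misspelling list* (accepted match, score < 1, non-partial)
  and a *synonym list* (matched name ≠ its accepted name) are emitted for
  review, and reviewed decisions are applied with an audit trail.
* **Cultivated/introduced screening** (`occurclean.flags`). Ex-situ
  localities are flagged by multilingual keywords and removed once
  confirmed; species with < 11 records whose external (e.g. GBIF-style)
  occurrences fall mostly outside the study region are flagged as
  introduced candidates.
* **Habit inference** (`occurclean.habit`). Word-boundary keyword tagging
  of label text over seven habit classes; per species the top-voted class
  is the primary habit, with a secondary habit when the primary holds less
  than half of the tags.
* **Synthetic fixtures** (`occurclean.synth`). Fully ground-truthed
  miniature worlds — tessellated countries, a backbone with synonyms,
  records with injected errors at configurable rates — so every stage is
  testable offline.

Every stage logs kept/discarded/merged decisions to a shared audit log, so
`records in = records kept + records discarded` holds at every step.

## Worked example

```python
from shapely.geometry import box
from occurclean.datamodel import OccurrenceRecord, TaxonName
from occurclean.geovalidate import CountryPolygonSet, validate_country
from occurclean.precision import assign_precision
from occurclean.habit import HabitClass, aggregate_habit

borders = CountryPolygonSet({"GAB": box(8, -4, 12, 2), "COG": box(12, -4, 16, 2)})
rec = OccurrenceRecord(
    "r1", taxon=TaxonName(genus="Acacia", species_epithet="adenocalyx"),
    country_code="COG", latitude=0.5, longitude=11.97,
)
res = validate_country(rec, borders)
print(res.classification.value, res.verdict.value, round(res.distance_km, 2))

print(assign_precision("4°15'N 12°33'E", 4.25, 12.55))

tags = [{HabitClass.shrub}] * 9 + [{HabitClass.liana}] * 7 \
     + [{HabitClass.tree}] * 2 + [{HabitClass.herb}] * 2
p = aggregate_habit("Acacia adenocalyx", tags)
print(p.primary_habit.value, p.secondary_habit.value, p.total_tags)
```

prints

```
Neighbour keep 3.34
PrecisionCode(code=5, approx_uncertainty_km=2.0)
shrub liana 20
```

The record is documented from COG but georeferenced 3.34 km inside GAB —
within the 5 km neighbour tolerance, so it is kept. The coordinate
4°15′N 12°33′E is exact to the whole minute: code 5, ≈ 2 km uncertainty
(the 15′ latitude alone would admit quarter-degree recording, but paired
with 33′ the pair must have been recorded to the minute). A species with
20 habit tags of which 9 say shrub and 7 liana gets primary habit *shrub*;
since 9 < 10 (less than half the tags), *liana* becomes its secondary
habit.

The same stages are available as a CLI:

```sh
occurclean synth --n-records 200 --seed 3 --out fixtures/
occurclean geo --polygons fixtures/borders.geojson fixtures/records.csv kept.csv --audit audit.csv
occurclean dedup --seed 1 kept.csv merged.csv --clusters clusters.csv
occurclean taxonomy --backbone fixtures/backbone.csv merged.csv standardized.csv
occurclean flags standardized.csv natural.csv
occurclean habit natural.csv species_habits.csv
```

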