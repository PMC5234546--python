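"""Screening for ex-situ collections and introduced/cultivated taxa.

A native-flora occurrence dataset must not contain specimens gathered from
botanical gardens, arboreta or plantations (*ex situ* living collections),
nor records of species present in the region only through cultivation or
introduction. Two screens are applied:

1. **Locality screen.** Locality strings are searched for ex-situ keywords
   ("botanical garden", "jardin botanique", "hortus", ...). Keyword hits
   form a preliminary list; only localities confirmed by a reviewer are
   discarded, the rest are emitted as a review file. The confirmation step
   is irreducibly human and is therefore surfaced as a decisions input.

2. **Rare-species external-range screen.** Cultivated and introduced taxa
   are rarely collected in the field, so candidates are sought among
   species with few records (default: fewer than 11). Each candidate is
   looked up in a pluggable external occurrence source; a species whose
   external records fall mostly (>50%) outside the study region polygon is
   an introduced candidate. Confirmed species are removed wholesale.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from occurclean.datamodel import Action, AuditLog, OccurrenceRecord, Stage

__all__ = [
    "DEFAULT_EX_SITU_KEYWORDS",
    "LocalityDecision",
    "LocalityFlag",
    "RangeDecision",
    "SpeciesRangeSummary",
    "ExternalOccurrenceSource",
    "screen_localities",
    "find_introduced_candidates",
    "apply_introduced_list",
]

#: Multilingual ex-situ keywords, matched case-insensitively as substrings.
DEFAULT_EX_SITU_KEYWORDS = (
    "botanical garden",
    "botanic garden",
    "jardin botanique",
    "hortus",
    "arboretum",
    "plantation",
    "cultivated",
    "cultivé",
    "garden",
    "jardin",
    "nursery",
    "greenhouse",
)


class LocalityDecision(str, enum.Enum):
    ex_situ = "ex_situ"
    natural = "natural"


@dataclass(frozen=True)
class LocalityFlag:
    locality: str
    matched_keyword: str
    decision: LocalityDecision


class RangeDecision(str, enum.Enum):
    native = "native"
    introduced_candidate = "introduced_candidate"
    introduced_confirmed = "introduced_confirmed"
    deferred = "deferred"


@dataclass(frozen=True)
class SpeciesRangeSummary:
    species: str
    n_records_internal: int
    n_records_external: int
    n_external_outside: int
    decision: RangeDecision


class ExternalOccurrenceSource(Protocol):
    """Interface to an external occurrence provider (e.g. a GBIF snapshot).

    Implementations return (lat, lon) pairs of occurrences of a species
    anywhere in the world, or an empty list when the species is unknown.
    """

    def lookup(self, species: str) -> Sequence[tuple[float, float]]: ...


def screen_localities(
    records: Sequence[OccurrenceRecord],
    keywords: Sequence[str] = DEFAULT_EX_SITU_KEYWORDS,
    confirmed_localities: Iterable[str] = (),
    audit: AuditLog | None = None,
) -> tuple[list[OccurrenceRecord], list[LocalityFlag], list[str]]:
    """Discard records from confirmed ex-situ localities.

    Returns ``(kept_records, flags, review_list)`` where ``review_list``
    holds the distinct keyword-matched locality strings *not* yet in
    ``confirmed_localities`` — the input to the human confirmation round.
    """
    confirmed = {c.strip().casefold() for c in confirmed_localities}
    kept: list[OccurrenceRecord] = []
    flags: list[LocalityFlag] = []
    review: dict[str, None] = {}
    kws = [(kw, kw.casefold()) for kw in keywords]
    for rec in records:
        loc = rec.locality_text
        low = loc.casefold()
        hit = next((kw for kw, kwl in kws if kwl and kwl in low), None)
        if hit is None:
            kept.append(rec)
            continue
        if low.strip() in confirmed:
            flags.append(LocalityFlag(loc, hit, LocalityDecision.ex_situ))
            if audit is not None:
                audit.add(rec.record_id, Stage.flags, Action.discarded, f"ex situ locality ({hit})")
        else:
            flags.append(LocalityFlag(loc, hit, LocalityDecision.natural))
            review.setdefault(loc)
            kept.append(rec)
    return kept, flags, list(review)


def find_introduced_candidates(
    records: Sequence[OccurrenceRecord],
    region: BaseGeometry,
    external_source: ExternalOccurrenceSource | None = None,
    threshold: int = 11,
    outside_fraction: float = 0.5,
) -> list[SpeciesRangeSummary]:
    """Flag rarely-collected species whose global range lies mostly outside
    the study region.

    Species with fewer than ``threshold`` records in ``records`` are looked
    up in ``external_source``; a species is an ``introduced_candidate``
    when the fraction of its external occurrences outside ``region``
    exceeds ``outside_fraction``. With no external evidence the species
    stays ``native``; with no source at all the decision is ``deferred``.
    """
    counts = Counter(r.taxon.canonical for r in records if r.taxon.species_epithet)
    summaries: list[SpeciesRangeSummary] = []
    for species in sorted(counts):
        n_internal = counts[species]
        if n_internal >= threshold:
            continue
        if external_source is None:
            summaries.append(SpeciesRangeSummary(species, n_internal, 0, 0, RangeDecision.deferred))
            continue
        external = external_source.lookup(species)
        n_ext = len(external)
        if n_ext == 0:
            summaries.append(SpeciesRangeSummary(species, n_internal, 0, 0, RangeDecision.native))
            continue
        outside = sum(1 for lat, lon in external if not region.covers(Point(lon, lat)))
        decision = (
            RangeDecision.introduced_candidate
            if outside / n_ext > outside_fraction
            else RangeDecision.native
        )
        summaries.append(SpeciesRangeSummary(species, n_internal, n_ext, outside, decision))
    return summaries


def apply_introduced_list(
    records: Sequence[OccurrenceRecord],
    confirmed_species: Iterable[str],
    audit: AuditLog | None = None,
) -> tuple[list[OccurrenceRecord], list[str]]:
    """Remove every record of the confirmed introduced/cultivated species.

    Returns ``(kept_records, warnings)``; a confirmed species absent from
    the data produces a warning string, never an error.
    """
    confirmed = {s.strip() for s in confirmed_species if s.strip()}
    present = {r.taxon.canonical for r in records}
    warnings = [f"species not in data: {s}" for s in sorted(confirmed - present)]
    kept = []
    for rec in records:
        if rec.taxon.canonical in confirmed:
            if audit is not None:
                audit.add(rec.record_id, Stage.flags, Action.discarded, f"introduced/cultivated: {rec.taxon.canonical}")
        else:
            kept.append(rec)
    return kept, warnings
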