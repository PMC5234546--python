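"""End-to-end curation pipeline: geo -> precision -> dedup -> taxonomy -> flags.

Convenience orchestration of the individual stage modules with a shared
audit log, preserving the conservation invariant at every stage
(records in = records kept + records discarded/merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from shapely.geometry.base import BaseGeometry

from occurclean.datamodel import AuditLog, OccurrenceRecord
from occurclean.dedup import DuplicateCluster, KeyConfig, dedup_records
from occurclean.flags import (
    ExternalOccurrenceSource,
    SpeciesRangeSummary,
    apply_introduced_list,
    find_introduced_candidates,
    screen_localities,
)
from occurclean.geovalidate import CountryPolygonSet, GeoValidationResult, validate_records
from occurclean.habit import HabitProfile, profile_species
from occurclean.precision import PrecisionCode, assign_precision_records
from occurclean.taxonomy import (
    Backbone,
    NameMatch,
    ResolvedAction,
    apply_standardization,
    build_misspelling_list,
    build_synonym_list,
    match_names,
)

__all__ = ["PipelineResult", "run_pipeline", "auto_decisions"]


@dataclass
class PipelineResult:
    records: list[OccurrenceRecord]
    audit: AuditLog
    geo_results: dict[str, GeoValidationResult]
    precision_codes: dict[str, PrecisionCode]
    clusters: list[DuplicateCluster]
    name_matches: list[NameMatch]
    range_summaries: list[SpeciesRangeSummary]
    habit_profiles: dict[str, HabitProfile]
    locality_review: list[str]


def auto_decisions(matches: Sequence[NameMatch]) -> dict[str, ResolvedAction]:
    """Turn the two review lists into mechanical decisions.

    Misspelling candidates are corrected to their matched name, synonym
    candidates mapped to their accepted name. In production these lists go
    to a human reviewer; the mechanical version is what fixture-based
    testing exercises.
    """
    decisions: dict[str, ResolvedAction] = {}
    for m in build_synonym_list(matches):
        decisions[m.submitted] = ResolvedAction.map_to_synonym_target
    for m in build_misspelling_list(matches):
        decisions.setdefault(m.submitted, ResolvedAction.correct_spelling)
    return decisions


def run_pipeline(
    records: Sequence[OccurrenceRecord],
    polygons: CountryPolygonSet,
    backbone: Backbone,
    region: BaseGeometry | None = None,
    external_source: ExternalOccurrenceSource | None = None,
    confirmed_ex_situ: Sequence[str] = (),
    confirmed_introduced: Sequence[str] = (),
    decisions: Mapping[str, ResolvedAction] | None = None,
    tolerance_km: float = 5.0,
    seed: int = 0,
    key_config: KeyConfig | None = None,
) -> PipelineResult:
    """Run every curation stage in order on ``records``.

    When ``decisions`` is None the taxonomy review lists are applied
    mechanically via :func:`auto_decisions`.
    """
    audit = AuditLog()

    geo = validate_records(records, polygons, tolerance_km, audit=audit)
    kept = [r for r in records if geo[r.record_id].keep]

    codes = assign_precision_records(kept)

    kept, clusters = dedup_records(
        kept, geo_results=geo, precision_codes=codes, key_config=key_config, seed=seed, audit=audit
    )

    names = sorted({r.taxon.canonical for r in kept if r.taxon.canonical})
    matches = match_names(names, backbone)
    dec = dict(decisions) if decisions is not None else auto_decisions(matches)
    kept = apply_standardization(kept, matches, dec, backbone, audit=audit)

    kept, _flags, review = screen_localities(
        kept, confirmed_localities=confirmed_ex_situ, audit=audit
    )
    summaries: list[SpeciesRangeSummary] = []
    if region is not None:
        summaries = find_introduced_candidates(kept, region, external_source)
    kept, _warn = apply_introduced_list(kept, confirmed_introduced, audit=audit)

    profiles = profile_species(kept)

    return PipelineResult(
        records=kept,
        audit=audit,
        geo_results=geo,
        precision_codes=codes,
        clusters=clusters,
        name_matches=matches,
        range_summaries=summaries,
        habit_profiles=profiles,
        locality_review=review,
    )
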