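"""Duplicate-specimen detection and consensus merging.

Herbarium gatherings are routinely split into several physical duplicates
distributed among institutions, so a compiled dataset holds many rows for
one collection event, each possibly carrying a different identification or
georeference. Records are clustered on a normalized match key — collector
surname(s) + collector number + collection year, with exact genus agreement
required when the collector number is absent — and each cluster is merged
into one consensus record.

Conflicts are settled by two priority cascades, each recording the first
step that produced a unique winner:

identification: personal (expert-curated) database > most recent
identification date > lowest (most specific) taxonomic rank > seeded
deterministic choice.

coordinates: member that passed the country quality check > personal
database > highest precision code > seeded deterministic choice.

"Random" fallbacks hash the sorted member ids together with a caller seed,
so merging is reproducible and independent of input order.
"""

from __future__ import annotations

import enum
import random
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from occurclean.datamodel import (
    Action,
    AuditEntry,
    AuditLog,
    OccurrenceRecord,
    Stage,
)
from occurclean.geovalidate import GeoValidationResult
from occurclean.precision import PrecisionCode

__all__ = [
    "KeyConfig",
    "IdRule",
    "CoordRule",
    "DuplicateCluster",
    "normalize_collector",
    "collector_similarity",
    "find_duplicates",
    "resolve_identification",
    "resolve_coordinates",
    "merge",
    "dedup_records",
]


class IdRule(str, enum.Enum):
    personal = "personal"
    most_recent_date = "most_recent_date"
    lowest_rank = "lowest_rank"
    random = "random"


class CoordRule(str, enum.Enum):
    passed_country_check = "passed_country_check"
    personal = "personal"
    highest_precision = "highest_precision"
    random = "random"


@dataclass(frozen=True)
class KeyConfig:
    """Tunables of the duplicate match key."""

    fuzzy_threshold: float = 0.85  # min normalized edit similarity of collector names
    require_genus_without_number: bool = True


@dataclass
class DuplicateCluster:
    members: list[OccurrenceRecord]
    match_key: tuple
    consensus: OccurrenceRecord | None = None
    id_resolution_rule_used: IdRule | None = None
    coord_resolution_rule_used: CoordRule | None = None

    @property
    def member_ids(self) -> list[str]:
        return sorted(m.record_id for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


# --- collector-name normalization -----------------------------------------

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)


def normalize_collector(name: str) -> frozenset[str]:
    """Surname token set: case-folded, accents stripped, punctuation folded,
    single-letter tokens (initials) dropped.

    "Harris, D.J." and "D.J. Harris" normalize identically.
    """
    folded = unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode()
    folded = _PUNCT.sub(" ", folded.casefold())
    return frozenset(t for t in folded.split() if len(t) > 1)


def _edit_similarity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b), 1)


def collector_similarity(a: frozenset[str], b: frozenset[str]) -> float:
    """Normalized similarity of two collector token sets in [0, 1]."""
    if not a or not b:
        return 1.0 if a == b else 0.0
    sa, sb = " ".join(sorted(a)), " ".join(sorted(b))
    return _edit_similarity(sa, sb)


def _normalize_number(number: str) -> str:
    return re.sub(r"\s+", "", number).casefold().lstrip("0") or ""


# --- clustering ------------------------------------------------------------


def find_duplicates(
    records: Sequence[OccurrenceRecord], key_config: KeyConfig | None = None
) -> list[DuplicateCluster]:
    """Partition records into duplicate clusters; singletons are excluded.

    Records are blocked on (collector number, collection year) — or on
    (genus, collection year) when the number is absent — then linked within
    a block when their collector token sets match exactly or with edit
    similarity above the configured threshold. The result is a partition:
    clusters are disjoint and every record belongs to at most one.
    """
    cfg = key_config or KeyConfig()
    blocks: dict[tuple, list[int]] = {}
    keys: list[tuple] = []
    for i, rec in enumerate(records):
        year = rec.collection_date.year if rec.collection_date else None
        number = _normalize_number(rec.collector_number)
        if number:
            block = ("num", number, year)
        elif cfg.require_genus_without_number:
            block = ("gen", rec.taxon.genus.casefold(), year)
        else:
            block = ("nonum", year)
        keys.append(block)
        blocks.setdefault(block, []).append(i)

    parent = list(range(len(records)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    norm = [normalize_collector(r.collector) for r in records]
    for block, idxs in blocks.items():
        if len(idxs) < 2:
            continue
        for ai, a in enumerate(idxs):
            for b in idxs[ai + 1 :]:
                if norm[a] == norm[b] or collector_similarity(norm[a], norm[b]) >= cfg.fuzzy_threshold:
                    union(a, b)

    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for idxs in groups.values():
        if len(idxs) < 2:
            continue
        members = sorted((records[i] for i in idxs), key=lambda r: r.record_id)
        clusters.append(DuplicateCluster(members=members, match_key=keys[idxs[0]]))
    clusters.sort(key=lambda c: c.member_ids[0])
    return clusters


# --- resolution cascades ---------------------------------------------------


def _seeded_pick(members: Sequence[OccurrenceRecord], all_ids: Sequence[str], seed: int) -> OccurrenceRecord:
    # keyed on the sorted ids of the whole cluster, not input order
    rng = random.Random(f"{seed}|{','.join(sorted(all_ids))}")
    chosen_id = rng.choice(sorted(m.record_id for m in members))
    return next(m for m in members if m.record_id == chosen_id)


def _unique(members: Sequence[OccurrenceRecord]) -> OccurrenceRecord | None:
    return members[0] if len(members) == 1 else None


def resolve_identification(
    cluster: DuplicateCluster, seed: int = 0
) -> tuple[OccurrenceRecord, IdRule]:
    """Choose the member whose identification the consensus record keeps."""
    members = cluster.members
    all_ids = cluster.member_ids
    candidates = list(members)

    personal = [m for m in candidates if m.expert_curated]
    if personal and len(personal) < len(candidates):
        candidates = personal
        if _unique(candidates) or len({m.taxon.canonical for m in candidates}) == 1:
            return min(candidates, key=lambda m: m.record_id), IdRule.personal

    dated = [m for m in candidates if m.identification_date is not None]
    if dated:
        latest = max(m.identification_date for m in dated)
        winners = [m for m in dated if m.identification_date == latest]
        if (w := _unique(winners)) is not None:
            return w, IdRule.most_recent_date
        candidates = winners

    best_rank = min(m.taxon.rank_order for m in candidates)
    winners = [m for m in candidates if m.taxon.rank_order == best_rank]
    if (w := _unique(winners)) is not None:
        return w, IdRule.lowest_rank
    candidates = winners

    return _seeded_pick(candidates, all_ids, seed), IdRule.random


def resolve_coordinates(
    cluster: DuplicateCluster,
    geo_results: Mapping[str, GeoValidationResult] | None = None,
    precision_codes: Mapping[str, PrecisionCode] | None = None,
    seed: int = 0,
) -> tuple[OccurrenceRecord, CoordRule]:
    """Choose the member whose georeference the consensus record keeps."""
    members = cluster.members
    all_ids = cluster.member_ids
    candidates = [m for m in members if m.has_coordinates] or list(members)

    if geo_results:
        passing = [
            m for m in candidates
            if m.record_id in geo_results and geo_results[m.record_id].keep
        ]
        if (w := _unique(passing)) is not None:
            return w, CoordRule.passed_country_check
        if passing:
            candidates = passing

    personal = [m for m in candidates if m.expert_curated]
    if personal and len(personal) < len(candidates):
        candidates = personal
        if (w := _unique(candidates)) is not None:
            return w, CoordRule.personal

    if precision_codes:
        coded = [m for m in candidates if m.record_id in precision_codes]
        if coded:
            best = max(precision_codes[m.record_id].code for m in coded)
            winners = [m for m in coded if precision_codes[m.record_id].code == best]
            if (w := _unique(winners)) is not None:
                return w, CoordRule.highest_precision
            candidates = winners

    return _seeded_pick(candidates, all_ids, seed), CoordRule.random


# --- merging ---------------------------------------------------------------

_UNION_FIELDS = (
    "source_id",
    "verbatim_coordinates",
    "locality_text",
    "description_text",
    "collector",
    "collector_number",
    "collection_date",
)


def merge(
    cluster: DuplicateCluster,
    geo_results: Mapping[str, GeoValidationResult] | None = None,
    precision_codes: Mapping[str, PrecisionCode] | None = None,
    seed: int = 0,
) -> tuple[OccurrenceRecord, list[AuditEntry]]:
    """Merge a cluster into one consensus record.

    Identification fields come from the identification winner, coordinate
    fields from the coordinate winner; every other field is the first
    non-empty value over members in record-id order. The consensus keeps
    the smallest member record_id, so the result does not depend on input
    order.
    """
    id_winner, id_rule = resolve_identification(cluster, seed=seed)
    co_winner, co_rule = resolve_coordinates(cluster, geo_results, precision_codes, seed=seed)

    ordered = sorted(cluster.members, key=lambda m: m.record_id)

    def first_nonempty(attr: str):
        for m in ordered:
            v = getattr(m, attr)
            if v not in (None, ""):
                return v
        return getattr(ordered[0], attr)

    consensus = OccurrenceRecord(
        record_id=ordered[0].record_id,
        source_id=first_nonempty("source_id"),
        source_kind=id_winner.source_kind,
        taxon=id_winner.taxon,
        identification_date=id_winner.identification_date,
        country_code=co_winner.country_code,
        latitude=co_winner.latitude,
        longitude=co_winner.longitude,
        verbatim_coordinates=co_winner.verbatim_coordinates,
        locality_text=first_nonempty("locality_text"),
        description_text=first_nonempty("description_text"),
        collector=first_nonempty("collector"),
        collector_number=first_nonempty("collector_number"),
        collection_date=first_nonempty("collection_date"),
    )
    cluster.consensus = consensus
    cluster.id_resolution_rule_used = id_rule
    cluster.coord_resolution_rule_used = co_rule

    entries = [
        AuditEntry(
            consensus.record_id,
            Stage.dedup,
            Action.modified,
            f"consensus of {len(cluster)} duplicates (id:{id_rule.value}, coord:{co_rule.value})",
        )
    ]
    for m in ordered[1:]:
        entries.append(
            AuditEntry(m.record_id, Stage.dedup, Action.merged, f"merged into {consensus.record_id}")
        )
    return consensus, entries


def dedup_records(
    records: Sequence[OccurrenceRecord],
    geo_results: Mapping[str, GeoValidationResult] | None = None,
    precision_codes: Mapping[str, PrecisionCode] | None = None,
    key_config: KeyConfig | None = None,
    seed: int = 0,
    audit: AuditLog | None = None,
) -> tuple[list[OccurrenceRecord], list[DuplicateCluster]]:
    """Full deduplication pass: cluster, resolve, merge.

    Output size equals ``len(records) - sum(len(c) - 1 for c in clusters)``.
    Output order is by record_id, so shuffled inputs yield identical output.
    """
    clusters = find_duplicates(records, key_config)
    merged_away: set[str] = set()
    consensus_by_id: dict[str, OccurrenceRecord] = {}
    for cluster in clusters:
        consensus, entries = merge(cluster, geo_results, precision_codes, seed=seed)
        if audit is not None:
            audit.extend(entries)
        consensus_by_id[consensus.record_id] = consensus
        merged_away.update(set(cluster.member_ids) - {consensus.record_id})

    out = []
    for rec in sorted(records, key=lambda r: r.record_id):
        if rec.record_id in merged_away:
            continue
        out.append(consensus_by_id.get(rec.record_id, rec))
    return out, clusters
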