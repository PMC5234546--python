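"""Taxonomic name standardization against a local backbone table.

The backbone is a reference table of canonical names with a status
(accepted / synonym / unresolved) and a link from every synonym to its
accepted name. Submitted names are matched to their best backbone
candidate by normalized edit similarity, scored separately on genus and
epithet and combined into an overall score in [0, 1] (1 iff exact match).

From the matches, two review lists are built:

* **misspellings** — names matching an *accepted* backbone name with a
  score below 1 and no partial match (both genus and epithet matched):
  almost certainly typos of an accepted name.
* **potential synonyms** — (i) exact matches (score 1) whose matched
  backbone name differs from its accepted name, and (ii) inexact matches
  whose matched name differs from its accepted name.

Both lists are inputs to a human review step: the pipeline never corrects
or excludes a name without an explicit decision, supplied as a
name -> action table. Applying the decisions rewrites names to their
accepted canonical form and drops excluded names with audit entries;
the operation is idempotent.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from occurclean.datamodel import (
    Action,
    AuditLog,
    OccurrenceRecord,
    Stage,
    TaxonName,
)

__all__ = [
    "BackboneEntry",
    "Backbone",
    "NameMatch",
    "ResolvedAction",
    "match_name",
    "match_names",
    "build_misspelling_list",
    "build_synonym_list",
    "apply_standardization",
]

#: epithet similarity below which a genus-only hit counts as partial
PARTIAL_EPITHET_THRESHOLD = 0.75


class Status(str, enum.Enum):
    accepted = "accepted"
    synonym = "synonym"
    unresolved = "unresolved"


class ResolvedAction(str, enum.Enum):
    accept_as_is = "accept_as_is"
    correct_spelling = "correct_spelling"
    map_to_synonym_target = "map_to_synonym_target"
    exclude = "exclude"


@dataclass(frozen=True)
class BackboneEntry:
    name_id: str
    name: str
    rank: str
    status: Status
    accepted_name_id: str  # self-link when accepted


class Backbone:
    """In-memory backbone with validated synonym->accepted links."""

    def __init__(self, entries: Iterable[BackboneEntry]) -> None:
        self.by_id: dict[str, BackboneEntry] = {}
        self.by_name: dict[str, BackboneEntry] = {}
        for e in entries:
            self.by_id[e.name_id] = e
            self.by_name[_norm(e.name)] = e
        for e in self.by_id.values():
            if e.status is Status.accepted and e.accepted_name_id != e.name_id:
                raise ValueError(f"accepted entry {e.name_id} must self-link")
            if e.status is Status.synonym:
                target = self.by_id.get(e.accepted_name_id)
                if target is None:
                    raise ValueError(f"synonym {e.name_id} links to unknown id")
                if target.status is not Status.accepted:
                    raise ValueError(f"synonym {e.name_id} must link to an accepted entry")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Backbone":
        """Load from CSV with columns name_id, name, rank, status, accepted_name_id."""
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    BackboneEntry(
                        name_id=row["name_id"],
                        name=row["name"],
                        rank=row.get("rank", "species"),
                        status=Status(row["status"]),
                        accepted_name_id=row["accepted_name_id"],
                    )
                )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["name_id", "name", "rank", "status", "accepted_name_id"])
            for e in sorted(self.by_id.values(), key=lambda e: e.name_id):
                w.writerow([e.name_id, e.name, e.rank, e.status.value, e.accepted_name_id])

    def accepted_of(self, entry: BackboneEntry) -> BackboneEntry:
        return self.by_id[entry.accepted_name_id]

    def entries(self) -> list[BackboneEntry]:
        return list(self.by_id.values())


@dataclass
class NameMatch:
    submitted: str
    matched: BackboneEntry | None
    overall_score: float
    partial: bool
    accepted_name: str | None = None
    resolved_action: ResolvedAction | None = None


def _norm(name: str) -> str:
    return " ".join(name.split()).casefold()


def _sim(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _split(name: str) -> tuple[str, str]:
    """(genus, rest-of-name) of a normalized name string."""
    parts = _norm(name).split(" ", 1)
    return parts[0], parts[1] if len(parts) > 1 else ""


def score_pair(submitted: str, candidate: str) -> tuple[float, float, float]:
    """(overall, genus_sim, epithet_sim) between two name strings.

    The overall score is the length-weighted mean of the genus and
    epithet(s) similarities; 1.0 iff the normalized strings are equal.
    """
    g1, e1 = _split(submitted)
    g2, e2 = _split(candidate)
    sg, se = _sim(g1, g2), _sim(e1, e2)
    wg, we = max(len(g1), len(g2)), max(len(e1), len(e2))
    if wg + we == 0:
        return 0.0, 0.0, 0.0
    return (wg * sg + we * se) / (wg + we), sg, se


def match_name(submitted: str, backbone: Backbone) -> NameMatch:
    """Best backbone candidate for one submitted name.

    ``partial`` is set when the best candidate agrees on the genus but the
    epithet does not plausibly match (similarity below
    ``PARTIAL_EPITHET_THRESHOLD``).
    """
    if not submitted or not submitted.strip():
        raise ValueError("empty submitted name")
    exact = backbone.by_name.get(_norm(submitted))
    if exact is not None:
        accepted = backbone.accepted_of(exact) if exact.status is Status.synonym else exact
        return NameMatch(submitted, exact, 1.0, False, accepted.name)

    best: BackboneEntry | None = None
    best_score, best_sg, best_se = -1.0, 0.0, 0.0
    for e in sorted(backbone.by_id.values(), key=lambda e: e.name_id):
        overall, sg, se = score_pair(submitted, e.name)
        # prefer higher score; among ties prefer accepted entries
        key = (overall, e.status is Status.accepted)
        if key > (best_score, best is not None and best.status is Status.accepted):
            best, best_score, best_sg, best_se = e, overall, sg, se
    if best is None:
        return NameMatch(submitted, None, 0.0, False, None)
    partial = best_sg == 1.0 and best_se < PARTIAL_EPITHET_THRESHOLD
    accepted = backbone.accepted_of(best) if best.status is Status.synonym else best
    score = min(best_score, 1.0 - 1e-9)  # score 1 is reserved for exact matches
    return NameMatch(submitted, best, score, partial, accepted.name)


def match_names(names: Iterable[str], backbone: Backbone) -> list[NameMatch]:
    return [match_name(n, backbone) for n in names]


def build_misspelling_list(matches: Iterable[NameMatch]) -> list[NameMatch]:
    """Candidate misspellings: accepted-status match, score < 1, not partial."""
    return [
        m
        for m in matches
        if m.matched is not None
        and m.matched.status is Status.accepted
        and m.overall_score < 1.0
        and not m.partial
    ]


def build_synonym_list(matches: Iterable[NameMatch]) -> list[NameMatch]:
    """Candidate synonyms.

    (i) exact matches whose submitted name differs from the accepted name;
    (ii) inexact matches whose matched name differs from its accepted name.
    """
    out = []
    for m in matches:
        if m.matched is None or m.accepted_name is None:
            continue
        if m.overall_score == 1.0 and _norm(m.submitted) != _norm(m.accepted_name):
            out.append(m)
        elif m.overall_score < 1.0 and _norm(m.matched.name) != _norm(m.accepted_name):
            out.append(m)
    return out


def _retag(rec: OccurrenceRecord, accepted: str) -> OccurrenceRecord:
    parts = accepted.split()
    genus = parts[0] if parts else ""
    epithet = parts[1] if len(parts) > 1 else ""
    infra_rank = infra_epithet = ""
    if len(parts) == 4:
        infra_rank, infra_epithet = parts[2], parts[3]
    elif len(parts) == 3:
        infra_epithet = parts[2]
    return rec.copy(
        taxon=TaxonName(
            family=rec.taxon.family,
            genus=genus,
            species_epithet=epithet,
            infra_rank=infra_rank,
            infra_epithet=infra_epithet,
            authorship=rec.taxon.authorship,
        )
    )


def apply_standardization(
    records: Sequence[OccurrenceRecord],
    matches: Iterable[NameMatch],
    decisions: Mapping[str, ResolvedAction | str],
    backbone: Backbone,
    audit: AuditLog | None = None,
) -> list[OccurrenceRecord]:
    """Rewrite record names per reviewed decisions; drop excluded names.

    ``decisions`` maps a submitted name to an action. A decision naming a
    name absent from ``matches`` raises ``ValueError``. Records whose name
    carries no decision pass through unchanged.
    """
    by_submitted = {_norm(m.submitted): m for m in matches}
    actions: dict[str, ResolvedAction] = {}
    for name, action in decisions.items():
        key = _norm(name)
        if key not in by_submitted:
            raise ValueError(f"decision references unknown name: {name!r}")
        actions[key] = ResolvedAction(action)

    out: list[OccurrenceRecord] = []
    for rec in records:
        key = _norm(rec.taxon.canonical)
        action = actions.get(key)
        if action is None or action is ResolvedAction.accept_as_is:
            out.append(rec)
            continue
        m = by_submitted[key]
        if action is ResolvedAction.exclude:
            if audit is not None:
                audit.add(rec.record_id, Stage.taxonomy, Action.discarded, f"name excluded: {rec.taxon.canonical}")
            continue
        if action is ResolvedAction.correct_spelling:
            target = m.matched.name if m.matched else rec.taxon.canonical
        else:  # map_to_synonym_target
            target = m.accepted_name or rec.taxon.canonical
        if audit is not None:
            audit.add(rec.record_id, Stage.taxonomy, Action.modified, f"{rec.taxon.canonical} -> {target}")
        out.append(_retag(rec, target))
    return out
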