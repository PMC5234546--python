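"""Growth-habit inference from specimen label text.

Herbarium labels usually describe the plant ("Small tree 8 m", "Arbuste ou
petite liane"), so a species' growth habit can be inferred by keyword
tagging over all its specimens. Seven habit classes are distinguished:
tree, shrub, herb, liana, epiphyte, mycoheterotroph and parasitic.

Keywords are matched at word boundaries (so "street" never tags 'tree')
and case-sensitively per listed variant ("Tree", "tree", "Arbre", "arbre",
"Arbor", "arbor" for the tree class). A specimen contributes at most one
tag per class regardless of how many of that class's keywords occur —
presence, not occurrence count — so verbose labels do not dominate.

Per species the tags are summed over specimens; the class with the most
tags is the primary habit. If the primary class holds *less than half* of
all tags, the runner-up becomes a secondary habit (e.g. 20 tags of which
shrub 9 and liana 7: shrub is primary, and since 9 < 10 liana is
secondary). Ties are broken by a fixed class order. Erect palm-like plants
(palms, *Dracaena*, *Pandanus*) defeat keyword inference and are handled
by a species-level override table following the literature.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from occurclean.datamodel import OccurrenceRecord

__all__ = [
    "HabitClass",
    "CLASS_PRIORITY",
    "DEFAULT_KEYWORDS",
    "HabitProfile",
    "tag_record",
    "aggregate_habit",
    "profile_species",
    "reconcile_habits",
]


class HabitClass(str, enum.Enum):
    tree = "tree"
    shrub = "shrub"
    herb = "herb"
    liana = "liana"
    epiphyte = "epiphyte"
    mycoheterotroph = "mycoheterotroph"
    parasitic = "parasitic"


#: Fixed tie-break order, first wins.
CLASS_PRIORITY: tuple[HabitClass, ...] = (
    HabitClass.tree,
    HabitClass.shrub,
    HabitClass.liana,
    HabitClass.herb,
    HabitClass.epiphyte,
    HabitClass.parasitic,
    HabitClass.mycoheterotroph,
)

#: Per-class keyword variants, matched case-sensitively at word boundaries.
#: The tree list follows standard multilingual label vocabulary
#: (English/French/Latin); all lists are editable configuration.
DEFAULT_KEYWORDS: Mapping[HabitClass, tuple[str, ...]] = {
    HabitClass.tree: ("Tree", "tree", "Arbre", "arbre", "Arbor", "arbor"),
    HabitClass.shrub: ("Shrub", "shrub", "Arbuste", "arbuste", "Shrublet", "shrublet", "Frutex", "frutex"),
    HabitClass.herb: ("Herb", "herb", "Herbe", "herbe", "Herba", "herba", "Herbaceous", "herbaceous"),
    HabitClass.liana: ("Liana", "liana", "Liane", "liane", "Climber", "climber", "Vine", "vine"),
    HabitClass.epiphyte: ("Epiphyte", "epiphyte", "Epiphytic", "epiphytic", "Épiphyte", "épiphyte"),
    HabitClass.mycoheterotroph: ("Mycoheterotroph", "mycoheterotroph", "Mycoheterotrophic", "mycoheterotrophic", "Saprophyte", "saprophyte", "Saprophytic", "saprophytic"),
    HabitClass.parasitic: ("Parasite", "parasite", "Parasitic", "parasitic", "Hemiparasite", "hemiparasite"),
}


@dataclass
class HabitProfile:
    species: str
    tag_counts: dict[HabitClass, int]
    primary_habit: HabitClass | None
    secondary_habit: HabitClass | None

    @property
    def total_tags(self) -> int:
        return sum(self.tag_counts.values())


def _compile(keywords: Mapping[HabitClass, Sequence[str]]) -> dict[HabitClass, re.Pattern]:
    return {
        cls: re.compile(r"\b(?:" + "|".join(re.escape(k) for k in kws) + r")\b")
        for cls, kws in keywords.items()
        if kws
    }


def tag_record(
    description_text: str,
    keyword_config: Mapping[HabitClass, Sequence[str]] = DEFAULT_KEYWORDS,
) -> set[HabitClass]:
    """Habit classes whose keywords occur in the text (at most once each)."""
    if not description_text:
        return set()
    patterns = _compile(keyword_config)
    return {cls for cls, pat in patterns.items() if pat.search(description_text)}


def _ranked(counts: Mapping[HabitClass, int]) -> list[HabitClass]:
    prio = {cls: i for i, cls in enumerate(CLASS_PRIORITY)}
    present = [c for c in counts if counts[c] > 0]
    return sorted(present, key=lambda c: (-counts[c], prio[c]))


def aggregate_habit(species: str, tags_per_record: Iterable[set[HabitClass]]) -> HabitProfile:
    """Sum per-record tags into a species profile and apply the voting rule.

    primary = class with the most tags (ties by class order); a secondary
    habit is assigned iff the primary holds strictly less than half of all
    tags, and is the second-ranked class. Aggregation is order-invariant.
    """
    counts: Counter[HabitClass] = Counter()
    for tags in tags_per_record:
        counts.update(tags)
    total = sum(counts.values())
    if total == 0:
        return HabitProfile(species, {}, None, None)
    ranked = _ranked(counts)
    primary = ranked[0]
    secondary = None
    if counts[primary] * 2 < total and len(ranked) > 1:
        secondary = ranked[1]
    return HabitProfile(species, dict(counts), primary, secondary)


def profile_species(
    records: Sequence[OccurrenceRecord],
    keyword_config: Mapping[HabitClass, Sequence[str]] = DEFAULT_KEYWORDS,
    overrides: Mapping[str, HabitClass] | None = None,
) -> dict[str, HabitProfile]:
    """Habit profile for every species in ``records``.

    ``overrides`` pins the primary habit of species whose label vocabulary
    misleads keyword voting (palm-like plants), bypassing aggregation.
    """
    patterns = _compile(keyword_config)
    by_species: dict[str, list[set[HabitClass]]] = {}
    for rec in records:
        sp = rec.taxon.canonical
        if not sp:
            continue
        tags = {cls for cls, pat in patterns.items() if pat.search(rec.description_text or "")}
        by_species.setdefault(sp, []).append(tags)
    profiles = {}
    for sp, tag_sets in sorted(by_species.items()):
        if overrides and sp in overrides:
            profiles[sp] = HabitProfile(sp, {overrides[sp]: 1}, overrides[sp], None)
        else:
            profiles[sp] = aggregate_habit(sp, tag_sets)
    return profiles


def reconcile_habits(
    profile: HabitProfile, reference_habits: Mapping[str, HabitClass] | None = None
) -> tuple[HabitClass | None, str]:
    """Cross-check an inferred habit against a reference table.

    Returns ``(final_habit, flag)`` with flag one of ``confirmed``,
    ``mismatch`` (keeps the inferred habit but marks it for manual review)
    or ``unverified`` (no reference available).
    """
    if not reference_habits or profile.species not in reference_habits:
        return profile.primary_habit, "unverified"
    ref = reference_habits[profile.species]
    if ref == profile.primary_habit:
        return profile.primary_habit, "confirmed"
    return profile.primary_habit, "mismatch"
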