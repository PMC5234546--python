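"""Ground-truthed synthetic fixtures for every curation stage.

The generator builds a miniature study system — a tessellated block of
rectangular countries with an ocean to the west, a taxonomic backbone of
pseudo-Latin binomials with synonyms, and an occurrence table with errors
injected at configurable rates — and records the planted fate of every
record (its true name, true duplicate cluster, geo classification and
keep/discard verdict, cultivated/ex-situ status and true habit), so each
pipeline stage can be scored against known truth without any download.

Geometry is planar lat/lon rectangles evaluated with great-circle
distances; at fixture extents of a few degrees the distortion is far below
the kilometre scale of the tolerances being exercised. Error offsets are
placed well away from the 5 km decision boundary (typically 2-3 km for
keeps, >=20 km for discards) so planted verdicts are unambiguous.
"""

from __future__ import annotations

import math
import random
import string
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import edlib
import pandas as pd
from shapely.geometry import box

from occurclean.datamodel import OccurrenceRecord, SourceKind, TaxonName
from occurclean.dedup import DuplicateCluster
from occurclean.geovalidate import CountryPolygonSet
from occurclean.taxonomy import Backbone, BackboneEntry, Status
from occurclean.habit import DEFAULT_KEYWORDS, HabitClass

import datetime as _dt

__all__ = [
    "FixtureSpec",
    "Fixture",
    "SyntheticExternalSource",
    "make_polygons",
    "make_backbone",
    "make_records",
    "make_fixture",
    "make_resolution_clusters",
]

_DEG_KM = 111.19492664455873  # km per degree of latitude on the mean sphere


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study system.

    ``error_rates`` maps error class -> per-record probability:
    ``border_swap`` (point nudged <5 km across an adjacent border),
    ``sea_point`` (point offshore; half near-keep, half far-discard),
    ``far_error`` (point in a non-adjacent country), ``duplicate``
    (record emitted in 2-3 copies with reformatted collector strings),
    ``misspelling`` / ``synonym_use`` (name corrupted / replaced by its
    synonym), ``cultivated`` (fraction of *species* that are introduced),
    ``ex_situ_locality`` (locality replaced by a living-collection one).
    """

    n_countries: int = 4
    n_species: int = 30
    n_records: int = 500
    error_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "border_swap": 0.05,
            "sea_point": 0.03,
            "far_error": 0.03,
            "duplicate": 0.10,
            "misspelling": 0.05,
            "synonym_use": 0.05,
            "cultivated": 0.08,
            "ex_situ_locality": 0.02,
        }
    )
    seed: int = 0
    origin_lon: float = 10.0  # west (coastal) edge of the country block
    origin_lat: float = -2.0
    cell_deg: float = 2.0  # side of one rectangular country

    def __post_init__(self) -> None:
        for k, v in self.error_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"error rate {k}={v} outside [0, 1]")

    def rate(self, key: str) -> float:
        return self.error_rates.get(key, 0.0)


def _codes(n: int) -> list[str]:
    """Synthetic alpha-3 codes XAA, XAB, ... (X prefix avoids real ISO codes)."""
    letters = string.ascii_uppercase
    return [f"X{letters[i // 26]}{letters[i % 26]}" for i in range(n)]


def make_polygons(spec: FixtureSpec) -> CountryPolygonSet:
    """Tessellate ``n_countries`` rectangles into a near-square grid.

    The grid's west edge is a coastline (ocean for lon < origin_lon);
    adjacency is rook-style (shared edges, not corners).
    """
    if spec.n_countries < 2:
        raise ValueError("need at least 2 countries")
    ncols = math.ceil(math.sqrt(spec.n_countries))
    polygons = {}
    for i, code in enumerate(_codes(spec.n_countries)):
        r, c = divmod(i, ncols)
        x0 = spec.origin_lon + c * spec.cell_deg
        y0 = spec.origin_lat + r * spec.cell_deg
        polygons[code] = box(x0, y0, x0 + spec.cell_deg, y0 + spec.cell_deg)
    return CountryPolygonSet(polygons)


_SYLLABLES = [
    "ba", "co", "da", "fe", "gi", "ha", "ke", "la", "mo", "ne",
    "pa", "qui", "ra", "se", "ta", "vu", "xa", "zo", "lu", "mi",
]


def _make_word(rng: random.Random, n_syll: int, existing: list[str], min_dist: int = 3) -> str:
    """Pseudo-Latin word at edit distance >= min_dist from all existing words,
    so a planted single-letter typo always matches its own source uniquely."""
    while True:
        w = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))
        if all(edlib.align(w, e)["editDistance"] >= min_dist for e in existing):
            existing.append(w)
            return w


def make_backbone(spec: FixtureSpec) -> Backbone:
    """Backbone of ``n_species`` accepted binomials, each with one synonym.

    Synonym names reuse the pool of genera with their own epithets, like
    real synonymies arising from transfers and redescriptions.
    """
    rng = random.Random(spec.seed * 7919 + 11)
    genera_words: list[str] = []
    epithets: list[str] = []
    n_genera = max(2, spec.n_species // 3)
    genera = [_make_word(rng, 3, genera_words).capitalize() for _ in range(n_genera)]
    entries = []
    for i in range(spec.n_species):
        genus = genera[i % n_genera]
        name = f"{genus} {_make_word(rng, 3, epithets)}"
        aid = f"A{i:04d}"
        entries.append(BackboneEntry(aid, name, "species", Status.accepted, aid))
        syn = f"{rng.choice(genera)} {_make_word(rng, 3, epithets)}"
        entries.append(BackboneEntry(f"S{i:04d}", syn, "species", Status.synonym, aid))
    return Backbone(entries)


class SyntheticExternalSource:
    """Stand-in for a global occurrence provider (synthetic).

    Cultivated species report occurrences far outside the study region;
    native species report a handful inside it.
    """

    def __init__(self, cultivated: set[str], region_center: tuple[float, float], seed: int = 0):
        self.cultivated = set(cultivated)
        self.center = region_center
        self.seed = seed

    def lookup(self, species: str) -> list[tuple[float, float]]:
        rng = random.Random(f"{self.seed}|{species}")
        lat0, lon0 = self.center
        if species in self.cultivated:
            # a well-collected alien: many records on another continent
            return [(lat0 + rng.uniform(-5, 5), lon0 + 80 + rng.uniform(-5, 5)) for _ in range(50)]
        return [(lat0 + rng.uniform(-0.5, 0.5), lon0 + rng.uniform(-0.5, 0.5)) for _ in range(5)]


_COLLECTORS = [
    ("Okonkwo", "A."), ("Mbeki", "L.T."), ("Vandermeer", "J.J."), ("Traore", "S."),
    ("Lindqvist", "E."), ("Carvalho", "M.R."), ("Nkemelu", "D."), ("Fournier", "P."),
]

_HABIT_PHRASES = {
    HabitClass.tree: ["Large tree 25 m tall", "Small tree 8 m", "arbre de 15 m"],
    HabitClass.shrub: ["Shrub 2 m", "Arbuste dense de 2 m", "shrub with white flowers"],
    HabitClass.herb: ["Erect herb to 50 cm", "herbe rampante", "Annual herb"],
    HabitClass.liana: ["Liana climbing to canopy", "Petite liane", "woody climber"],
    HabitClass.epiphyte: ["Epiphyte on trunk", "epiphytic on branches"],
    HabitClass.parasitic: ["Parasitic on roots", "hemiparasite on branches"],
    HabitClass.mycoheterotroph: ["Achlorophyllous mycoheterotroph", "saprophyte of leaf litter"],
}

_EX_SITU_LOCALITIES = [
    "Botanical garden, Yaounde",
    "Jardin botanique de Kisantu",
    "Arboretum of the forestry school",
]


@dataclass
class Fixture:
    spec: FixtureSpec
    polygons: CountryPolygonSet
    backbone: Backbone
    records: list[OccurrenceRecord]
    truth: pd.DataFrame  # one row per record_id
    external_source: SyntheticExternalSource
    region: object  # shapely geometry of the study region


def _interior_point(rng: random.Random, x0, y0, cell, margin_deg=0.25):
    lon = rng.uniform(x0 + margin_deg, x0 + cell - margin_deg)
    lat = rng.uniform(y0 + margin_deg, y0 + cell - margin_deg)
    return lat, lon


def make_records(spec: FixtureSpec, polygons: CountryPolygonSet, backbone: Backbone) -> Fixture:
    """Generate the occurrence table and its ground-truth ledger."""
    rng = random.Random(spec.seed)
    ncols = math.ceil(math.sqrt(spec.n_countries))
    codes = _codes(spec.n_countries)
    cells = {code: divmod(i, ncols) for i, code in enumerate(codes)}

    accepted = sorted(
        (e for e in backbone.entries() if e.status is Status.accepted), key=lambda e: e.name_id
    )
    synonym_of = {
        e.accepted_name_id: e for e in backbone.entries() if e.status is Status.synonym
    }
    species_names = [e.name for e in accepted]
    n_cult = round(spec.rate("cultivated") * len(species_names))
    cultivated = set(rng.sample(species_names, n_cult)) if n_cult else set()
    true_habit = {name: rng.choice(list(_HABIT_PHRASES)) for name in species_names}

    records: list[OccurrenceRecord] = []
    truth_rows: list[dict] = []
    rid = 0

    def cell_origin(code):
        r, c = cells[code]
        return spec.origin_lon + c * spec.cell_deg, spec.origin_lat + r * spec.cell_deg

    for _ in range(spec.n_records):
        entry = rng.choice(accepted)
        species = entry.name
        home = rng.choice(codes)
        x0, y0 = cell_origin(home)
        lat, lon = _interior_point(rng, x0, y0, spec.cell_deg)
        geo_class, geo_keep = "Match", True

        u = rng.random()
        if u < spec.rate("border_swap") and polygons.adjacency[home]:
            # nudge 2-3 km across a shared edge into a neighbour: kept
            neighbour = rng.choice(sorted(polygons.adjacency[home]))
            lat, lon = _point_across_border(rng, spec, cells, home, neighbour, km=rng.uniform(2, 3))
            geo_class, geo_keep = "Neighbour", True
        elif u < spec.rate("border_swap") + spec.rate("sea_point"):
            km = rng.choice([2.0, 40.0])
            coastal = codes[0] if cells[home][1] != 0 else home  # a column-0 country
            for c in codes:
                if cells[c][1] == 0:
                    coastal = c
                    break
            home = coastal
            cx0, cy0 = cell_origin(home)
            lat = cy0 + spec.cell_deg / 2
            lon = spec.origin_lon - km / (_DEG_KM * math.cos(math.radians(lat)))
            geo_class, geo_keep = "Sea", km <= 5.0
        elif u < spec.rate("border_swap") + spec.rate("sea_point") + spec.rate("far_error"):
            non_adj = [c for c in codes if c != home and c not in polygons.adjacency[home]]
            if non_adj:
                other = rng.choice(non_adj)
                ox0, oy0 = cell_origin(other)
                lat, lon = _interior_point(rng, ox0, oy0, spec.cell_deg)
                geo_class, geo_keep = "Error", False

        name_error = "none"
        used_name = species
        v = rng.random()
        if v < spec.rate("misspelling"):
            genus, epithet = species.split(" ", 1)
            pos = rng.randrange(len(epithet))
            alt = rng.choice([c for c in "abcdefghilmnoprstu" if c != epithet[pos]])
            used_name = f"{genus} {epithet[:pos]}{alt}{epithet[pos + 1:]}"
            name_error = "misspelling"
        elif v < spec.rate("misspelling") + spec.rate("synonym_use"):
            used_name = synonym_of[entry.name_id].name
            name_error = "synonym_use"

        ex_situ = rng.random() < spec.rate("ex_situ_locality")
        locality = rng.choice(_EX_SITU_LOCALITIES) if ex_situ else f"forest near camp {rng.randrange(100)}"
        surname, initials = rng.choice(_COLLECTORS)
        habit = true_habit[species]
        description = rng.choice(_HABIT_PHRASES[habit])

        genus, _, rest = used_name.partition(" ")
        base = OccurrenceRecord(
            record_id=f"R{rid:06d}",
            source_id=rng.choice(["HERB1", "HERB2", "PERS1"]),
            source_kind=SourceKind.institutional,
            taxon=TaxonName(genus=genus, species_epithet=rest),
            identification_date=_dt.date(rng.randrange(1990, 2015), rng.randrange(1, 13), 1),
            country_code=home,
            latitude=round(lat, 6),
            longitude=round(lon, 6),
            locality_text=locality,
            description_text=description,
            collector=f"{surname}, {initials}",
            collector_number=str(rng.randrange(100, 9999)),
            collection_date=_dt.date(rng.randrange(1960, 2015), rng.randrange(1, 13), rng.randrange(1, 28)),
        )
        rid += 1

        copies = [base]
        cluster_id = ""
        if rng.random() < spec.rate("duplicate"):
            cluster_id = f"C{base.record_id}"
            n_extra = rng.choice([1, 1, 2])
            for _ in range(n_extra):
                dup = replace(
                    base,
                    record_id=f"R{rid:06d}",
                    source_id=rng.choice(["HERB1", "HERB2"]),
                    collector=f"{initials} {surname}",  # reformatted, same gathering
                )
                rid += 1
                copies.append(dup)

        for rec in copies:
            records.append(rec)
            truth_rows.append(
                {
                    "record_id": rec.record_id,
                    "true_species": species,
                    "used_name": used_name,
                    "name_error": name_error,
                    "geo_class": geo_class,
                    "geo_keep": geo_keep,
                    "cluster_id": cluster_id,
                    "cultivated": species in cultivated,
                    "ex_situ": ex_situ,
                    "true_habit": habit.value,
                }
            )

    nrows = math.ceil(spec.n_countries / ncols)
    region = box(
        spec.origin_lon,
        spec.origin_lat,
        spec.origin_lon + ncols * spec.cell_deg,
        spec.origin_lat + nrows * spec.cell_deg,
    )
    center = ((spec.origin_lat * 2 + nrows * spec.cell_deg) / 2, (spec.origin_lon * 2 + ncols * spec.cell_deg) / 2)
    source = SyntheticExternalSource(cultivated, center, seed=spec.seed)
    truth = pd.DataFrame(truth_rows).set_index("record_id")
    return Fixture(spec, polygons, backbone, records, truth, source, region)


def _point_across_border(rng, spec, cells, home, neighbour, km):
    """Point inside ``neighbour`` at ~``km`` from the edge shared with ``home``."""
    ncols = math.ceil(math.sqrt(spec.n_countries))
    rh, ch = cells[home]
    rn, cn = cells[neighbour]
    x0h = spec.origin_lon + ch * spec.cell_deg
    y0h = spec.origin_lat + rh * spec.cell_deg
    margin = 0.3
    if rh == rn:  # vertical shared edge
        edge_lon = x0h + spec.cell_deg if cn > ch else x0h
        lat = rng.uniform(y0h + margin, y0h + spec.cell_deg - margin)
        dlon = km / (_DEG_KM * math.cos(math.radians(lat)))
        lon = edge_lon + dlon if cn > ch else edge_lon - dlon
    else:  # horizontal shared edge
        edge_lat = y0h + spec.cell_deg if rn > rh else y0h
        lon = rng.uniform(x0h + margin, x0h + spec.cell_deg - margin)
        dlat = km / _DEG_KM
        lat = edge_lat + dlat if rn > rh else edge_lat - dlat
    return lat, lon


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """One-call fixture: polygons + backbone + records + truth."""
    spec = spec or FixtureSpec()
    polygons = make_polygons(spec)
    backbone = make_backbone(spec)
    return make_records(spec, polygons, backbone)


# --- cascade fixtures -------------------------------------------------------


def make_resolution_clusters(
    n_clusters: int, seed: int = 0
) -> list[tuple[DuplicateCluster, str | None, str | None]]:
    """Duplicate clusters with planted cascade winners.

    Returns ``(cluster, true_id_winner, true_coord_winner)`` triples, the
    truths being record_ids or None when the planted situation is
    undecidable (so the cascade must fall back to its seeded choice).
    Situations cycle through: personal-vs-institutional, dated
    identifications, rank differences, and fully tied clusters.
    """
    rng = random.Random(seed)
    out = []
    for k in range(n_clusters):
        kind = k % 4
        rid_a, rid_b = f"D{k:05d}a", f"D{k:05d}b"
        common = dict(
            collector="Harris, D.J.",
            collector_number=str(1000 + k),
            collection_date=_dt.date(2000, 1, 15),
            country_code="XAA",
            latitude=0.5,
            longitude=10.5,
        )
        t_full = TaxonName(genus="Genusa", species_epithet="plantula")
        if kind == 0:  # personal member wins both cascades
            a = OccurrenceRecord(rid_a, source_kind=SourceKind.institutional, taxon=t_full,
                                 identification_date=_dt.date(2010, 1, 1), **common)
            b = OccurrenceRecord(rid_b, source_kind=SourceKind.personal,
                                 taxon=TaxonName(genus="Genusa", species_epithet="alterum"),
                                 identification_date=_dt.date(2001, 1, 1), **common)
            truth_id = truth_co = rid_b
        elif kind == 1:  # most recent identification date
            a = OccurrenceRecord(rid_a, taxon=t_full, identification_date=_dt.date(2001, 1, 1), **common)
            b = OccurrenceRecord(rid_b, taxon=TaxonName(genus="Genusa", species_epithet="alterum"),
                                 identification_date=_dt.date(2010, 1, 1), **common)
            truth_id, truth_co = rid_b, None
        elif kind == 2:  # lowest (most specific) rank, no dates
            a = OccurrenceRecord(rid_a, taxon=TaxonName(genus="Genusa"), **common)
            b = OccurrenceRecord(
                rid_b,
                taxon=TaxonName(genus="Genusa", species_epithet="plantula",
                                infra_rank="subsp.", infra_epithet="minor"),
                **common,
            )
            truth_id, truth_co = rid_b, None
        else:  # fully tied -> seeded random fallback
            a = OccurrenceRecord(rid_a, taxon=t_full, **common)
            b = OccurrenceRecord(rid_b, taxon=t_full, **common)
            truth_id = truth_co = None
        cluster = DuplicateCluster(members=[a, b], match_key=("num", str(1000 + k), 2000))
        out.append((cluster, truth_id, truth_co))
    return out
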