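"""Core record types, CSV I/O and the audit log shared by all curation stages.

Records follow Darwin-Core-style semantics: one row is one documented
occurrence of a taxon at a place and time, usually backed by a herbarium
specimen. Coordinates are WGS84 decimal degrees. All text is UTF-8.

The audit log is the conservation ledger of the pipeline: every record that
a stage discards, modifies or merges leaves an :class:`AuditEntry`, so that
``records in == records kept + records discarded`` can be checked at every
stage.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "SourceKind",
    "TaxonName",
    "OccurrenceRecord",
    "AuditEntry",
    "AuditLog",
    "Stage",
    "Action",
    "read_records",
    "write_records",
    "COUNTRY_NAME_TO_ALPHA3",
    "normalize_country",
]


class SourceKind(str, enum.Enum):
    """Provenance class of a source dataset.

    ``personal`` datasets are compiled by individual experts and are given
    priority in the duplicate-merging cascades; ``institutional`` are large
    herbarium databases; ``silica`` and ``plot`` cover silica-gel
    collections and vegetation-plot inventories.
    """

    institutional = "institutional"
    personal = "personal"
    silica = "silica"
    plot = "plot"

    @property
    def expert_curated(self) -> bool:
        return self is SourceKind.personal


class Stage(str, enum.Enum):
    geo = "geo"
    taxonomy = "taxonomy"
    dedup = "dedup"
    flags = "flags"
    habit = "habit"


class Action(str, enum.Enum):
    kept = "kept"
    discarded = "discarded"
    modified = "modified"
    merged = "merged"


_RANK_ORDER = {"infraspecific": 0, "species": 1, "genus": 2, "family": 3, "unknown": 4}


@dataclass(frozen=True)
class TaxonName:
    """Structured scientific name; empty strings mean "not recorded"."""

    family: str = ""
    genus: str = ""
    species_epithet: str = ""
    infra_rank: str = ""
    infra_epithet: str = ""
    authorship: str = ""

    @property
    def rank(self) -> str:
        """Most specific rank the name reaches."""
        if self.infra_epithet:
            return "infraspecific"
        if self.species_epithet:
            return "species"
        if self.genus:
            return "genus"
        if self.family:
            return "family"
        return "unknown"

    @property
    def rank_order(self) -> int:
        """Integer rank, 0 = most specific. Lower wins in the dedup cascade."""
        return _RANK_ORDER[self.rank]

    @property
    def canonical(self) -> str:
        """Canonical name string without authorship (binomial or trinomial)."""
        parts = [p for p in (self.genus, self.species_epithet) if p]
        if self.infra_epithet:
            if self.infra_rank:
                parts.append(self.infra_rank)
            parts.append(self.infra_epithet)
        return " ".join(parts)


@dataclass
class OccurrenceRecord:
    """One occurrence row.

    ``latitude``/``longitude`` are ``None`` when absent or unparseable;
    a coordinate outside the valid WGS84 range is never stored — readers
    blank it and log an audit entry instead of failing.
    """

    record_id: str
    source_id: str = ""
    source_kind: SourceKind = SourceKind.institutional
    taxon: TaxonName = field(default_factory=TaxonName)
    identification_date: _dt.date | None = None
    country_code: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    verbatim_coordinates: str | None = None
    locality_text: str = ""
    description_text: str = ""
    collector: str = ""
    collector_number: str = ""
    collection_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of [-180, 180]")

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None

    @property
    def expert_curated(self) -> bool:
        return self.source_kind.expert_curated

    def copy(self, **changes) -> "OccurrenceRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class AuditEntry:
    record_id: str
    stage: Stage
    action: Action
    reason: str = ""


class AuditLog:
    """Append-only log of per-record curation decisions."""

    def __init__(self, entries: Iterable[AuditEntry] = ()) -> None:
        self.entries: list[AuditEntry] = list(entries)

    def add(self, record_id: str, stage: Stage | str, action: Action | str, reason: str = "") -> None:
        self.entries.append(AuditEntry(record_id, Stage(stage), Action(action), reason))

    def extend(self, entries: Iterable[AuditEntry]) -> None:
        self.entries.extend(entries)

    def discarded_ids(self, stage: Stage | str | None = None) -> set[str]:
        stage = Stage(stage) if stage is not None else None
        return {
            e.record_id
            for e in self.entries
            if e.action is Action.discarded and (stage is None or e.stage is stage)
        }

    def merged_ids(self) -> set[str]:
        return {e.record_id for e in self.entries if e.action is Action.merged}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AuditEntry]:
        return iter(self.entries)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "stage", "action", "reason"])
            for e in self.entries:
                w.writerow([e.record_id, e.stage.value, e.action.value, e.reason])


# --- country-name normalization -------------------------------------------

#: Name -> ISO-3166 alpha-3 lookup for the countries of continental tropical
#: Africa and its surroundings (plus a few common variant spellings).
COUNTRY_NAME_TO_ALPHA3: Mapping[str, str] = {
    "angola": "AGO", "benin": "BEN", "botswana": "BWA", "burkina faso": "BFA",
    "burundi": "BDI", "cameroon": "CMR", "cameroun": "CMR",
    "cape verde": "CPV", "cabo verde": "CPV",
    "central african republic": "CAF", "chad": "TCD", "tchad": "TCD",
    "congo": "COG", "republic of the congo": "COG", "congo-brazzaville": "COG",
    "democratic republic of the congo": "COD", "congo, the democratic republic of the": "COD",
    "congo-kinshasa": "COD", "zaire": "COD",
    "cote d'ivoire": "CIV", "ivory coast": "CIV",
    "djibouti": "DJI", "equatorial guinea": "GNQ", "eritrea": "ERI",
    "ethiopia": "ETH", "gabon": "GAB", "gambia": "GMB", "ghana": "GHA",
    "guinea": "GIN", "guinea-bissau": "GNB", "kenya": "KEN", "liberia": "LBR",
    "malawi": "MWI", "mali": "MLI", "mauritania": "MRT", "mozambique": "MOZ",
    "namibia": "NAM", "niger": "NER", "nigeria": "NGA", "rwanda": "RWA",
    "sao tome and principe": "STP", "senegal": "SEN", "sierra leone": "SLE",
    "somalia": "SOM", "south africa": "ZAF", "south sudan": "SSD",
    "sudan": "SDN", "tanzania": "TZA", "united republic of tanzania": "TZA",
    "togo": "TGO", "uganda": "UGA", "zambia": "ZMB", "zimbabwe": "ZWE",
}

_ALPHA3 = re.compile(r"^[A-Za-z]{3}$")


def normalize_country(value: str | None) -> str | None:
    """Return an ISO-3166 alpha-3 code for a country name or code, or None.

    Codes already in alpha-3 form pass through upper-cased; recognizable
    names are looked up; anything else is returned upper-cased as-is so
    that synthetic/non-ISO fixture codes survive round-trips.
    """
    if value is None:
        return None
    v = value.strip()
    if not v:
        return None
    key = v.lower().replace("’", "'")
    if key in COUNTRY_NAME_TO_ALPHA3:
        return COUNTRY_NAME_TO_ALPHA3[key]
    if _ALPHA3.match(v):
        return v.upper()
    return v.upper()


# --- CSV I/O ---------------------------------------------------------------

#: Canonical column order of the package's CSV dialect.
COLUMNS: tuple[str, ...] = (
    "record_id", "source_id", "source_kind",
    "family", "genus", "species_epithet", "infra_rank", "infra_epithet", "authorship",
    "identification_date", "country_code", "latitude", "longitude",
    "verbatim_coordinates", "locality_text", "description_text",
    "collector", "collector_number", "collection_date",
)

#: Default mapping from package field -> CSV header. Override entries to
#: load Darwin Core exports directly, e.g. {"record_id": "occurrenceID",
#: "latitude": "decimalLatitude", ...}.
DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in COLUMNS}

MANDATORY = ("record_id", "genus")

_DATE_PATTERNS = ("%Y-%m-%d", "%Y/%m/%d", "%d-%m-%Y", "%d/%m/%Y", "%Y")


def _parse_date(value: str) -> _dt.date | None:
    v = value.strip()
    if not v:
        return None
    for pat in _DATE_PATTERNS:
        try:
            return _dt.datetime.strptime(v, pat).date()
        except ValueError:
            continue
    return None  # unparseable -> absent, never a guess


def _parse_float(value: str) -> float | None:
    v = value.strip().replace(",", ".")
    if not v:
        return None
    try:
        return float(v)
    except ValueError:
        return None


def read_records(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    audit: AuditLog | None = None,
) -> list[OccurrenceRecord]:
    """Read occurrence records from a UTF-8 CSV file.

    One record is produced per data row; unparseable or out-of-range
    coordinates yield absent coordinates (with an audit entry when an
    ``audit`` log is given), never a failure. Missing mandatory columns
    (record id, taxon genus) raise ``ValueError`` naming the column.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    records: list[OccurrenceRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for f in MANDATORY:
            if mapping[f] not in header:
                raise ValueError(f"missing mandatory column: {mapping[f]!r}")

        def get(row: Mapping[str, str], f: str) -> str:
            return (row.get(mapping[f]) or "").strip()

        for row in reader:
            rid = get(row, "record_id")
            lat = _parse_float(get(row, "latitude"))
            lon = _parse_float(get(row, "longitude"))
            if lat is not None and not -90.0 <= lat <= 90.0:
                if audit is not None:
                    audit.add(rid, Stage.geo, Action.modified, "lat out of range")
                lat = None
            if lon is not None and not -180.0 <= lon <= 180.0:
                if audit is not None:
                    audit.add(rid, Stage.geo, Action.modified, "lon out of range")
                lon = None
            if (lat is None) != (lon is None):  # half a coordinate is no coordinate
                lat = lon = None
            kind_raw = get(row, "source_kind") or "institutional"
            try:
                kind = SourceKind(kind_raw)
            except ValueError:
                kind = SourceKind.institutional
            records.append(
                OccurrenceRecord(
                    record_id=rid,
                    source_id=get(row, "source_id"),
                    source_kind=kind,
                    taxon=TaxonName(
                        family=get(row, "family"),
                        genus=get(row, "genus"),
                        species_epithet=get(row, "species_epithet"),
                        infra_rank=get(row, "infra_rank"),
                        infra_epithet=get(row, "infra_epithet"),
                        authorship=get(row, "authorship"),
                    ),
                    identification_date=_parse_date(get(row, "identification_date")),
                    country_code=normalize_country(get(row, "country_code")) or None,
                    latitude=lat,
                    longitude=lon,
                    verbatim_coordinates=get(row, "verbatim_coordinates") or None,
                    locality_text=get(row, "locality_text"),
                    description_text=get(row, "description_text"),
                    collector=get(row, "collector"),
                    collector_number=get(row, "collector_number"),
                    collection_date=_parse_date(get(row, "collection_date")),
                )
            )
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # repr round-trips doubles exactly
    if isinstance(value, _dt.date):
        return value.isoformat()
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def record_to_row(rec: OccurrenceRecord) -> list[str]:
    t = rec.taxon
    return [
        _fmt(v)
        for v in (
            rec.record_id, rec.source_id, rec.source_kind,
            t.family, t.genus, t.species_epithet, t.infra_rank, t.infra_epithet, t.authorship,
            rec.identification_date, rec.country_code, rec.latitude, rec.longitude,
            rec.verbatim_coordinates, rec.locality_text, rec.description_text,
            rec.collector, rec.collector_number, rec.collection_date,
        )
    ]


def write_records(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    """Write records as UTF-8 CSV in the canonical column order.

    Output is byte-stable for a given input and round-trips through
    :func:`read_records` field-wise losslessly.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(COLUMNS)
        for rec in records:
            w.writerow(record_to_row(rec))
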