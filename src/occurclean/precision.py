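"""Ordinal coordinate precision coding (codes 1-8).

A stored coordinate pair carries an implicit granularity: a collector who
wrote "4N 12E" on the label localized the gathering to a whole degree
(~110 km), one who wrote 4°15.123'N to a thousandth of a decimal minute
(~2 m). The code summarizes that granularity on an 8-step ordinal scale:

====  ==============================  ===================
code  criterion                       ~uncertainty
====  ==============================  ===================
1     degree only                     ~110 km
2     15-minute (quarter degree)      ~30 km
3     5-minute                        ~10 km
4     2-minute                        ~4 km
5     whole minute                    ~2 km
6     1/10 decimal minute             ~200 m
7     1/100 decimal minute            ~20 m
8     1/1000 decimal minute           ~2 m
====  ==============================  ===================

When a verbatim sexagesimal string is available the code is derived from
its stated granularity; otherwise it is inferred from the decimal degrees.
In both paths the record-level code is the coarsest granularity of which
*both* components are integer multiples: a latitude of 15' is consistent
with quarter-degree recording, but paired with a longitude of 33' the pair
as a whole must have been recorded to the minute (code 5).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from occurclean.datamodel import OccurrenceRecord

__all__ = ["PrecisionCode", "UNCERTAINTY_KM", "assign_precision", "assign_precision_records"]

#: code -> approximate positional uncertainty in km.
UNCERTAINTY_KM = {1: 110.0, 2: 30.0, 3: 10.0, 4: 4.0, 5: 2.0, 6: 0.2, 7: 0.02, 8: 0.002}

#: code -> granularity in degrees, coarsest first.
_GRANULARITY_DEG = [
    (1, Fraction(1)),            # 1 degree
    (2, Fraction(1, 4)),         # 15 minutes
    (3, Fraction(1, 12)),        # 5 minutes
    (4, Fraction(1, 30)),        # 2 minutes
    (5, Fraction(1, 60)),        # 1 minute
    (6, Fraction(1, 600)),       # 0.1 minute
    (7, Fraction(1, 6000)),      # 0.01 minute
    (8, Fraction(1, 60000)),     # 0.001 minute
]

_TOL = 1e-9


@dataclass(frozen=True)
class PrecisionCode:
    code: int
    approx_uncertainty_km: float

    @classmethod
    def of(cls, code: int) -> "PrecisionCode":
        return cls(code, UNCERTAINTY_KM[code])


# one sexagesimal component: degrees, optional minutes (possibly decimal),
# hemisphere letter; separators are flexible (° ' " or whitespace).
_COMPONENT = re.compile(
    r"""(?P<deg>\d{1,3})\s*[°d:\s]?\s*
        (?:(?P<min>\d{1,2}(?:[.,]\d+)?)\s*['′m]?\s*)?
        (?P<hemi>[NSEWnsew])""",
    re.VERBOSE,
)


def _parse_verbatim(verbatim: str) -> list[tuple[Fraction, int]] | None:
    """Parse a verbatim coordinate string into per-component
    (minutes as exact fraction, number of minute decimals); None on failure.

    A component without a minute token is reported as (0 minutes, -1
    decimals) so that degree-only records stay distinguishable from
    records whose minutes happen to be zero.
    """
    comps = []
    for m in _COMPONENT.finditer(verbatim):
        if m.group("min") is None:
            comps.append((Fraction(0), -1))
        else:
            raw = m.group("min").replace(",", ".")
            decimals = len(raw.split(".")[1]) if "." in raw else 0
            comps.append((Fraction(raw), decimals))
    if len(comps) != 2:
        return None
    return comps


def _code_from_verbatim(comps: list[tuple[Fraction, int]]) -> int:
    minutes = [c[0] for c in comps]
    decimals = max(c[1] for c in comps)
    if decimals == -1:
        return 1  # degrees only
    if decimals > 0:
        return min(8, 5 + decimals)  # 1/2/3+ decimal minutes -> 6/7/8
    # integer minutes: shared coarsest granularity of both components
    for code, step in ((2, 15), (3, 5), (4, 2)):
        if all(m % step == 0 for m in minutes):
            return code
    return 5


def _decimal_component_codes(lat: float, lon: float) -> int | None:
    """Coarsest code whose granularity divides both decimal coordinates,
    or None when not even the finest granularity matches."""
    for code, g in _GRANULARITY_DEG:
        step = float(g)
        ok = True
        for v in (lat, lon):
            v = round(abs(v), 10)  # defeat binary float artifacts
            q = v / step
            if abs(q - round(q)) * step > _TOL:
                ok = False
                break
        if ok:
            return code
    return None


def assign_precision(
    verbatim: str | None, lat: float, lon: float
) -> PrecisionCode:
    """Assign the precision code for one coordinate pair.

    A parseable verbatim sexagesimal string wins; otherwise the code is
    inferred from the decimal degrees as the coarsest tabulated granularity
    of which both components are integer multiples (tolerance 1e-9). True
    decimal-degree values matching no granularity are coded 8 — the scale
    has no finer class.
    """
    if verbatim:
        comps = _parse_verbatim(verbatim)
        if comps is not None:
            return PrecisionCode.of(_code_from_verbatim(comps))
        # unparseable verbatim: fall through to decimal inference
    code = _decimal_component_codes(lat, lon)
    return PrecisionCode.of(code if code is not None else 8)


def assign_precision_records(
    records: Iterable[OccurrenceRecord],
) -> dict[str, PrecisionCode]:
    """Precision code per record id; records without coordinates are skipped."""
    out: dict[str, PrecisionCode] = {}
    for rec in records:
        if rec.has_coordinates:
            out[rec.record_id] = assign_precision(
                rec.verbatim_coordinates, rec.latitude, rec.longitude
            )
    return out
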