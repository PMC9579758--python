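"""Local/traded classification, element-origin association, and
qualitative date conversion.

A specimen assigned to the western Atlantic is by definition traded (for
the London/Iberian sites studied, any western-Atlantic fish crossed the
ocean). An eastern specimen is classified from its haplogroup share and
putative origin: local when the origin lies in the near-catchment set
(North Sea, Irish Sea by default), traded when it lies in the
distant-water set (Northeast Arctic, Iceland, the Norwegian Coast, ...),
and unclassified when the strongest haplogroup share falls below the
confidence threshold (0.75) or the putative origins span both sets.

The element-origin association is Fisher's exact test on the 2x2 table of
bone element (cranial / postcranial) against origin (local / traded);
unclassified specimens are excluded from the table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import fisher_exact

from .affinity import AffinityResult
from .cluster import WESTERN

DEFAULT_GROUP_THRESHOLD = 0.75
DEFAULT_LOCAL_POPULATIONS = frozenset({"North Sea", "Irish Sea"})

LOCAL, TRADED, UNCLASSIFIED = "local", "traded", "unclassified"


@dataclass
class TradeClassification:
    specimen_id: str
    status: str  # local | traded | unclassified
    basis: str


@dataclass
class DateInterval:
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError(f"empty date interval [{self.start_year}, {self.end_year}]")


@dataclass
class ContingencyTable2x2:
    """Counts a..d laid out as [[a, b], [c, d]]: rows cranial/postcranial,
    columns local/traded."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def classify_trade_status(
    affinity: AffinityResult | None,
    assigned_cluster: str,
    group_threshold: float = DEFAULT_GROUP_THRESHOLD,
    local_populations: frozenset[str] = DEFAULT_LOCAL_POPULATIONS,
) -> TradeClassification:
    """Classify one specimen as local, traded, or unclassified.

    ``assigned_cluster`` is the genome-wide cluster label; ``affinity`` may
    be None when the specimen never reached specific assignment.
    """
    sid = affinity.specimen_id if affinity is not None else "?"
    if assigned_cluster == WESTERN:
        return TradeClassification(sid, TRADED, "western Atlantic genome-wide assignment")
    if affinity is None or not affinity.haplogroup:
        return TradeClassification(sid, UNCLASSIFIED, "no haplogroup shares available")
    top_group, top_share = max(affinity.haplogroup.items(), key=lambda kv: kv[1])
    if top_share < group_threshold:
        return TradeClassification(
            sid,
            UNCLASSIFIED,
            f"strongest haplogroup ({top_group}) at {top_share:.2f} below "
            f"{group_threshold:.2f}",
        )
    origins = set(affinity.putative_origin)
    if not origins:
        return TradeClassification(sid, UNCLASSIFIED, "no putative origin")
    basis = f"{top_group} {top_share:.2f}; origin {', '.join(affinity.putative_origin)}"
    if origins <= local_populations:
        return TradeClassification(sid, LOCAL, basis)
    if origins.isdisjoint(local_populations):
        return TradeClassification(sid, TRADED, basis)
    return TradeClassification(sid, UNCLASSIFIED, f"ambiguous origin spanning local and distant: {basis}")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value under the conventional
    probability-mass ordering (tables at least as extreme are those with
    hypergeometric probability <= the observed table's)."""
    _, p = fisher_exact(table.as_list(), alternative="two-sided")
    return float(p)


def test_element_origin_association(
    records: Iterable[tuple[str, TradeClassification]],
) -> tuple[ContingencyTable2x2, float]:
    """Build the cranial/postcranial x local/traded table and test it.

    Unclassified specimens are dropped. A table missing a whole row or
    column (fewer than two observed elements or statuses) is degenerate and
    raises.
    """
    cells = {("cranial", LOCAL): 0, ("cranial", TRADED): 0,
             ("postcranial", LOCAL): 0, ("postcranial", TRADED): 0}
    elements: set[str] = set()
    statuses: set[str] = set()
    for element, classification in records:
        if classification.status not in (LOCAL, TRADED):
            continue
        if element not in ("cranial", "postcranial"):
            raise ValueError(f"unknown bone element {element!r}")
        cells[(element, classification.status)] += 1
        elements.add(element)
        statuses.add(classification.status)
    if len(elements) < 2 or len(statuses) < 2:
        raise ValueError("degenerate table: need both elements and both statuses observed")
    table = ContingencyTable2x2(
        cells[("cranial", LOCAL)], cells[("cranial", TRADED)],
        cells[("postcranial", LOCAL)], cells[("postcranial", TRADED)],
    )
    return table, fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# qualitative dates

_ORDINALS = {
    "first": 1, "second": 2, "third": 3, "fourth": 4, "fifth": 5,
    "sixth": 6, "seventh": 7, "eighth": 8, "ninth": 9, "tenth": 10,
    "eleventh": 11, "twelfth": 12, "thirteenth": 13, "fourteenth": 14,
    "fifteenth": 15, "sixteenth": 16, "seventeenth": 17, "eighteenth": 18,
    "nineteenth": 19, "twentieth": 20, "twentyfirst": 21,
}

_QUALIFIERS = ("early", "mid", "late")

_RANGE_SPLIT = re.compile(r"\s*(?:–|—|-|\bto\b)\s*")


class DateParseError(ValueError):
    pass


def _parse_century_phrase(phrase: str) -> DateInterval:
    tokens = phrase.split()
    qualifier = None
    if tokens and tokens[0] in _QUALIFIERS:
        qualifier = tokens[0]
        tokens = tokens[1:]
    if not tokens:
        raise DateParseError(f"missing century ordinal in {phrase!r}")
    ordinal = tokens[0]
    if ordinal not in _ORDINALS:
        raise DateParseError(f"unrecognized century ordinal {ordinal!r}")
    rest = tokens[1:]
    if rest and rest[0] not in ("century", "centuries"):
        raise DateParseError(f"unexpected token {rest[0]!r} after century ordinal")
    n = _ORDINALS[ordinal]
    start = (n - 1) * 100
    if qualifier == "early":
        return DateInterval(start, start + 50)
    if qualifier == "mid":
        return DateInterval(start + 25, start + 75)
    if qualifier == "late":
        return DateInterval(start + 50, start + 100)
    return DateInterval(start, start + 100)


def parse_qualitative_date(text: str) -> DateInterval:
    """Convert qualitative date text into a calendar-year interval.

    A century N spans (N-1)*100 to N*100 CE; 'early' keeps the first half
    ('00-'50), 'mid' keeps '25-'75, 'late' the second half ('50-'00).
    Ranges joined by a dash or 'to' take the union of the endpoints, so
    "late fifteenth-early sixteenth centuries" gives 1450-1550.
    """
    cleaned = text.strip().lower()
    cleaned = re.sub(r"^(ca\.?|circa|c\.)\s+", "", cleaned)
    # protect the only hyphenated ordinal from the range splitter
    cleaned = cleaned.replace("twenty-first", "twentyfirst")
    if not cleaned:
        raise DateParseError("empty date text")
    parts = [p for p in _RANGE_SPLIT.split(cleaned) if p]
    intervals = [_parse_century_phrase(p) for p in parts]
    return DateInterval(
        min(iv.start_year for iv in intervals),
        max(iv.end_year for iv in intervals),
    )
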