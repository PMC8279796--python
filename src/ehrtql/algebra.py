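"""Pure per-patient temporal algebra over canonical interval sets.

Each operation takes and returns :class:`~ehrtql.model.IntervalSet` values and
is calendar-free: durations use fixed-length units (1 MONTH = 30 days,
1 YEAR = 365 days).  SEQUENCE windows are anchored at the start day of the
starred interval and test the start day of the non-starred operand's
intervals; window boundaries are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .model import EMPTY_SET, Interval, IntervalSet, coalesce

# Star position in SEQUENCE: which operand's intervals are returned.
STAR_FIRST = 1
STAR_SECOND = 2

PRESENCE = "presence"
ABSENCE = "absence"

#: Fixed-length duration units, in days.
UNIT_DAYS = {
    "DAY": 1, "DAYS": 1,
    "MONTH": 30, "MONTHS": 30,
    "YEAR": 365, "YEARS": 365,
}


def duration_days(amount: int, unit: Optional[str] = None) -> int:
    """Convert a signed duration to days; bare numbers are days."""
    if unit is None:
        return int(amount)
    try:
        return int(amount) * UNIT_DAYS[unit.upper()]
    except KeyError:
        raise ValueError(f"unknown duration unit {unit!r}") from None


@dataclass(frozen=True)
class WindowModifier:
    """A ``+(lo, hi)`` (presence) or ``-(lo, hi)`` (absence) SEQUENCE window.

    ``lo``/``hi`` are signed day offsets relative to the start of a starred
    interval; ``None`` means unbounded (the MAX sentinel).
    """

    mode: str  # PRESENCE or ABSENCE
    lo: Optional[int]
    hi: Optional[int]

    def __post_init__(self):
        if self.mode not in (PRESENCE, ABSENCE):
            raise ValueError(f"bad window mode {self.mode!r}")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"window bounds inverted: ({self.lo}, {self.hi})")


def t_union(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Coalesced union — intervals where any operand was true."""
    if not sets:
        raise ValueError("UNION needs at least one operand")
    if len(sets) == 1:
        return sets[0]
    spans: List[Interval] = []
    for s in sets:
        spans.extend(s.spans)
    return coalesce(spans)


def _intersect2(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    out: List[Interval] = []
    ai = bi = 0
    aspans, bspans = a.spans, b.spans
    while ai < len(aspans) and bi < len(bspans):
        s1, e1 = aspans[ai]
        s2, e2 = bspans[bi]
        lo, hi = max(s1, s2), min(e1, e2)
        if lo < hi:
            out.append(Interval(lo, hi))
        if e1 <= e2:
            ai += 1
        else:
            bi += 1
    # intersection of canonical sets stays canonical (no adjacency can appear)
    return IntervalSet(tuple(out))


def t_intersect(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Intervals where all operands were simultaneously true."""
    if not sets:
        raise ValueError("INTERSECT needs at least one operand")
    acc = sets[0]
    for s in sets[1:]:
        if not acc:
            return EMPTY_SET
        acc = _intersect2(acc, s)
    return acc


def t_invert(x: IntervalSet, span: Interval) -> IntervalSet:
    """Complement of ``x`` within the patient's observation span."""
    clipped = _intersect2(x, IntervalSet((span,)))
    out: List[Interval] = []
    cursor = span.start
    for s, e in clipped:
        if cursor < s:
            out.append(Interval(cursor, s))
        cursor = e
    if cursor < span.end:
        out.append(Interval(cursor, span.end))
    return IntervalSet(tuple(out))


def t_sequence(a: IntervalSet, b: IntervalSet, star: int,
               window: Optional[WindowModifier] = None) -> IntervalSet:
    """Starred intervals that stand in the requested order/window relation.

    Without a window the non-starred interval must start strictly before
    (star on the second operand) or strictly after (star on the first) the
    starred one.  A presence window keeps starred intervals with some
    non-starred start in ``[start+lo, start+hi]``; an absence window keeps
    those with none.
    """
    if star not in (STAR_FIRST, STAR_SECOND):
        raise ValueError("star must be STAR_FIRST or STAR_SECOND")
    starred, other = (a, b) if star == STAR_FIRST else (b, a)
    other_starts = [iv.start for iv in other]
    kept: List[Interval] = []
    for iv in starred:
        if window is None:
            if star == STAR_SECOND:
                ok = any(n < iv.start for n in other_starts)
            else:
                ok = any(n > iv.start for n in other_starts)
        else:
            lo = iv.start + window.lo if window.lo is not None else None
            hi = iv.start + window.hi if window.hi is not None else None
            hit = any((lo is None or n >= lo) and (hi is None or n <= hi)
                      for n in other_starts)
            ok = hit if window.mode == PRESENCE else not hit
        if ok:
            kept.append(iv)
    # a subset of a canonical set is canonical
    return IntervalSet(tuple(kept))


def t_count(x: IntervalSet, min_n: int, max_n: Optional[int]) -> IntervalSet:
    """``x`` unchanged when its number of disjoint intervals is within bounds.

    Counting is of coalesced disjoint intervals, not raw source rows: two
    codes on the same day contribute a single occurrence.  ``max_n=None`` is
    the MAX sentinel.
    """
    if min_n < 0:
        raise ValueError("COUNT minimum must be >= 0")
    if max_n is not None and min_n > max_n:
        raise ValueError(f"COUNT bounds inverted: ({min_n}, {max_n})")
    n = len(x)
    if n >= min_n and (max_n is None or n <= max_n):
        return x
    return EMPTY_SET


def t_first_mention(x: IntervalSet) -> IntervalSet:
    """The single earliest interval of ``x`` (empty stays empty)."""
    first = x.first()
    return IntervalSet((first,)) if first is not None else EMPTY_SET


def t_no_history_of(x: IntervalSet, span: Interval) -> IntervalSet:
    """The part of the timeline before ``x`` first occurs.

    The whole span when ``x`` is empty; empty when ``x`` starts at or before
    the span.
    """
    first = x.first()
    if first is None:
        return IntervalSet((span,))
    if first.start <= span.start:
        return EMPTY_SET
    return IntervalSet((Interval(span.start, first.start),))


def t_never_had(x: IntervalSet, span: Interval) -> IntervalSet:
    """The whole span when ``x`` is empty, else nothing."""
    return EMPTY_SET if x else IntervalSet((span,))
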