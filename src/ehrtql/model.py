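"""Core data model: day-resolution intervals, clinical events, patient objects,
and the indexed in-memory patient store.

Every value a temporal query produces for a patient is an :class:`IntervalSet` —
a canonical (sorted, disjoint, non-adjacent) sequence of half-open day
intervals.  Days are integer offsets from a fixed epoch (1900-01-01), which
makes adjacency and merging unambiguous at the day resolution of typical
date-stamped clinical records; a point event on day ``d`` is stored as
``[d, d+1)``.

The :class:`PatientStore` groups all of one patient's data into a single
:class:`PatientObject` and maintains a feature index (feature key → set of
patient ids) so that a query evaluator can cheaply determine which patients
could possibly match before doing a full per-patient evaluation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, NamedTuple, Optional, Tuple

from .errors import DataLoadError

EPOCH = _dt.date(1900, 1, 1)
_EPOCH_ORD = EPOCH.toordinal()

#: Recognised feature-key namespaces.
NAMESPACES = (
    "ICD9", "ICD10", "CPT", "RX", "ATC", "LOINC", "TEXT",
    "GENDER", "RACE", "VISIT", "NOTE_TYPE",
)


def date_to_day(d: _dt.date) -> int:
    """Integer day index of a calendar date (days since 1900-01-01)."""
    return d.toordinal() - _EPOCH_ORD


def day_to_date(day: int) -> _dt.date:
    """Calendar date for an integer day index."""
    return _dt.date.fromordinal(day + _EPOCH_ORD)


class Interval(NamedTuple):
    """Half-open day interval ``[start, end)`` with ``start < end``."""

    start: int
    end: int

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"[{self.start},{self.end})"


class FeatureKey(NamedTuple):
    """A namespaced clinical feature, e.g. ``(ICD9, "434.91")``.

    Codes compare by exact string match within a namespace.
    """

    namespace: str
    code: str


class IntervalSet:
    """Canonical set of half-open day intervals.

    Instances are immutable.  The constructor trusts its input to already be
    canonical; use :func:`coalesce` to build one from arbitrary intervals.
    """

    __slots__ = ("_spans",)

    def __init__(self, spans: Tuple[Interval, ...] = ()):
        self._spans = spans

    @property
    def spans(self) -> Tuple[Interval, ...]:
        return self._spans

    def __bool__(self) -> bool:
        return bool(self._spans)

    def __len__(self) -> int:
        return len(self._spans)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._spans)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._spans == other._spans

    def __hash__(self) -> int:
        return hash(self._spans)

    def __repr__(self) -> str:
        return "IntervalSet(" + ", ".join(map(repr, self._spans)) + ")"

    def first(self) -> Optional[Interval]:
        """Earliest interval, or None when empty."""
        return self._spans[0] if self._spans else None

    def total_days(self) -> int:
        return sum(e - s for s, e in self._spans)

    def days(self) -> set:
        """The set of integer days covered — the day-membership oracle view.

        An IntervalSet is fully characterised by this set; only use it on
        spans of a few thousand days.
        """
        out: set = set()
        for s, e in self._spans:
            out.update(range(s, e))
        return out


EMPTY_SET = IntervalSet()


def coalesce(intervals: Iterable[Tuple[int, int]]) -> IntervalSet:
    """Canonicalise arbitrary intervals: sort, merge overlaps and adjacency.

    Total covered days are preserved.  Raises ``ValueError`` for any interval
    with ``start >= end``.
    """
    items: List[Tuple[int, int]] = []
    for s, e in intervals:
        if s >= e:
            raise ValueError(f"invalid interval [{s},{e}): start must be < end")
        items.append((int(s), int(e)))
    if not items:
        return EMPTY_SET
    items.sort()
    merged: List[Interval] = []
    cur_s, cur_e = items[0]
    for s, e in items[1:]:
        if s <= cur_e:  # overlap or adjacency under the half-open convention
            if e > cur_e:
                cur_e = e
        else:
            merged.append(Interval(cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append(Interval(cur_s, cur_e))
    return IntervalSet(tuple(merged))


@dataclass(slots=True)
class Event:
    """One dated clinical fact on a patient timeline.

    ``value`` is set for measurements (LOINC), ``flags`` only for TEXT
    mentions (subset of {"NEGATED", "FAMILY_HISTORY"}).  ``original`` is False
    for events added by ontology expansion (ancestor diagnosis codes, ATC
    drug-class codes).
    """

    key: FeatureKey
    interval: Interval
    value: Optional[float] = None
    flags: FrozenSet[str] = frozenset()
    original: bool = True


@dataclass
class PatientObject:
    """One patient's full record.

    Demographics are attributes (not events); ``span`` is the observation
    period, the universe for timeline inversion and "no history" semantics.
    ``key_index`` maps every feature key present (including expansion keys)
    to that key's events ordered by start day.
    """

    patient_id: str
    birth_day: int
    gender: str
    race: str
    span: Interval
    events: List[Event] = field(default_factory=list)
    key_index: Dict[FeatureKey, List[Event]] = field(default_factory=dict, repr=False)

    def rebuild_key_index(self) -> None:
        idx: Dict[FeatureKey, List[Event]] = {}
        for ev in self.events:
            idx.setdefault(ev.key, []).append(ev)
        for evs in idx.values():
            evs.sort(key=lambda ev: ev.interval)
        self.key_index = idx

    def keys(self) -> Iterable[FeatureKey]:
        return self.key_index.keys()


@dataclass
class PatientStore:
    """Immutable collection of patient objects plus the feature index.

    The index maps every event-derived feature key to the exact set of
    patients holding ≥1 event with that key.  Demographic postings
    (GENDER/RACE with lower-cased values) are included as well so that a
    candidate filter can prune on demographics, mirroring index-first
    filtering on features such as "male patients over 65".
    """

    patients: Dict[str, PatientObject]
    index: Dict[FeatureKey, FrozenSet[str]]
    shards: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patients)

    def all_ids(self) -> FrozenSet[str]:
        return frozenset(self.patients)

    def lookup(self, key: FeatureKey) -> FrozenSet[str]:
        """Patients having the key; empty set for unknown keys (never raises)."""
        return self.index.get(key, frozenset())


def demographic_keys(patient: PatientObject) -> Tuple[FeatureKey, ...]:
    """Index postings derived from patient attributes (values lower-cased)."""
    keys = []
    if patient.gender:
        keys.append(FeatureKey("GENDER", patient.gender.lower()))
    if patient.race:
        keys.append(FeatureKey("RACE", patient.race.lower()))
    return tuple(keys)


def build_store(patients: Iterable[PatientObject], shards: Optional[List[str]] = None) -> PatientStore:
    """Group patient objects into an indexed store.

    Raises :class:`DataLoadError` on duplicate patient ids.  Patients whose
    ``key_index`` is empty but have events get their index rebuilt.
    """
    by_id: Dict[str, PatientObject] = {}
    for p in patients:
        if p.patient_id in by_id:
            raise DataLoadError(f"duplicate patient_id: {p.patient_id!r}")
        if p.events and not p.key_index:
            p.rebuild_key_index()
        by_id[p.patient_id] = p

    raw: Dict[FeatureKey, set] = {}
    for pid, p in by_id.items():
        for key in p.key_index:
            raw.setdefault(key, set()).add(pid)
        for key in demographic_keys(p):
            raw.setdefault(key, set()).add(pid)
    index = {k: frozenset(v) for k, v in raw.items()}
    return PatientStore(patients=by_id, index=index, shards=list(shards or []))


def index_lookup(store: PatientStore, key: FeatureKey) -> FrozenSet[str]:
    """Set of patient ids holding ``key``; empty for unknown keys."""
    return store.lookup(key)
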