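"""Independent day-membership interpreter.

A canonical interval set over a bounded span is fully characterised by the
set of integer days it covers; maximal runs of consecutive days recover its
intervals.  This module re-implements every query construct directly on
Python day sets, scanning the raw event list rather than the key index, and
shares no code with the interval algebra or the engine.  It exists as a
second, simple semantics against which the fast implementation is checked,
and as the generator's self-verification of its ground-truth tables.  Only
use it on observation spans up to a few thousand days.
"""

from __future__ import annotations

import datetime as _dt
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .algebra import ABSENCE, PRESENCE, STAR_FIRST
from .errors import EvalError
from .model import PatientObject, PatientStore, date_to_day
from .parser import (Age, Count, Export, Expression, Feature, Labs, Nary,
                     QueryProgram, SequenceOp, Text, Unary, VarRef, Year)


def runs(days: Set[int]) -> List[Tuple[int, int]]:
    """Maximal half-open runs of consecutive days, sorted."""
    if not days:
        return []
    ordered = sorted(days)
    out: List[Tuple[int, int]] = []
    start = prev = ordered[0]
    for d in ordered[1:]:
        if d == prev + 1:
            prev = d
        else:
            out.append((start, prev + 1))
            start = prev = d
    out.append((start, prev + 1))
    return out


def _span_days(patient: PatientObject) -> Set[int]:
    return set(range(patient.span.start, patient.span.end))


def _event_days(patient: PatientObject, match) -> Set[int]:
    out: Set[int] = set()
    for ev in patient.events:
        if match(ev):
            out.update(range(ev.interval.start, ev.interval.end))
    return out


def eval_days(expr: Expression, patient: PatientObject,
              defs: Optional[Dict[str, Expression]] = None,
              memo: Optional[Dict[str, Set[int]]] = None,
              original_only: bool = False) -> Set[int]:
    """Day set covered by the expression for this patient."""
    if memo is None:
        memo = {}

    def ev(e: Expression, original: bool) -> Set[int]:
        if isinstance(e, VarRef):
            if e.name not in memo:
                if defs is None or e.name not in defs:
                    raise EvalError(f"unbound variable ${e.name}")
                memo[e.name] = ev(defs[e.name], original)
            return memo[e.name]
        if isinstance(e, Feature):
            if e.namespace == "GENDER":
                return _span_days(patient) if patient.gender.lower() == e.code.lower() else set()
            if e.namespace == "RACE":
                return _span_days(patient) if patient.race.lower() == e.code.lower() else set()
            return _event_days(
                patient,
                lambda ev_: (ev_.key.namespace == e.namespace and ev_.key.code == e.code
                             and (not original or ev_.original)))
        if isinstance(e, Labs):
            return _event_days(
                patient,
                lambda ev_: (ev_.key.namespace == "LOINC" and ev_.key.code == e.code
                             and ev_.value is not None
                             and (e.lo is None or ev_.value >= e.lo)
                             and (e.hi is None or ev_.value <= e.hi)
                             and (not original or ev_.original)))
        if isinstance(e, Text):
            return _event_days(
                patient,
                lambda ev_: (ev_.key.namespace == "TEXT"
                             and ev_.key.code == e.phrase.lower()
                             and ev_.flags == e.flags))
        if isinstance(e, Age):
            lo = patient.birth_day + e.lo
            hi = patient.span.end if e.hi is None else patient.birth_day + e.hi
            return set(range(lo, hi)) & _span_days(patient)
        if isinstance(e, Year):
            lo = date_to_day(_dt.date(e.lo, 1, 1))
            hi = (patient.span.end if e.hi is None
                  else date_to_day(_dt.date(e.hi + 1, 1, 1)))
            return set(range(max(lo, patient.span.start), hi)) & _span_days(patient)
        if isinstance(e, Nary):
            if e.op in ("AND", "OR", "NOT"):
                vals = [ev(o, original) for o in e.operands]
                if e.op == "AND":
                    hit = all(vals)
                elif e.op == "OR":
                    hit = any(vals)
                else:
                    hit = not any(vals)
                return _span_days(patient) if hit else set()
            if e.op == "UNION":
                out: Set[int] = set()
                for o in e.operands:
                    out |= ev(o, original)
                return out
            if e.op == "INTERSECT":
                acc = ev(e.operands[0], original)
                for o in e.operands[1:]:
                    acc &= ev(o, original)
                return acc
            if e.op == "DIFF":
                a = ev(e.operands[0], original)
                return a if not ev(e.operands[1], original) else set()
            raise EvalError(f"unknown operator {e.op}")
        if isinstance(e, Unary):
            if e.op == "ORIGINAL":
                return ev(e.operand, True)
            x = ev(e.operand, original)
            if e.op == "INVERT":
                return _span_days(patient) - x
            if e.op == "FIRST_MENTION":
                r = runs(x)
                return set(range(*r[0])) if r else set()
            if e.op == "NO_HISTORY_OF":
                if not x:
                    return _span_days(patient)
                return set(range(patient.span.start, min(x)))
            if e.op == "NEVER_HAD":
                return set() if x else _span_days(patient)
            raise EvalError(f"unknown operator {e.op}")
        if isinstance(e, Count):
            x = ev(e.operand, original)
            n = len(runs(x))
            if n >= e.min_n and (e.max_n is None or n <= e.max_n):
                return x
            return set()
        if isinstance(e, SequenceOp):
            a = ev(e.first, original)
            b = ev(e.second, original)
            starred, other = (a, b) if e.star == STAR_FIRST else (b, a)
            other_starts = [s for s, _ in runs(other)]
            out: Set[int] = set()
            for s, t in runs(starred):
                if e.window is None:
                    if e.star == STAR_FIRST:
                        ok = any(n > s for n in other_starts)
                    else:
                        ok = any(n < s for n in other_starts)
                else:
                    lo = None if e.window.lo is None else s + e.window.lo
                    hi = None if e.window.hi is None else s + e.window.hi
                    hit = any((lo is None or n >= lo) and (hi is None or n <= hi)
                              for n in other_starts)
                    ok = hit if e.window.mode == PRESENCE else not hit
                if ok:
                    out.update(range(s, t))
            return out
        if isinstance(e, Export):
            return ev(e.cohort, original)
        raise EvalError(f"cannot evaluate {type(e).__name__}")

    return ev(expr, original_only)


def evaluate_program_days(program: QueryProgram, patient: PatientObject) -> Set[int]:
    return eval_days(program.final_expr, patient, defs=program.var_defs, memo={})


def evaluate_store_days(program: QueryProgram, store: PatientStore) -> Dict[str, Set[int]]:
    """Matched patients (nonempty day sets only) by full scan."""
    out: Dict[str, Set[int]] = {}
    for pid in sorted(store.patients):
        days = evaluate_program_days(program, store.patients[pid])
        if days:
            out[pid] = days
    return out
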