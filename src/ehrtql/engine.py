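"""Two-phase query execution.

Phase 1 computes a *sound* candidate set from the feature index: a structural
over-approximation of the patients that could possibly match (selector →
index posting; intersection-like operators → intersection of operand
candidates; union-like → union; anything negation-bearing → all patients for
that branch).  Phase 2 fully evaluates the query AST per candidate patient,
producing an interval set; patients with a nonempty result form the cohort.
The two-phase result is identical to brute-force evaluation of every patient
— the index only prunes, never decides.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Set

from . import algebra
from .algebra import STAR_FIRST, STAR_SECOND
from .errors import EvalError
from .model import (EMPTY_SET, FeatureKey, Interval, IntervalSet, PatientObject,
                    PatientStore, coalesce, date_to_day)
from .parser import (Age, Count, Export, Expression, Feature, Labs, Nary,
                     QueryProgram, SequenceOp, Text, Unary, VarRef, Year)


@dataclass
class ResultSet:
    """Patients matching a query, with the intervals where it was true."""

    matches: Dict[str, IntervalSet]
    program: QueryProgram
    store: PatientStore

    def __len__(self) -> int:
        return len(self.matches)

    def patient_ids(self) -> FrozenSet[str]:
        return frozenset(self.matches)


def _reachable_vars(program: QueryProgram) -> Set[str]:
    """Names of variables the final expression (transitively) references."""
    needed: Set[str] = set()

    def visit(expr: Expression) -> None:
        if isinstance(expr, VarRef):
            if expr.name not in needed:
                needed.add(expr.name)
                visit(program.var_defs[expr.name])
        elif isinstance(expr, Nary):
            for op in expr.operands:
                visit(op)
        elif isinstance(expr, (Unary, Count)):
            visit(expr.operand)
        elif isinstance(expr, SequenceOp):
            visit(expr.first)
            visit(expr.second)
        elif isinstance(expr, Export):
            visit(expr.cohort)
            visit(expr.time_expr)
            for _, col in expr.columns:
                visit(col)

    visit(program.final_expr)
    return needed


# ---------------------------------------------------------------------------
# Full per-patient evaluation
# ---------------------------------------------------------------------------

def _feature_intervals(patient: PatientObject, key: FeatureKey,
                       original_only: bool) -> IntervalSet:
    events = patient.key_index.get(key)
    if not events:
        return EMPTY_SET
    if original_only:
        spans = [ev.interval for ev in events if ev.original]
    else:
        spans = [ev.interval for ev in events]
    return coalesce(spans) if spans else EMPTY_SET


def _span_set(patient: PatientObject) -> IntervalSet:
    return IntervalSet((patient.span,))


def evaluate_patient(expr: Expression, patient: PatientObject,
                     bindings: Optional[Dict[str, IntervalSet]] = None,
                     defs: Optional[Dict[str, Expression]] = None,
                     original_only: bool = False) -> IntervalSet:
    """Evaluate an expression to the patient's interval set.

    ``bindings`` memoizes variable values within this patient's evaluation;
    ``defs`` supplies variable definitions for lazy resolution.
    """
    if bindings is None:
        bindings = {}

    def ev(e: Expression, original: bool) -> IntervalSet:
        if isinstance(e, VarRef):
            val = bindings.get(e.name)
            if val is None:
                if defs is None or e.name not in defs:
                    raise EvalError(f"unbound variable ${e.name}")
                val = ev(defs[e.name], original)
                bindings[e.name] = val
            return val
        if isinstance(e, Feature):
            ns = e.namespace
            if ns == "GENDER":
                return _span_set(patient) if patient.gender.lower() == e.code.lower() else EMPTY_SET
            if ns == "RACE":
                return _span_set(patient) if patient.race.lower() == e.code.lower() else EMPTY_SET
            return _feature_intervals(patient, FeatureKey(ns, e.code), original)
        if isinstance(e, Labs):
            events = patient.key_index.get(FeatureKey("LOINC", e.code))
            if not events:
                return EMPTY_SET
            spans = [x.interval for x in events
                     if x.value is not None
                     and (e.lo is None or x.value >= e.lo)
                     and (e.hi is None or x.value <= e.hi)
                     and (not original or x.original)]
            return coalesce(spans) if spans else EMPTY_SET
        if isinstance(e, Text):
            events = patient.key_index.get(FeatureKey("TEXT", e.phrase.lower()))
            if not events:
                return EMPTY_SET
            spans = [x.interval for x in events if x.flags == e.flags]
            return coalesce(spans) if spans else EMPTY_SET
        if isinstance(e, Age):
            lo = patient.birth_day + e.lo
            hi = patient.span.end if e.hi is None else patient.birth_day + e.hi
            s = max(lo, patient.span.start)
            t = min(hi, patient.span.end)
            return IntervalSet((Interval(s, t),)) if s < t else EMPTY_SET
        if isinstance(e, Year):
            s = max(date_to_day(_dt.date(e.lo, 1, 1)), patient.span.start)
            if e.hi is None:
                t = patient.span.end
            else:
                t = min(date_to_day(_dt.date(e.hi + 1, 1, 1)), patient.span.end)
            return IntervalSet((Interval(s, t),)) if s < t else EMPTY_SET
        if isinstance(e, Nary):
            op = e.op
            if op in ("AND", "OR", "NOT"):
                vals = [ev(o, original) for o in e.operands]
                if op == "AND":
                    hit = all(vals)
                elif op == "OR":
                    hit = any(vals)
                else:  # NOT: no record of any of the features
                    hit = not any(vals)
                return _span_set(patient) if hit else EMPTY_SET
            if op == "UNION":
                return algebra.t_union([ev(o, original) for o in e.operands])
            if op == "INTERSECT":
                acc = ev(e.operands[0], original)
                for o in e.operands[1:]:
                    if not acc:
                        return EMPTY_SET
                    acc = algebra.t_intersect([acc, ev(o, original)])
                return acc
            if op == "DIFF":
                a = ev(e.operands[0], original)
                if not a:
                    return EMPTY_SET
                return a if not ev(e.operands[1], original) else EMPTY_SET
            raise EvalError(f"unknown operator {op}")
        if isinstance(e, Unary):
            if e.op == "ORIGINAL":
                return ev(e.operand, True)
            x = ev(e.operand, original)
            if e.op == "INVERT":
                return algebra.t_invert(x, patient.span)
            if e.op == "FIRST_MENTION":
                return algebra.t_first_mention(x)
            if e.op == "NO_HISTORY_OF":
                return algebra.t_no_history_of(x, patient.span)
            if e.op == "NEVER_HAD":
                return algebra.t_never_had(x, patient.span)
            raise EvalError(f"unknown operator {e.op}")
        if isinstance(e, Count):
            return algebra.t_count(ev(e.operand, original), e.min_n, e.max_n)
        if isinstance(e, SequenceOp):
            return algebra.t_sequence(ev(e.first, original), ev(e.second, original),
                                      e.star, e.window)
        if isinstance(e, Export):
            return ev(e.cohort, original)
        raise EvalError(f"cannot evaluate {type(e).__name__}")

    return ev(expr, original_only)


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def candidate_set(expr: Expression, store: PatientStore,
                  program: Optional[QueryProgram] = None,
                  _memo: Optional[Dict[str, FrozenSet[str]]] = None) -> FrozenSet[str]:
    """Sound over-approximation of the patients whose evaluation is nonempty."""
    all_ids = store.all_ids()
    memo: Dict[str, FrozenSet[str]] = _memo if _memo is not None else {}

    def cand(e: Expression) -> FrozenSet[str]:
        if isinstance(e, VarRef):
            got = memo.get(e.name)
            if got is None:
                if program is None or e.name not in program.var_defs:
                    return all_ids
                got = cand(program.var_defs[e.name])
                memo[e.name] = got
            return got
        if isinstance(e, Feature):
            if e.namespace in ("GENDER", "RACE"):
                return store.lookup(FeatureKey(e.namespace, e.code.lower()))
            return store.lookup(FeatureKey(e.namespace, e.code))
        if isinstance(e, Labs):
            return store.lookup(FeatureKey("LOINC", e.code))
        if isinstance(e, Text):
            return store.lookup(FeatureKey("TEXT", e.phrase.lower()))
        if isinstance(e, (Age, Year)):
            return all_ids
        if isinstance(e, Nary):
            if e.op in ("OR", "UNION"):
                out: Set[str] = set()
                for o in e.operands:
                    out |= cand(o)
                return frozenset(out)
            if e.op in ("AND", "INTERSECT"):
                acc = cand(e.operands[0])
                for o in e.operands[1:]:
                    if not acc:
                        return frozenset()
                    acc = acc & cand(o)
                return acc
            if e.op == "DIFF":
                return cand(e.operands[0])  # second operand is negated
            return all_ids  # NOT
        if isinstance(e, Unary):
            if e.op in ("FIRST_MENTION", "ORIGINAL"):
                return cand(e.operand)
            return all_ids  # INVERT, NO_HISTORY_OF, NEVER_HAD
        if isinstance(e, Count):
            if e.min_n == 0:
                # zero occurrences satisfy the bound for every patient, but the
                # returned set is still the operand's (possibly empty) value,
                # so the operand's candidates remain sound
                return cand(e.operand)
            return cand(e.operand)
        if isinstance(e, SequenceOp):
            starred = e.first if e.star == STAR_FIRST else e.second
            other = e.second if e.star == STAR_FIRST else e.first
            if e.window is not None and e.window.mode == algebra.ABSENCE:
                return cand(starred)  # non-starred branch is negated
            return cand(starred) & cand(other)
        if isinstance(e, Export):
            return cand(e.cohort)
        return all_ids

    return cand(expr)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def execute(program: QueryProgram, store: PatientStore,
            use_index: bool = True) -> ResultSet:
    """Run a parsed program over the store.

    With ``use_index=False`` every patient is fully evaluated (the brute-force
    path); results are identical either way.
    """
    if use_index:
        candidates = candidate_set(program.final_expr, store, program)
    else:
        candidates = store.all_ids()

    needed = _reachable_vars(program)
    defs = {name: e for name, e in program.var_defs.items() if name in needed}

    matches: Dict[str, IntervalSet] = {}
    for pid in sorted(candidates):
        patient = store.patients[pid]
        bindings: Dict[str, IntervalSet] = {}
        try:
            result = evaluate_patient(program.final_expr, patient, bindings, defs)
        except EvalError as exc:
            raise EvalError(f"patient {pid}: {exc}") from exc
        if result:
            matches[pid] = result
    return ResultSet(matches=matches, program=program, store=store)


def execute_text(text: str, store: PatientStore, use_index: bool = True) -> ResultSet:
    """Parse and run TQL source in one step (library entry point)."""
    from .parser import parse_program
    return execute(parse_program(text), store, use_index=use_index)
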