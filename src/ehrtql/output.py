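"""Result surfaces: cohort summary statistics, per-patient timeline tracks,
EXPORT flat files, and JSON serialization of result sets."""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .engine import ResultSet, evaluate_patient
from .errors import EvalError, TQLError
from .model import Interval, IntervalSet, PatientStore, day_to_date, date_to_day
from .parser import Export, Labs, QueryProgram

#: Feature-namespace groups reported in cohort summaries.
_SUMMARY_GROUPS = {"ICD9": "ICD", "ICD10": "ICD", "CPT": "CPT",
                   "RX": "RX", "LOINC": "LOINC"}

AGE_BIN_LABELS = tuple(f"{lo}-{lo + 9}" for lo in range(0, 100, 10)) + ("100+",)


@dataclass
class CohortSummary:
    """Aggregate description of a matched cohort.

    Age is age at the first matched interval, in 10-year bins; record length
    is the observation-period length in 1-year bins; ``top_features`` lists,
    per namespace group, the codes with the most distinct matched patients
    holding ≥1 source-data event of the code (ties broken lexicographically).
    """

    n_patients: int
    age_histogram: Dict[str, int] = field(default_factory=dict)
    record_length_histogram: Dict[str, int] = field(default_factory=dict)
    gender_counts: Dict[str, int] = field(default_factory=dict)
    race_ethnicity_counts: Dict[str, int] = field(default_factory=dict)
    top_features: Dict[str, List[Tuple[str, int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "age_histogram": self.age_histogram,
            "record_length_histogram": self.record_length_histogram,
            "gender_counts": self.gender_counts,
            "race_ethnicity_counts": self.race_ethnicity_counts,
            "top_features": {g: [list(t) for t in feats]
                             for g, feats in self.top_features.items()},
        }


def summarize(result: ResultSet, store: Optional[PatientStore] = None,
              k: int = 10) -> CohortSummary:
    """Compute the cohort summary over the matched patients only."""
    if k < 1:
        raise ValueError("k must be >= 1")
    store = store or result.store
    summary = CohortSummary(n_patients=len(result.matches))
    ages: Counter = Counter()
    lengths: Counter = Counter()
    genders: Counter = Counter()
    races: Counter = Counter()
    feature_patients: Dict[str, Counter] = {g: Counter()
                                            for g in set(_SUMMARY_GROUPS.values())}

    for pid, intervals in result.matches.items():
        p = store.patients[pid]
        age_years = (intervals.first().start - p.birth_day) // 365
        bin_idx = min(max(age_years, 0) // 10, 10)
        ages[AGE_BIN_LABELS[bin_idx]] += 1
        lengths[str((p.span.end - p.span.start) // 365)] += 1
        genders[p.gender.lower()] += 1
        races[p.race.lower()] += 1
        seen = set()
        for ev in p.events:
            group = _SUMMARY_GROUPS.get(ev.key.namespace)
            if group and ev.original and ev.key not in seen:
                seen.add(ev.key)
                feature_patients[group][ev.key.code] += 1

    summary.age_histogram = dict(sorted(ages.items()))
    summary.record_length_histogram = dict(sorted(lengths.items(), key=lambda kv: int(kv[0])))
    summary.gender_counts = dict(sorted(genders.items()))
    summary.race_ethnicity_counts = dict(sorted(races.items()))
    summary.top_features = {
        group: sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for group, counts in feature_patients.items()
    }
    return summary


def timelines(result: ResultSet, variables: Sequence[str]
              ) -> Dict[str, Dict[str, IntervalSet]]:
    """Per matched patient, the interval track of each requested variable —
    the data behind a patient-timeline view (one row per patient, one
    coloured track per criterion)."""
    program = result.program
    for name in variables:
        if name not in program.var_defs:
            raise EvalError(f"unknown variable ${name}")
    out: Dict[str, Dict[str, IntervalSet]] = {}
    for pid in result.matches:
        patient = result.store.patients[pid]
        bindings: Dict[str, IntervalSet] = {}
        tracks = {}
        for name in variables:
            tracks[name] = evaluate_patient(program.var_defs[name], patient,
                                            bindings, program.var_defs)
        out[pid] = tracks
    return out


def export_flat(program: QueryProgram, store: PatientStore) -> pd.DataFrame:
    """Materialise a top-level EXPORT as a flat labeled table.

    One row per patient matching the cohort expression; TIME is the start of
    the first interval of the TIME expression (ISO date); interval-valued
    label columns export 1/0 nonempty indicators, LABS columns export the
    first in-range measurement value.
    """
    export = program.final_expr
    if not isinstance(export, Export):
        raise TQLError("program's final query is not an EXPORT")

    from .engine import execute
    result = execute(program, store)

    rows = []
    for pid in sorted(result.matches):
        patient = store.patients[pid]
        bindings: Dict[str, IntervalSet] = {}
        time_val = evaluate_patient(export.time_expr, patient, bindings,
                                    program.var_defs)
        if not time_val:
            raise EvalError(f"patient {pid}: TIME expression is empty")
        row = {"patient_id": pid,
               "TIME": day_to_date(time_val.first().start).isoformat()}
        for label, expr in export.columns:
            if isinstance(expr, Labs):
                row[label] = _first_lab_value(patient, expr)
            else:
                val = evaluate_patient(expr, patient, bindings, program.var_defs)
                row[label] = 1 if val else 0
        rows.append(row)
    columns = ["patient_id", "TIME"] + [label for label, _ in export.columns]
    return pd.DataFrame(rows, columns=columns)


def _first_lab_value(patient, labs: Labs):
    from .model import FeatureKey
    events = patient.key_index.get(FeatureKey("LOINC", labs.code), [])
    for ev in events:  # ordered by start day
        if (ev.value is not None
                and (labs.lo is None or ev.value >= labs.lo)
                and (labs.hi is None or ev.value <= labs.hi)):
            return ev.value
    return None


# ---------------------------------------------------------------------------
# JSON result schema
# ---------------------------------------------------------------------------
# {"n_patients": N, "patients": {pid: [["YYYY-MM-DD", "YYYY-MM-DD"], ...]}}
# Interval ends are exclusive, consistent with the half-open day convention.

def result_to_json(result: ResultSet, indent: Optional[int] = None) -> str:
    payload = {
        "n_patients": len(result.matches),
        "patients": {
            pid: [[day_to_date(s).isoformat(), day_to_date(e).isoformat()]
                  for s, e in intervals]
            for pid, intervals in sorted(result.matches.items())
        },
    }
    return json.dumps(payload, indent=indent)


def matches_from_json(text: str) -> Dict[str, IntervalSet]:
    """Inverse of :func:`result_to_json` (matches only)."""
    import datetime as _dt
    payload = json.loads(text)
    return {
        pid: IntervalSet(tuple(
            Interval(date_to_day(_dt.date.fromisoformat(s)),
                     date_to_day(_dt.date.fromisoformat(e)))
            for s, e in spans))
        for pid, spans in payload["patients"].items()
    }
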