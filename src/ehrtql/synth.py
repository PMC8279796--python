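"""Seeded synthetic OMOP-subset cohorts with planted, known-truth temporal
structure.

Each named :class:`CohortSpec` emulates the population one of the four
fixture queries is meant to retrieve: patients are assigned a *role*
(a planted trajectory such as "two type II diabetes codes, then glipizide,
then a stroke within 90 days", or a near-miss control that violates exactly
one criterion), role events are laid down with seeded inter-event gaps, and
neutral background events (hypertension codes, office visits, normal-range
labs, note mentions) are sprinkled on every timeline.  Background codes are
chosen disjoint from each query's code set so planted roles alone decide
membership.

All randomness flows from one seed through a counter-based per-patient
stream (``default_rng([seed, patient_index])``), so output is byte-identical
for identical seeds and adding patients never shifts existing ones.  Before
a ground-truth table is written it is verified against the independent
day-set interpreter; generation fails loudly if the planted qualifying set
and the verified matched set ever disagree.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import dayset, etl, fixtures
from .knowledge import fixture_drug_map, fixture_ontologies
from .model import PatientStore, date_to_day, day_to_date
from .parser import parse_program

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Step:
    """One planted event: a code placed ``gap_lo..gap_hi`` days after the
    previous step (the first step sits on the trajectory anchor day)."""

    namespace: str
    code: str
    gap_lo: int = 0
    gap_hi: int = 0
    value_lo: Optional[float] = None  # LOINC only
    value_hi: Optional[float] = None


@dataclass(frozen=True)
class Trajectory:
    """A planted role with its prevalence and demographic constraints.

    ``qualifying`` marks the roles the spec's query is expected to retrieve;
    these form the ground-truth table.
    """

    name: str
    prevalence: float
    steps: Tuple[Step, ...]
    gender: Optional[str] = None
    birth_year_range: Optional[Tuple[int, int]] = None
    qualifying: bool = False


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic OMOP-subset cohort."""

    name: str
    n_patients: int
    query_box: int  # fixture query this cohort is built for
    trajectories: Tuple[Trajectory, ...]
    gender_probs: Tuple[Tuple[str, float], ...] = (("male", 0.5), ("female", 0.5))
    race_probs: Tuple[Tuple[str, float], ...] = (
        ("white", 0.55), ("asian", 0.15), ("hispanic", 0.13),
        ("black", 0.12), ("other", 0.05))
    birth_year_range: Tuple[int, int] = (1940, 1990)
    obs_start_year_range: Tuple[int, int] = (2008, 2012)
    obs_years_range: Tuple[int, int] = (8, 12)
    background_icd9: Tuple[str, ...] = ()
    background_icd10: Tuple[str, ...] = ()
    background_cpt: Tuple[str, ...] = ("99213", "93000")
    background_rx: Tuple[str, ...] = ("161",)
    background_rate: float = 0.4  # events per code per year
    background_lab: Optional[Tuple[str, float, float, float]] = None  # code, rate/yr, lo, hi
    text_phrases: Tuple[str, ...] = ("cough", "chest pain")

    def __post_init__(self):
        total = sum(t.prevalence for t in self.trajectories)
        if total > 1.0 + 1e-9:
            raise ValueError(f"trajectory prevalences sum to {total} > 1")
        for t in self.trajectories:
            for s in t.steps:
                if s.gap_lo < 0 or s.gap_lo > s.gap_hi:
                    raise ValueError(f"bad gap range in {t.name}: {s}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "person": ["person_id", "gender_source_value", "race_source_value",
               "year_of_birth", "month_of_birth", "day_of_birth"],
    "observation_period": ["observation_period_id", "person_id",
                           "observation_period_start_date",
                           "observation_period_end_date"],
    "condition_occurrence": ["condition_occurrence_id", "person_id",
                             "condition_start_date", "condition_source_value"],
    "procedure_occurrence": ["procedure_occurrence_id", "person_id",
                             "procedure_date", "procedure_source_value"],
    "drug_exposure": ["drug_exposure_id", "person_id",
                      "drug_exposure_start_date", "drug_exposure_end_date",
                      "drug_source_value"],
    "measurement": ["measurement_id", "person_id", "measurement_date",
                    "measurement_source_value", "value_as_number",
                    "unit_source_value"],
    "text_mention": ["person_id", "note_date", "phrase", "negated",
                     "family_history", "note_type"],
}


def _choice(rng: np.random.Generator, probs: Sequence[Tuple[str, float]]) -> str:
    labels = [l for l, _ in probs]
    weights = np.asarray([w for _, w in probs], dtype=float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _iso(day: int) -> str:
    return day_to_date(day).isoformat()


def generate_tables(spec: CohortSpec, seed: int
                    ) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the OMOP-subset tables and the verified ground-truth table.

    Returns ``(frames, ground_truth)`` where ground truth has one row per
    matched patient: planted trajectory name, patient id, and the first day
    (and ISO date) on which the cohort definition is satisfied.
    """
    rows: Dict[str, List[list]] = {t: [] for t in _TABLE_COLUMNS}
    roles: Dict[str, str] = {}
    counters = {t: 1 for t in _TABLE_COLUMNS}

    cum: List[Tuple[float, Trajectory]] = []
    acc = 0.0
    for t in spec.trajectories:
        acc += t.prevalence
        cum.append((acc, t))

    for i in range(spec.n_patients):
        rng = np.random.default_rng([seed, i])
        pid = f"P{i:06d}"

        u = rng.random()
        role: Optional[Trajectory] = None
        for bound, t in cum:
            if u < bound:
                role = t
                break
        roles[pid] = role.name if role else "background"

        gender = role.gender if role and role.gender else _choice(rng, spec.gender_probs)
        race = _choice(rng, spec.race_probs)
        by_lo, by_hi = (role.birth_year_range if role and role.birth_year_range
                        else spec.birth_year_range)
        birth = _dt.date(int(rng.integers(by_lo, by_hi + 1)),
                         int(rng.integers(1, 13)), int(rng.integers(1, 29)))

        sy_lo, sy_hi = spec.obs_start_year_range
        start = _dt.date(int(rng.integers(sy_lo, sy_hi + 1)),
                         int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        span_days = int(rng.integers(spec.obs_years_range[0] * 365,
                                     spec.obs_years_range[1] * 365 + 1))
        s_day = date_to_day(start)
        e_day = s_day + span_days

        rows["person"].append([pid, gender, race, birth.year, birth.month, birth.day])
        rows["observation_period"].append(
            [counters["observation_period"], pid, _iso(s_day), _iso(e_day)])
        counters["observation_period"] += 1

        # planted trajectory events
        if role:
            max_total = sum(s.gap_hi for s in role.steps)
            hi_anchor = max(s_day + 61, e_day - max_total - 60)
            day = int(rng.integers(s_day + 60, hi_anchor + 1))
            for k, step in enumerate(role.steps):
                if k > 0:
                    day += int(rng.integers(step.gap_lo, step.gap_hi + 1))
                day = min(day, e_day - 1)
                _emit_event(rows, counters, pid, day, step.namespace, step.code,
                            None if step.value_lo is None else
                            float(np.round(rng.uniform(step.value_lo, step.value_hi), 1)))

        # background events, per code
        years = span_days / 365.0
        for ns, codes in (("ICD9", spec.background_icd9),
                          ("ICD10", spec.background_icd10),
                          ("CPT", spec.background_cpt),
                          ("RX", spec.background_rx)):
            for code in codes:
                for _ in range(int(rng.poisson(spec.background_rate * years))):
                    d = int(rng.integers(s_day, e_day))
                    _emit_event(rows, counters, pid, d, ns, code, None)
        if spec.background_lab is not None:
            code, rate, vlo, vhi = spec.background_lab
            for _ in range(int(rng.poisson(rate * years))):
                d = int(rng.integers(s_day, e_day))
                _emit_event(rows, counters, pid, d, "LOINC", code,
                            float(np.round(rng.uniform(vlo, vhi), 1)))
        for _ in range(int(rng.poisson(0.3 * years))):
            d = int(rng.integers(s_day, e_day))
            phrase = spec.text_phrases[int(rng.integers(0, len(spec.text_phrases)))]
            negated = int(rng.random() < 0.2)
            famhx = int((not negated) and rng.random() < 0.1)
            rows["text_mention"].append([pid, _iso(d), phrase, negated, famhx, "progress"])

    frames = {t: pd.DataFrame(rows[t], columns=cols).astype(str)
              for t, cols in _TABLE_COLUMNS.items()}

    truth = _verified_truth(spec, frames, roles)
    return frames, truth


def _emit_event(rows, counters, pid: str, day: int, ns: str, code: str,
                value: Optional[float]) -> None:
    iso = _iso(day)
    if ns in ("ICD9", "ICD10"):
        rows["condition_occurrence"].append(
            [counters["condition_occurrence"], pid, iso, f"{ns}:{code}"])
        counters["condition_occurrence"] += 1
    elif ns == "CPT":
        rows["procedure_occurrence"].append(
            [counters["procedure_occurrence"], pid, iso, f"CPT:{code}"])
        counters["procedure_occurrence"] += 1
    elif ns == "RX":
        rows["drug_exposure"].append(
            [counters["drug_exposure"], pid, iso, iso, code])
        counters["drug_exposure"] += 1
    elif ns == "LOINC":
        rows["measurement"].append(
            [counters["measurement"], pid, iso, code,
             "" if value is None else f"{value:.1f}", "%"])
        counters["measurement"] += 1
    else:  # pragma: no cover - spec construction error
        raise ValueError(f"cannot emit event in namespace {ns}")


def build_store(spec: CohortSpec, seed: int) -> Tuple[PatientStore, pd.DataFrame]:
    """Generate, load through the standard ETL, and return (store, truth)."""
    frames, truth = generate_tables(spec, seed)
    ontologies = fixture_ontologies()
    store = etl.load_frames(frames, ontologies, fixture_drug_map(ontologies["ATC"]))
    return store, truth


def _verified_truth(spec: CohortSpec, frames: Dict[str, pd.DataFrame],
                    roles: Dict[str, str]) -> pd.DataFrame:
    """Evaluate the spec's query with the day-set interpreter and check that
    exactly the planted qualifying patients match."""
    ontologies = fixture_ontologies()
    store = etl.load_frames(frames, ontologies, fixture_drug_map(ontologies["ATC"]))
    program = parse_program(fixtures.box_text(spec.query_box))
    matched = dayset.evaluate_store_days(program, store)

    qualifying_roles = {t.name for t in spec.trajectories if t.qualifying}
    planted = {pid for pid, r in roles.items() if r in qualifying_roles}
    if set(matched) != planted:
        extra = sorted(set(matched) - planted)[:5]
        missing = sorted(planted - set(matched))[:5]
        raise RuntimeError(
            f"{spec.name}: planted truth failed verification "
            f"(unexpected={extra}, missing={missing})")

    records = [
        {"trajectory": roles[pid], "patient_id": pid,
         "first_day": min(days), "first_date": _iso(min(days))}
        for pid, days in sorted(matched.items())
    ]
    return pd.DataFrame(records,
                        columns=["trajectory", "patient_id", "first_day", "first_date"])


def generate(spec: CohortSpec, out_dir, seed: int) -> dict:
    """Write the OMOP CSVs, ``ground_truth.csv`` and ``spec.json``.

    Returns a small manifest dict.  Identical seeds yield byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, truth = generate_tables(spec, seed)
    for table, df in frames.items():
        df.to_csv(out / f"{table}.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    payload = dataclasses.asdict(spec)
    payload["seed"] = seed
    with open(out / "spec.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return {"spec": spec.name, "seed": seed, "n_patients": spec.n_patients,
            "n_truth": len(truth), "dir": str(out)}


# ---------------------------------------------------------------------------
# Default spec catalog — one population per fixture query
# ---------------------------------------------------------------------------

_HBA1C = "4548-4 [%]"


def _diabetes_stroke(n: int) -> CohortSpec:
    old = (1930, 1941)
    young = (1968, 1985)
    dm_steps = (Step("ICD9", "250.00"),
                Step("ICD9", "250.00", 20, 160),
                Step("RX", "310490", 10, 120))
    lab_steps = (Step("LOINC", _HBA1C, 0, 0, 8.5, 12.0),
                 Step("LOINC", _HBA1C, 20, 160, 8.5, 12.0),
                 Step("RX", "310490", 10, 120))
    stroke = Step("ICD9", "434.91", 2, 85)      # within the 3-month window
    late_stroke = Step("ICD9", "434.91", 120, 250)  # outside it
    return CohortSpec(
        name="diabetes_stroke", n_patients=n, query_box=1,
        trajectories=(
            Trajectory("qualifying", 0.10, dm_steps + (stroke,),
                       gender="male", birth_year_range=old, qualifying=True),
            Trajectory("lab_qualifying", 0.05, lab_steps + (stroke,),
                       gender="male", birth_year_range=old, qualifying=True),
            Trajectory("female_counterpart", 0.04, dm_steps + (stroke,),
                       gender="female", birth_year_range=old),
            Trajectory("young_counterpart", 0.04, dm_steps + (stroke,),
                       gender="male", birth_year_range=young),
            Trajectory("stroke_first", 0.05,
                       (Step("ICD9", "434.91"),) + tuple(
                           dataclasses.replace(s, gap_lo=max(s.gap_lo, 30),
                                               gap_hi=max(s.gap_hi, 30))
                           for s in dm_steps),
                       gender="male", birth_year_range=old),
            Trajectory("late_stroke", 0.04, dm_steps + (late_stroke,),
                       gender="male", birth_year_range=old),
            Trajectory("no_stroke", 0.05, dm_steps,
                       gender="male", birth_year_range=old),
        ),
        background_icd9=("401.9", "462", "486", "780.60"),
        background_icd10=("J20.9", "N18.3"),
        background_lab=(_HBA1C, 0.3, 4.8, 6.9),
    )


def _bronchitis_hedis(n: int) -> CohortSpec:
    adult = (1962, 1988)
    senior = (1935, 1942)
    return CohortSpec(
        name="bronchitis_hedis", n_patients=n, query_box=2,
        birth_year_range=adult,
        trajectories=(
            Trajectory("clean_bronchitis", 0.12, (Step("ICD9", "466.0"),),
                       birth_year_range=adult, qualifying=True),
            Trajectory("treated", 0.06,
                       (Step("ICD9", "466.0"), Step("RX", "723", 1, 3)),
                       birth_year_range=adult),
            Trajectory("prior_antibiotic", 0.05,
                       (Step("RX", "723"), Step("ICD9", "466.0", 5, 25)),
                       birth_year_range=adult),
            Trajectory("comorbid_ccvs", 0.05,
                       (Step("ICD9", "491.21"), Step("ICD9", "466.0", 30, 300)),
                       birth_year_range=adult),
            Trajectory("senior_bronchitis", 0.04, (Step("ICD9", "466.0"),),
                       birth_year_range=senior),
        ),
        background_icd9=("401.9", "724.2", "780.60"),
        background_icd10=("E11.9",),
        background_cpt=("99213", "71020"),
        background_lab=(_HBA1C, 0.2, 4.8, 6.9),
    )


def _breast_ca_trial(n: int) -> CohortSpec:
    old = (1928, 1936)
    young = (1965, 1985)
    return CohortSpec(
        name="breast_ca_trial", n_patients=n, query_box=3,
        trajectories=(
            Trajectory("eligible", 0.12, (Step("ICD9", "233.0"),),
                       gender="female", birth_year_range=old, qualifying=True),
            Trajectory("eligible_then_invasive", 0.04,
                       (Step("ICD9", "233.0"), Step("ICD9", "174.9", 60, 400)),
                       gender="female", birth_year_range=old, qualifying=True),
            Trajectory("prior_invasive", 0.06,
                       (Step("ICD9", "174.9"), Step("ICD9", "233.0", 60, 400)),
                       gender="female", birth_year_range=old),
            Trajectory("male_cis", 0.04, (Step("ICD9", "233.0"),),
                       gender="male", birth_year_range=old),
            Trajectory("young_cis", 0.05, (Step("ICD9", "233.0"),),
                       gender="female", birth_year_range=young),
        ),
        background_icd9=("401.9", "462", "486"),
        background_icd10=("J20.9",),
    )


def _t2d_labels(n: int) -> CohortSpec:
    code_steps = (Step("ICD9", "250.00"), Step("ICD9", "250.00", 20, 200))
    lab_steps = (Step("LOINC", _HBA1C, 0, 0, 8.5, 12.0),
                 Step("LOINC", _HBA1C, 20, 200, 8.5, 12.0))
    return CohortSpec(
        name="t2d_labels", n_patients=n, query_box=4,
        trajectories=(
            Trajectory("t2d_codes", 0.10, code_steps, qualifying=True),
            Trajectory("t2d_labs", 0.06, lab_steps, qualifying=True),
            Trajectory("t2d_with_t1d", 0.05,
                       code_steps + (Step("ICD9", "250.01", 10, 100),)),
            Trajectory("t1d_only", 0.04,
                       (Step("ICD9", "250.01"), Step("ICD9", "250.03", 30, 200))),
            Trajectory("single_code", 0.05, (Step("ICD9", "250.00"),)),
        ),
        background_icd9=("401.9", "462", "780.60"),
        background_lab=(_HBA1C, 0.3, 4.8, 6.9),
    )


def default_specs(n_patients: Optional[Dict[str, int]] = None) -> Dict[str, CohortSpec]:
    """The four named cohort specs, one per fixture query.

    ``n_patients`` overrides the per-spec default population sizes.
    """
    n = {"diabetes_stroke": 400, "bronchitis_hedis": 400,
         "breast_ca_trial": 300, "t2d_labels": 300}
    if n_patients:
        n.update(n_patients)
    return {
        "diabetes_stroke": _diabetes_stroke(n["diabetes_stroke"]),
        "bronchitis_hedis": _bronchitis_hedis(n["bronchitis_hedis"]),
        "breast_ca_trial": _breast_ca_trial(n["breast_ca_trial"]),
        "t2d_labels": _t2d_labels(n["t2d_labels"]),
    }


# ---------------------------------------------------------------------------
# Random query generation (stress/benchmark plumbing)
# ---------------------------------------------------------------------------

CORE_COMMANDS = ("AND", "OR", "INTERSECT", "UNION", "SEQUENCE")


def code_pools(store: PatientStore) -> Dict[str, List[str]]:
    """Codes present in the store index for the four coded namespaces, plus a
    few absent codes so random queries also exercise empty postings."""
    pools: Dict[str, List[str]] = {ns: [] for ns in ("ICD9", "ICD10", "CPT", "RX")}
    for key in store.index:
        if key.namespace in pools:
            pools[key.namespace].append(key.code)
    for ns in pools:
        pools[ns] = sorted(set(pools[ns])) + [f"ZZZ-{ns}"]
    return pools


def random_core_query(rng: np.random.Generator, pools: Dict[str, List[str]]) -> str:
    """One random query over the five core commands with random ICD9/ICD10/
    CPT/RX feature parameters (OR/UNION of 4 features, AND/INTERSECT/SEQUENCE
    of 2, matching the published benchmark design)."""
    cmd = CORE_COMMANDS[int(rng.integers(0, len(CORE_COMMANDS)))]
    arity = 4 if cmd in ("OR", "UNION") else 2

    def feat() -> str:
        namespaces = [ns for ns, codes in pools.items() if codes]
        ns = namespaces[int(rng.integers(0, len(namespaces)))]
        code = pools[ns][int(rng.integers(0, len(pools[ns])))]
        return f'{ns}="{code}"'

    args = [feat() for _ in range(arity)]
    if cmd != "SEQUENCE":
        return f"{cmd}({', '.join(args)})"
    star = int(rng.integers(0, 2))
    args[star] += "*"
    query = f"SEQUENCE({args[0]}, {args[1]})"
    if rng.random() < 0.3:
        lo = int(rng.integers(-365, 181))
        hi = lo + int(rng.integers(0, 365))
        sign = "+" if rng.random() < 0.5 else "-"
        query += f"{sign}({lo} DAYS, {hi} DAYS)"
    return query
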