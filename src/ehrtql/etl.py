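"""Load an OMOP-CDM-v5.3-subset CSV directory into an indexed patient store.

Codes are read from ``*_source_value`` columns so that queries can use source
terminologies directly (no concept-id joins): condition and procedure source
values carry a namespace prefix (``ICD9:434.91``, ``CPT:99213``), drug
exposures carry a bare RxCUI, measurements a bare LOINC code with
``value_as_number``.  A pre-extracted ``text_mention.csv`` supplies note
mentions (phrase, negation/family-history flags, note type).  Events are
clipped to the patient's observation-period span at load; events entirely
outside the span are dropped with a logged warning.  Knowledge-graph
expansion (ancestor diagnosis codes, RxCUI→ATC classes) happens here, once,
at load time.

The loaded store can be written to a directory of shard files — autonomous
JSON partitions by patient-id hash plus a JSON manifest — and reloaded fully
or partially.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import zlib
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .errors import DataLoadError
from .knowledge import CodeOntology, DrugClassMap, expand_events
from .model import (Event, FeatureKey, Interval, PatientObject, PatientStore,
                    build_store, date_to_day)

logger = logging.getLogger(__name__)

MANDATORY_TABLES = ("person", "observation_period")
EVENT_TABLES = ("condition_occurrence", "procedure_occurrence", "drug_exposure",
                "measurement", "text_mention")
ALL_TABLES = MANDATORY_TABLES + EVENT_TABLES


def _parse_day(value, table: str, row: int) -> int:
    try:
        return date_to_day(_dt.date.fromisoformat(str(value).strip()))
    except (ValueError, TypeError):
        raise DataLoadError(f"{table}.csv row {row}: unparseable date {value!r}") from None


def _split_source(value: str, table: str, row: int, default_ns: Optional[str] = None):
    value = str(value).strip()
    if ":" in value:
        ns, code = value.split(":", 1)
        ns = ns.strip().upper()
        return ns, code.strip()
    if default_ns is not None:
        return default_ns, value
    raise DataLoadError(
        f"{table}.csv row {row}: source value {value!r} lacks a namespace prefix")


def read_omop_dir(path) -> Dict[str, pd.DataFrame]:
    """Read the CSV tables present in an OMOP subset directory."""
    path = Path(path)
    frames: Dict[str, pd.DataFrame] = {}
    for table in ALL_TABLES:
        f = path / f"{table}.csv"
        if f.exists():
            frames[table] = pd.read_csv(f, dtype=str, keep_default_na=False)
    for table in MANDATORY_TABLES:
        if table not in frames:
            raise DataLoadError(f"missing mandatory table {table}.csv in {path}")
    return frames


def load_frames(frames: Dict[str, pd.DataFrame],
                ontologies: Optional[Dict[str, CodeOntology]] = None,
                drug_map: Optional[DrugClassMap] = None,
                expand: bool = True) -> PatientStore:
    """Build a store from in-memory OMOP tables (the core of :func:`load_omop`)."""
    for table in MANDATORY_TABLES:
        if table not in frames:
            raise DataLoadError(f"missing mandatory table {table!r}")

    person = frames["person"]
    obs = frames["observation_period"]

    spans: Dict[str, Interval] = {}
    for i, row in enumerate(obs.itertuples(index=False)):
        pid = str(row.person_id)
        s = _parse_day(row.observation_period_start_date, "observation_period", i)
        e = _parse_day(row.observation_period_end_date, "observation_period", i)
        if s >= e:
            raise DataLoadError(
                f"observation_period.csv row {i}: empty span for patient {pid}")
        if pid in spans:  # multiple periods: keep the covering span
            spans[pid] = Interval(min(spans[pid].start, s), max(spans[pid].end, e))
        else:
            spans[pid] = Interval(s, e)

    patients: Dict[str, PatientObject] = {}
    for i, row in enumerate(person.itertuples(index=False)):
        pid = str(row.person_id)
        if pid in patients:
            raise DataLoadError(f"person.csv row {i}: duplicate patient_id {pid!r}")
        year = int(row.year_of_birth)
        month = int(getattr(row, "month_of_birth", 1) or 1)
        day = int(getattr(row, "day_of_birth", 1) or 1)
        birth = date_to_day(_dt.date(year, month, day))
        span = spans.get(pid)
        if span is None:
            logger.warning("person %s has no observation period; skipped", pid)
            continue
        patients[pid] = PatientObject(
            patient_id=pid,
            birth_day=birth,
            gender=str(getattr(row, "gender_source_value", "")),
            race=str(getattr(row, "race_source_value", "")),
            span=span,
        )

    known = set(patients) | {str(r) for r in person["person_id"]}
    dropped = 0

    def add_event(pid: str, table: str, row: int, event: Event) -> None:
        nonlocal dropped
        if pid not in known:
            raise DataLoadError(f"{table}.csv row {row}: unknown person_id {pid!r}")
        patient = patients.get(pid)
        if patient is None:
            return  # person present but skipped (no observation period)
        s, e = event.interval
        span = patient.span
        if e <= span.start or s >= span.end:
            dropped += 1
            return
        clipped = Interval(max(s, span.start), min(e, span.end))
        event.interval = clipped
        patient.events.append(event)

    if "condition_occurrence" in frames:
        for i, row in enumerate(frames["condition_occurrence"].itertuples(index=False)):
            pid = str(row.person_id)
            d = _parse_day(row.condition_start_date, "condition_occurrence", i)
            ns, code = _split_source(row.condition_source_value, "condition_occurrence", i)
            add_event(pid, "condition_occurrence", i,
                      Event(FeatureKey(ns, code), Interval(d, d + 1)))

    if "procedure_occurrence" in frames:
        for i, row in enumerate(frames["procedure_occurrence"].itertuples(index=False)):
            pid = str(row.person_id)
            d = _parse_day(row.procedure_date, "procedure_occurrence", i)
            ns, code = _split_source(row.procedure_source_value,
                                     "procedure_occurrence", i, default_ns="CPT")
            add_event(pid, "procedure_occurrence", i,
                      Event(FeatureKey(ns, code), Interval(d, d + 1)))

    if "drug_exposure" in frames:
        df = frames["drug_exposure"]
        has_end = "drug_exposure_end_date" in df.columns
        for i, row in enumerate(df.itertuples(index=False)):
            pid = str(row.person_id)
            s = _parse_day(row.drug_exposure_start_date, "drug_exposure", i)
            e = s + 1
            if has_end and str(row.drug_exposure_end_date).strip():
                # inclusive end date -> half-open interval
                e = max(_parse_day(row.drug_exposure_end_date, "drug_exposure", i) + 1,
                        s + 1)
            code = str(row.drug_source_value).strip()
            add_event(pid, "drug_exposure", i,
                      Event(FeatureKey("RX", code), Interval(s, e)))

    if "measurement" in frames:
        for i, row in enumerate(frames["measurement"].itertuples(index=False)):
            pid = str(row.person_id)
            d = _parse_day(row.measurement_date, "measurement", i)
            raw = str(row.value_as_number).strip()
            try:
                value = float(raw)
            except ValueError:
                raise DataLoadError(
                    f"measurement.csv row {i}: non-numeric value {raw!r}") from None
            code = str(row.measurement_source_value).strip()
            add_event(pid, "measurement", i,
                      Event(FeatureKey("LOINC", code), Interval(d, d + 1), value=value))

    if "text_mention" in frames:
        for i, row in enumerate(frames["text_mention"].itertuples(index=False)):
            pid = str(row.person_id)
            d = _parse_day(row.note_date, "text_mention", i)
            flags = set()
            if str(getattr(row, "negated", "0")).strip() in ("1", "true", "True"):
                flags.add("NEGATED")
            if str(getattr(row, "family_history", "0")).strip() in ("1", "true", "True"):
                flags.add("FAMILY_HISTORY")
            phrase = str(row.phrase).strip().lower()
            add_event(pid, "text_mention", i,
                      Event(FeatureKey("TEXT", phrase), Interval(d, d + 1),
                            flags=frozenset(flags)))
            note_type = str(getattr(row, "note_type", "")).strip().lower()
            if note_type:
                add_event(pid, "text_mention", i,
                          Event(FeatureKey("NOTE_TYPE", note_type), Interval(d, d + 1)))

    if dropped:
        logger.warning("dropped %d events entirely outside their patient's "
                       "observation period", dropped)

    if expand and (ontologies or drug_map):
        for p in patients.values():
            expand_events(p, ontologies, drug_map)
    for p in patients.values():
        p.rebuild_key_index()
    return build_store(patients.values())


def load_omop(path,
              ontologies: Optional[Dict[str, CodeOntology]] = None,
              drug_map: Optional[DrugClassMap] = None,
              expand: bool = True) -> PatientStore:
    """Load an OMOP subset directory into a fully indexed :class:`PatientStore`."""
    return load_frames(read_omop_dir(path), ontologies, drug_map, expand)


# ---------------------------------------------------------------------------
# Shard files
# ---------------------------------------------------------------------------

def shard_of(patient_id: str, n_shards: int) -> int:
    """Deterministic shard assignment by patient-id hash."""
    return zlib.crc32(patient_id.encode("utf-8")) % n_shards


def _patient_to_obj(p: PatientObject) -> dict:
    return {
        "patient_id": p.patient_id,
        "birth_day": p.birth_day,
        "gender": p.gender,
        "race": p.race,
        "span": [p.span.start, p.span.end],
        "events": [
            [ev.key.namespace, ev.key.code, ev.interval.start, ev.interval.end,
             ev.value, sorted(ev.flags), ev.original]
            for ev in p.events
        ],
    }


def _patient_from_obj(obj: dict) -> PatientObject:
    p = PatientObject(
        patient_id=obj["patient_id"],
        birth_day=obj["birth_day"],
        gender=obj["gender"],
        race=obj["race"],
        span=Interval(*obj["span"]),
        events=[
            Event(FeatureKey(ns, code), Interval(s, e), value=value,
                  flags=frozenset(flags), original=original)
            for ns, code, s, e, value, flags, original in obj["events"]
        ],
    )
    p.rebuild_key_index()
    return p


def write_shards(store: PatientStore, path, n_shards: int = 1,
                 ontology_labels: Optional[Dict[str, str]] = None) -> dict:
    """Write the store as ``n_shards`` self-contained JSON shard files.

    Returns the manifest (also written as ``manifest.json``).  Partitioning
    is deterministic by patient-id hash, so rewrites are stable.
    """
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    buckets: List[List[str]] = [[] for _ in range(n_shards)]
    for pid in sorted(store.patients):
        buckets[shard_of(pid, n_shards)].append(pid)

    shard_infos = []
    for i, pids in enumerate(buckets):
        shard_id = f"shard-{i:04d}"
        payload = {
            "shard_id": shard_id,
            "patients": [_patient_to_obj(store.patients[pid]) for pid in pids],
        }
        with open(path / f"{shard_id}.json", "w") as fh:
            json.dump(payload, fh, separators=(",", ":"))
        shard_infos.append({"id": shard_id, "n_patients": len(pids)})

    manifest = {
        "format_version": 1,
        "epoch": "1900-01-01",
        "n_shards": n_shards,
        "n_patients": len(store.patients),
        "shards": shard_infos,
        "ontologies": ontology_labels or {},
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_shards(path, shard_ids: Optional[Sequence[str]] = None) -> PatientStore:
    """Reload a shard directory (all shards, or any subset by id)."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise DataLoadError(f"no manifest.json in {path}")
    with open(manifest_file) as fh:
        manifest = json.load(fh)
    available = [s["id"] for s in manifest["shards"]]
    wanted = list(shard_ids) if shard_ids is not None else available
    unknown = set(wanted) - set(available)
    if unknown:
        raise DataLoadError(f"unknown shard ids: {sorted(unknown)}")
    patients: List[PatientObject] = []
    for sid in wanted:
        with open(path / f"{sid}.json") as fh:
            payload = json.load(fh)
        patients.extend(_patient_from_obj(obj) for obj in payload["patients"])
    return build_store(patients, shards=wanted)
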