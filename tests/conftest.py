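"""Shared fixtures: tiny hand-built patients/stores and seeded RNG helpers."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ehrtql.knowledge import CodeOntology, DrugClassMap
from ehrtql.model import (Event, FeatureKey, Interval, PatientObject,
                          build_store)

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_patient(pid="P1", birth_day=0, gender="male", race="white",
                 span=(10_000, 14_000), events=()):
    """Build a PatientObject from (namespace, code, day[, value[, original]])
    tuples; point events on the given day."""
    evs = []
    for spec in events:
        ns, code, day = spec[0], spec[1], spec[2]
        value = spec[3] if len(spec) > 3 else None
        original = spec[4] if len(spec) > 4 else True
        evs.append(Event(FeatureKey(ns, code), Interval(day, day + 1),
                         value=value, original=original))
    p = PatientObject(patient_id=pid, birth_day=birth_day, gender=gender,
                      race=race, span=Interval(*span), events=evs)
    p.rebuild_key_index()
    return p


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture
def toy_icd9():
    return CodeOntology.from_edges("ICD9", [
        ("250.00", "250.0"), ("250.01", "250.0"), ("250.02", "250.0"),
        ("250.03", "250.0"), ("250.0", "250"),
        ("434.91", "434.9"), ("434.9", "434"),
    ])


@pytest.fixture
def toy_atc():
    return CodeOntology.from_edges("ATC", [
        ("N02BE", "N02B"), ("N02B", "N02"), ("N02", "N"),
        ("A10BB", "A10B"), ("A10B", "A10"), ("A10", "A"),
    ])


@pytest.fixture
def toy_drug_map(toy_atc):
    return DrugClassMap({"161": frozenset({"N02BE"}),
                         "310490": frozenset({"A10BB"})}, toy_atc)


@pytest.fixture
def small_store(patient_factory):
    """Ten patients with varied coded events for index/scan checks."""
    rng = np.random.default_rng(1234)
    codes = [("ICD9", "250.00"), ("ICD9", "434.91"), ("ICD10", "E11.9"),
             ("CPT", "99213"), ("RX", "310490"), ("RX", "161")]
    patients = []
    for i in range(10):
        n_events = int(rng.integers(0, 8))
        events = []
        for _ in range(n_events):
            ns, code = codes[int(rng.integers(0, len(codes)))]
            day = int(rng.integers(10_000, 13_900))
            events.append((ns, code, day))
        patients.append(patient_factory(
            pid=f"P{i}", gender="male" if i % 2 else "female",
            birth_day=int(rng.integers(-20_000, 0)), events=events))
    return build_store(patients)


def random_interval_set(rng, span=(0, 500), max_intervals=6):
    """Raw (possibly overlapping) intervals inside span for coalesce tests."""
    n = int(rng.integers(0, max_intervals + 1))
    out = []
    for _ in range(n):
        s = int(rng.integers(span[0], span[1] - 1))
        e = s + int(rng.integers(1, 40))
        out.append((s, min(e, span[1])))
    return out
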