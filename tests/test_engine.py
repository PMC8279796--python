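"""Per-patient evaluation semantics, candidate soundness, and the core
index/scan equivalence property."""

import numpy as np
import pytest

from conftest import make_patient
from ehrtql import dayset, randgen, synth
from ehrtql.engine import candidate_set, evaluate_patient, execute, execute_text
from ehrtql.errors import EvalError, TQLSyntaxError
from ehrtql.knowledge import expand_events
from ehrtql.model import FeatureKey, Interval, build_store, coalesce
from ehrtql.parser import parse_expression, parse_program

SPAN = (10_000, 14_000)


def ev_days(expr_text, patient, **kw):
    return evaluate_patient(parse_expression(expr_text), patient, **kw).days()


class TestSelectorSemantics:
    def test_feature_selector_coalesces_event_days(self, patient_factory):
        p = patient_factory(events=[("ICD9", "434.91", 12_000),
                                    ("ICD9", "434.91", 12_000),
                                    ("ICD9", "434.91", 12_500)])
        assert ev_days('ICD9="434.91"', p) == {12_000, 12_500}

    def test_demographic_selectors_return_span_case_insensitively(self, patient_factory):
        p = patient_factory(gender="male", race="white")
        assert ev_days('GENDER="MALE"', p) == set(range(*SPAN))
        assert ev_days('GENDER="female"', p) == set()
        assert ev_days('RACE="White"', p) == set(range(*SPAN))

    def test_age_selector_clipped_to_span(self, patient_factory):
        p = patient_factory(birth_day=0)  # span [10000, 14000)
        assert ev_days("AGE(30 YEARS, MAX)", p) == set(range(10_950, 14_000))
        assert ev_days("AGE(60 YEARS, MAX)", p) == set()

    def test_labs_value_filter(self, patient_factory):
        p = patient_factory(events=[("LOINC", "4548-4 [%]", 12_000, 8.5),
                                    ("LOINC", "4548-4 [%]", 12_100, 6.0)])
        assert ev_days('LABS("4548-4 [%]", 8, MAX)', p) == {12_000}
        assert ev_days('LABS("4548-4 [%]", 0, 7)', p) == {12_100}

    def test_text_selector_respects_flags(self):
        from ehrtql.model import Event
        p = make_patient()
        p.events = [Event(FeatureKey("TEXT", "cough"), Interval(12_000, 12_001)),
                    Event(FeatureKey("TEXT", "cough"), Interval(12_100, 12_101),
                          flags=frozenset({"NEGATED"}))]
        p.rebuild_key_index()
        assert ev_days('TEXT("cough")', p) == {12_000}
        assert ev_days('TEXT("cough", NEGATED)', p) == {12_100}

    def test_empty_patient_matches_nothing(self, patient_factory):
        p = patient_factory(gender="unknown", race="unknown", events=[])
        for q in ['ICD9="250.00"', 'GENDER="male"', 'LABS("x", 0, MAX)',
                  'UNION(ICD9="1", RX="2")']:
            assert ev_days(q, p) == set()


class TestBooleanAndDiff:
    def test_boolean_ops_return_span_or_empty(self, patient_factory):
        p = patient_factory(events=[("ICD9", "250.00", 12_000)])
        span_days = set(range(*SPAN))
        assert ev_days('AND(ICD9="250.00", GENDER="male")', p) == span_days
        assert ev_days('AND(ICD9="250.00", ICD9="999")', p) == set()
        assert ev_days('OR(ICD9="999", ICD9="250.00")', p) == span_days
        assert ev_days('NOT(ICD9="250.00")', p) == set()
        assert ev_days('NOT(ICD9="999", ICD9="998")', p) == span_days

    def test_diff_keeps_first_operand_intervals(self, patient_factory):
        p = patient_factory(events=[("ICD9", "466.0", 12_000),
                                    ("RX", "723", 12_002)])
        assert ev_days('DIFF(ICD9="466.0", RX="999")', p) == {12_000}
        assert ev_days('DIFF(ICD9="466.0", RX="723")', p) == set()


class TestOriginalAndHierarchy:
    @pytest.fixture
    def expanded_patient(self, toy_icd9):
        p = make_patient(events=[("ICD9", "250.02", 12_000)])
        return expand_events(p, {"ICD9": toy_icd9})

    def test_parent_queries_match_after_expansion(self, expanded_patient):
        for code in ("250.02", "250.0", "250"):
            assert ev_days(f'ICD9="{code}"', expanded_patient) == {12_000}

    def test_original_restricts_to_source_codes(self, expanded_patient):
        assert ev_days('ORIGINAL(ICD9="250.02")', expanded_patient) == {12_000}
        assert ev_days('ORIGINAL(ICD9="250.0")', expanded_patient) == set()
        assert ev_days('ORIGINAL(ICD9="250")', expanded_patient) == set()

    def test_expansion_is_monotone_for_queries(self, toy_icd9):
        # with expansion, every query matches at least what ORIGINAL matches
        p = make_patient(events=[("ICD9", "250.02", 12_000),
                                 ("ICD9", "250.0", 12_500)])
        expand_events(p, {"ICD9": toy_icd9})
        for code in ("250.02", "250.0", "250"):
            plain = ev_days(f'ICD9="{code}"', p)
            orig = ev_days(f'ORIGINAL(ICD9="{code}")', p)
            assert orig <= plain


class TestTrialEligibilityExample:
    def test_carcinoma_in_situ_inclusion(self, patient_factory):
        """Female, 72 at diagnosis, breast carcinoma in situ, no prior
        invasive-cancer code: matched on the diagnosis day."""
        birth = 0
        dx_day = 72 * 365
        p = patient_factory(gender="female", birth_day=birth,
                            span=(70 * 365, 75 * 365),
                            events=[("ICD9", "233.0", dx_day)])
        program = parse_program(
            'varage= AGE(70 YEARS, MAX)\n'
            'varfemale= GENDER="FEMALE"\n'
            'varbcis= INTERSECT(ICD9="233.0", NO HISTORY OF(ICD9="174"))\n'
            'INTERSECT($bcis,$age,$female)')
        got = evaluate_patient(program.final_expr, p, {}, program.var_defs)
        assert got == coalesce([(dx_day, dx_day + 1)])

    def test_prior_invasive_code_excludes(self, patient_factory):
        p = patient_factory(gender="female", birth_day=0, span=(70 * 365, 75 * 365),
                            events=[("ICD9", "174", 71 * 365),
                                    ("ICD9", "233.0", 72 * 365)])
        program = parse_program(
            'varbcis= INTERSECT(ICD9="233.0", NO HISTORY OF(ICD9="174"))\n$bcis')
        assert not evaluate_patient(program.final_expr, p, {}, program.var_defs)


class TestCandidates:
    def test_selector_candidates_are_index_postings(self, small_store):
        expr = parse_expression('ICD9="250.00"')
        assert (candidate_set(expr, small_store)
                == small_store.lookup(FeatureKey("ICD9", "250.00")))
        assert candidate_set(parse_expression('ICD9="nope"'), small_store) == frozenset()

    def test_intersection_of_postings(self, small_store):
        expr = parse_expression('INTERSECT(GENDER="male", ICD9="250.00", RX="161")')
        expected = (small_store.lookup(FeatureKey("GENDER", "male"))
                    & small_store.lookup(FeatureKey("ICD9", "250.00"))
                    & small_store.lookup(FeatureKey("RX", "161")))
        assert candidate_set(expr, small_store) == expected

    def test_negation_widens_to_all_patients(self, small_store):
        expr = parse_expression('NOT(ICD9="250.00")')
        assert candidate_set(expr, small_store) == small_store.all_ids()

    def test_candidates_sound_for_random_queries(self, small_store):
        rng = np.random.default_rng(31)
        pools = synth.code_pools(small_store)
        for _ in range(100):
            expr = randgen.random_expression(rng, pools, depth=3)
            cands = candidate_set(expr, small_store)
            matched = {pid for pid, p in small_store.patients.items()
                       if evaluate_patient(expr, p)}
            assert matched <= cands


class TestExecute:
    def test_unknown_code_gives_empty_result(self, small_store):
        result = execute_text('ICD9="does-not-exist"', small_store)
        assert len(result) == 0

    def test_indexed_equals_full_scan_on_random_core_queries(self, small_store):
        rng = np.random.default_rng(32)
        pools = synth.code_pools(small_store)
        for _ in range(60):
            program = parse_program(synth.random_core_query(rng, pools))
            fast = execute(program, small_store)
            slow = execute(program, small_store, use_index=False)
            assert fast.matches == slow.matches

    def test_execution_is_deterministic(self, small_store):
        q = 'UNION(ICD9="250.00", RX="161", CPT="99213")'
        a = execute_text(q, small_store).matches
        b = execute_text(q, small_store).matches
        assert a == b

    def test_variable_context_in_errors(self, small_store):
        program = parse_program('var x = ICD9="250.00"\n$x')
        program.var_defs["x"] = object()  # corrupt AST to force an eval error
        with pytest.raises(EvalError, match="patient"):
            execute(program, small_store)

    def test_agreement_with_dayset_interpreter_on_random_asts(self, small_store):
        rng = np.random.default_rng(33)
        pools = synth.code_pools(small_store)
        patients = list(small_store.patients.values())
        for _ in range(500):
            expr = randgen.random_expression(rng, pools, depth=3)
            p = patients[int(rng.integers(0, len(patients)))]
            assert evaluate_patient(expr, p).days() == dayset.eval_days(expr, p)
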