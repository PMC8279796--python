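"""Cohort summaries, timeline tracks, EXPORT tables, JSON round-trip, CLI."""

import json

import pytest
from click.testing import CliRunner

from conftest import make_patient
from ehrtql import engine, fixtures, output, synth
from ehrtql.cli import main
from ehrtql.engine import execute
from ehrtql.errors import EvalError
from ehrtql.model import build_store
from ehrtql.parser import parse_program


@pytest.fixture(scope="module")
def t2d_store():
    spec = synth.default_specs({"t2d_labels": 120})["t2d_labels"]
    return synth.build_store(spec, seed=8)


@pytest.fixture(scope="module")
def box1_result():
    spec = synth.default_specs({"diabetes_stroke": 150})["diabetes_stroke"]
    store, truth = synth.build_store(spec, seed=8)
    return execute(fixtures.box_program(1), store), store, truth


class TestSummarize:
    def test_empty_result_zero_summary(self, t2d_store):
        store, _ = t2d_store
        result = engine.execute_text('ICD9="nope"', store)
        summary = output.summarize(result, store)
        assert summary.n_patients == 0
        assert summary.age_histogram == {} and summary.top_features["ICD"] == []

    def test_histograms_match_direct_tabulation(self, box1_result):
        result, store, _ = box1_result
        summary = output.summarize(result, store)
        assert summary.n_patients == len(result.matches) > 0
        assert sum(summary.age_histogram.values()) == summary.n_patients
        assert sum(summary.record_length_histogram.values()) == summary.n_patients
        ages = {}
        for pid, ivs in result.matches.items():
            p = store.patients[pid]
            y = (ivs.first().start - p.birth_day) // 365
            label = output.AGE_BIN_LABELS[min(y // 10, 10)]
            ages[label] = ages.get(label, 0) + 1
        assert summary.age_histogram == ages
        # all planted qualifiers are male seniors
        assert set(summary.gender_counts) == {"male"}
        assert set(summary.age_histogram) <= {"60-69", "70-79", "80-89", "90-99"}

    def test_top_features_ordered_by_patient_count_then_code(self, box1_result):
        result, store, _ = box1_result
        summary = output.summarize(result, store, k=5)
        for group, feats in summary.top_features.items():
            counts = [c for _, c in feats]
            assert counts == sorted(counts, reverse=True)
            for (c1, n1), (c2, n2) in zip(feats, feats[1:]):
                if n1 == n2:
                    assert c1 < c2
        # every matched patient carries the planted stroke code and glipizide
        assert dict(summary.top_features["ICD"]).get("434.91") == summary.n_patients
        assert dict(summary.top_features["RX"]).get("310490") == summary.n_patients

    def test_counts_reproducible_by_independent_tabulation(self, box1_result):
        result, store, _ = box1_result
        summary = output.summarize(result, store, k=3)
        code, n = summary.top_features["RX"][0]
        direct = sum(
            1 for pid in result.matches
            if any(ev.original and ev.key.namespace == "RX" and ev.key.code == code
                   for ev in store.patients[pid].events))
        assert n == direct


class TestTimelines:
    def test_tracks_subset_of_variable_evaluation(self, box1_result):
        result, store, _ = box1_result
        tracks = output.timelines(result, ["diabetes_then_glipizide",
                                           "glipizide_then_stroke"])
        assert set(tracks) == set(result.matches)
        for pid, row in tracks.items():
            p = store.patients[pid]
            for name, ivs in row.items():
                again = engine.evaluate_patient(
                    result.program.var_defs[name], p, {}, result.program.var_defs)
                assert ivs == again

    def test_no_variables_gives_empty_tracks(self, box1_result):
        result, _, _ = box1_result
        tracks = output.timelines(result, [])
        assert all(row == {} for row in tracks.values())

    def test_unknown_variable_rejected(self, box1_result):
        result, _, _ = box1_result
        with pytest.raises(EvalError, match="unknown variable"):
            output.timelines(result, ["nope"])


class TestExport:
    def test_t2d_labels_export(self, t2d_store):
        store, truth = t2d_store
        program = fixtures.box_program(4)
        table = output.export_flat(program, store)
        assert list(table.columns) == ["patient_id", "TIME", "T2D"]
        assert list(table.patient_id) == list(truth.patient_id)
        assert list(table.TIME) == list(truth.first_date)
        assert set(table["T2D"]) <= {1}

    def test_empty_cohort_exports_header_only(self, patient_factory):
        store = build_store([patient_factory()])
        program = parse_program(
            'var x = ICD9="000.0"\nEXPORT($x, TIME=$x, "L"=$x)')
        table = output.export_flat(program, store)
        assert len(table) == 0
        assert list(table.columns) == ["patient_id", "TIME", "L"]

    def test_labs_column_exports_first_in_range_value(self, patient_factory):
        p = patient_factory(events=[("ICD9", "250.00", 12_000),
                                    ("LOINC", "4548-4 [%]", 12_100, 9.5),
                                    ("LOINC", "4548-4 [%]", 12_200, 8.2)])
        store = build_store([p])
        program = parse_program(
            'var x = ICD9="250.00"\n'
            'EXPORT($x, TIME=$x, "A1C"=LABS("4548-4 [%]", 8, MAX))')
        table = output.export_flat(program, store)
        assert list(table["A1C"]) == [9.5]

    def test_row_count_equals_cohort_size(self, t2d_store):
        store, _ = t2d_store
        program = fixtures.box_program(4)
        table = output.export_flat(program, store)
        assert len(table) == len(engine.execute(program, store))


class TestJsonRoundTrip:
    def test_matches_survive_serialization(self, box1_result):
        result, _, _ = box1_result
        text = output.result_to_json(result)
        assert output.matches_from_json(text) == result.matches
        assert json.loads(text)["n_patients"] == len(result.matches)


class TestCli:
    @pytest.fixture(scope="class")
    @staticmethod
    def synth_dir(tmp_path_factory):
        out = tmp_path_factory.mktemp("synth")
        runner = CliRunner()
        res = runner.invoke(main, ["synth", "--spec", "breast_ca_trial",
                                   "--n", "80", "--seed", "13", "--out", str(out)])
        assert res.exit_code == 0, res.output
        return out

    def test_query_json_end_to_end(self, synth_dir, tmp_path):
        q = tmp_path / "box3.tql"
        q.write_text(fixtures.box_text(3))
        res = CliRunner().invoke(main, ["query", "--data", str(synth_dir),
                                        "--query", str(q)])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        truth = (synth_dir / "ground_truth.csv").read_text().splitlines()[1:]
        assert sorted(payload["patients"]) == [l.split(",")[1] for l in truth]

    def test_malformed_query_exits_3_naming_token(self, synth_dir, tmp_path):
        q = tmp_path / "bad.tql"
        q.write_text('INTERSECT(ICD9="233.0" BOGUS')
        res = CliRunner().invoke(main, ["query", "--data", str(synth_dir),
                                        "--query", str(q)])
        assert res.exit_code == 3
        assert "BOGUS" in res.output

    def test_etl_then_query_equals_in_memory(self, synth_dir, tmp_path):
        shard_dir = tmp_path / "store"
        res = CliRunner().invoke(main, ["etl", "--omop", str(synth_dir),
                                        "--out", str(shard_dir), "--shards", "3"])
        assert res.exit_code == 0, res.output
        q = tmp_path / "box3.tql"
        q.write_text(fixtures.box_text(3))
        from_shards = CliRunner().invoke(
            main, ["query", "--data", str(shard_dir), "--query", str(q)])
        from_csvs = CliRunner().invoke(
            main, ["query", "--data", str(synth_dir), "--query", str(q)])
        assert from_shards.exit_code == from_csvs.exit_code == 0
        assert (json.loads(from_shards.output)["patients"]
                == json.loads(from_csvs.output)["patients"])

    def test_summary_format(self, synth_dir, tmp_path):
        q = tmp_path / "box3.tql"
        q.write_text(fixtures.box_text(3))
        res = CliRunner().invoke(main, ["query", "--data", str(synth_dir),
                                        "--query", str(q),
                                        "--out-format", "summary"])
        assert res.exit_code == 0
        summary = json.loads(res.output)
        assert summary["n_patients"] == sum(summary["age_histogram"].values())
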