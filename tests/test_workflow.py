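import json

import numpy as np
import pytest
from click.testing import CliRunner

from tmsid.cli import main as cli_main
from tmsid.evaluation import summarize
from tmsid.synthetic_data import (GeneratorConfig, make_benchmark,
                                  write_bundle)
from tmsid.workflow import (RunConfig, groups_from_bundle, load_bundle,
                            run_evaluate, run_identify, run_train)


class TestTrain:
    def test_completes_with_report_schema(self, trained_small):
        rep = trained_small.report
        assert set(rep) >= {"curation", "fingerprints", "model"}
        assert rep["curation"]["n_input"] == 60
        assert rep["curation"]["n_output"] == 60  # compliant bundle: no removals
        assert rep["model"]["lambda"] > 0
        assert rep["fingerprints"]["n_retained"] == trained_small.mask.n_retained

    def test_rerun_same_config_identical_model_hash(self, small_bundle):
        a = run_train(RunConfig(master_seed=3), small_bundle)
        b = run_train(RunConfig(master_seed=3), small_bundle)
        assert a.model_hash() == b.model_hash()

    def test_missing_source_errors(self):
        with pytest.raises(ValueError, match="no data source"):
            run_train(RunConfig())
        with pytest.raises(FileNotFoundError, match="structures"):
            run_train(RunConfig(bundle_dir="/nonexistent/path"))


class TestIdentify:
    def test_one_row_per_query_candidate(self, small_bundle, trained_small):
        results, table = run_identify(RunConfig(master_seed=3),
                                      trained_small, small_bundle)
        assert len(results) == len(small_bundle.test_queries)
        expected_rows = sum(len(cs.candidates)
                            for cs in small_bundle.candidate_sets.values())
        assert len(table[table["error"] == ""]) == expected_rows

    def test_identical_query_spectra_identical_ranks(self, small_bundle,
                                                     trained_small):
        q = small_bundle.test_queries[0]
        import copy
        bundle2 = copy.copy(small_bundle)
        bundle2.test_queries = [q, q]
        results, _ = run_identify(RunConfig(master_seed=3), trained_small, bundle2)
        assert results[0].ranking == results[1].ranking

    def test_empty_candidate_set_recorded_not_fatal(self, small_bundle,
                                                    trained_small):
        import copy
        bundle2 = copy.copy(small_bundle)
        bundle2.candidate_sets = dict(small_bundle.candidate_sets)
        qid = small_bundle.test_queries[0].record.record_id
        del bundle2.candidate_sets[qid]
        results, table = run_identify(RunConfig(master_seed=3),
                                      trained_small, bundle2)
        assert len(results) == len(small_bundle.test_queries) - 1
        err_rows = table[table["error"] != ""]
        assert list(err_rows["query_id"]) == [qid]


class TestEvaluate:
    def test_matches_direct_evaluation_module_call(self, small_bundle,
                                                   trained_small, tmp_path):
        cfg = RunConfig(master_seed=3, out_dir=str(tmp_path))
        results, _ = run_identify(cfg, trained_small, small_bundle)
        out = run_evaluate(cfg, results, groups_from_bundle(small_bundle))
        direct = summarize(results)[0]
        merged = out["merged"][0]
        assert merged.top_k == direct.top_k
        assert merged.mean_rrp == direct.mean_rrp
        assert {"Yes", "No"} <= {s.group for s in out["in_training"]}
        assert (tmp_path / "summary.json").exists()
        payload = json.loads((tmp_path / "summary.json").read_text())
        assert "merged" in payload and "class" in payload

    def test_merged_only_without_groups(self, small_bundle, trained_small):
        results, _ = run_identify(RunConfig(master_seed=3), trained_small,
                                  small_bundle)
        out = run_evaluate(RunConfig(master_seed=3), results)
        assert list(out) == ["merged"]


class TestBundleSerialization:
    def test_write_load_round_trip_preserves_results(self, small_bundle,
                                                     trained_small, tmp_path):
        write_bundle(small_bundle, tmp_path / "b")
        loaded = load_bundle(tmp_path / "b")
        assert len(loaded.train_records) == len(small_bundle.train_records)
        assert len(loaded.test_queries) == len(small_bundle.test_queries)
        r1, _ = run_identify(RunConfig(master_seed=3), trained_small, small_bundle)
        r2, _ = run_identify(RunConfig(master_seed=3), trained_small, loaded)
        assert [(r.query_id, r.rank_of_true) for r in r1] == \
               [(r.query_id, r.rank_of_true) for r in r2]

    def test_bundle_hash_deterministic(self):
        cfg = GeneratorConfig(n_train=12, n_test=4, master_seed=17)
        assert make_benchmark(cfg).content_hash() == \
            make_benchmark(cfg).content_hash()


class TestCLI:
    def test_synth_curate_train_smoke(self, tmp_path):
        runner = CliRunner()
        bdir = str(tmp_path / "bundle")
        res = runner.invoke(cli_main, ["synth", "--out", bdir, "--seed", "4",
                                       "--n-train", "30", "--n-test", "5"])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["curate", "--bundle", bdir,
                                       "--report", str(tmp_path / "rep.json")])
        assert res.exit_code == 0, res.output
        assert "30 -> 30" in res.output
        rep = json.loads((tmp_path / "rep.json").read_text())
        assert rep["n_input"] == 30
        res = runner.invoke(cli_main, ["train", "--bundle", bdir,
                                       "--out", str(tmp_path / "out"),
                                       "--seed", "4"])
        assert res.exit_code == 0, res.output
        assert "IOKR Results" in res.output
        assert (tmp_path / "out" / "train_report.json").exists()

    def test_config_error_exit_code(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["curate", "--bundle",
                                       str(tmp_path / "missing")])
        assert res.exit_code == 2
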