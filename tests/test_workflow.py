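"""Fixtures consistency, end-to-end benchmark runs, ranking comparison, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from diagrank import fixtures, workflow
from diagrank.cli import main as cli_main
from diagrank.synthetic import FoldPlan, SyntheticModelSpec, simulate_predictions


class TestFixtureConsistency:
    def test_validate_fixtures_passes(self):
        fixtures.validate_fixtures()

    def test_erratum_is_the_only_correction(self):
        raw = fixtures.load_fold_accuracies(corrected=False)
        fixed = fixtures.load_fold_accuracies(corrected=True)
        diff = (raw != fixed).to_numpy().sum()
        assert diff == len(fixtures.FOLD_ACCURACY_ERRATA) == 1
        # the corrected cell reproduces the summary mean AND std exactly
        row = fixed.loc["DenseNet201"]
        assert round(row.mean(), 2) == 93.94
        assert round(row.std(ddof=1), 2) == 4.97
        # the verbatim value reproduces neither
        raw_row = raw.loc["DenseNet201"]
        assert round(raw_row.mean(), 2) != 93.94

    def test_summary_complements_hold_at_printed_precision(self):
        means = fixtures.load_criterion_means()
        assert np.allclose(means["err"], 100 - means["acc"], atol=0.005 + 1e-9)
        assert np.allclose(means["fnr"], 100 - means["sen"], atol=0.005 + 1e-9)
        assert np.allclose(means["fpr"], 100 - means["spe"], atol=0.005 + 1e-9)


class TestCompareRankings:
    def test_published_columns_agree_at_fourteen_positions(
        self, reference_rankings
    ):
        agr = workflow.compare_rankings(
            reference_rankings["rank_promethee"], reference_rankings["rank_vikor"]
        )
        assert agr.n_identical == 14
        assert agr.identical_ranks == (1, 2, 3, 4, 5, 6, 7, 10, 11, 12, 13, 15, 18, 19)

    def test_identical_rankings(self, reference_rankings):
        r = reference_rankings["rank_promethee"]
        agr = workflow.compare_rankings(r, r.copy())
        assert agr.n_identical == agr.n_alternatives == 19
        assert agr.spearman == pytest.approx(1.0)

    def test_reversed_five_item_ranking(self):
        r1 = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        r2 = pd.Series({"a": 5, "b": 4, "c": 3, "d": 2, "e": 1})
        agr = workflow.compare_rankings(r1, r2)
        assert agr.n_identical == 1  # only the middle position survives
        assert agr.identical_ranks == (3,)
        assert agr.spearman == pytest.approx(-1.0)

    def test_mismatched_alternative_sets_rejected(self):
        with pytest.raises(ValueError):
            workflow.compare_rankings(
                pd.Series({"a": 1, "b": 2}), pd.Series({"a": 1, "c": 2})
            )


class TestRunBenchmark:
    @pytest.fixture
    def predictions_csv(self, tmp_path):
        specs = [
            SyntheticModelSpec("good", 0.95, 0.95, 2.0),
            SyntheticModelSpec("bad", 0.7, 0.7, 80.0),
        ]
        plan = FoldPlan(n_pos=200, n_neg=200, n_folds=5, seed=21)
        path = tmp_path / "preds.csv"
        simulate_predictions(specs, plan).to_csv(path, index=False)
        return path

    def test_dominant_model_wins_both_methods(self, predictions_csv):
        report = workflow.run_benchmark(
            {
                "predictions": str(predictions_csv),
                "complexity": {"good": 2.0, "bad": 80.0},
                "positive_label": "positive",
                "weights": "entropy",
            }
        )
        assert report.promethee.rank_["good"] == 1
        assert report.vikor.rank_["good"] == 1
        assert report.weights.provenance == "entropy"

    def test_matrix_input_with_yaml_config(self, tmp_path, case_matrix):
        matrix_path = tmp_path / "dm.csv"
        case_matrix.to_csv(matrix_path)
        cfg = {
            "matrix": str(matrix_path),
            "directions": dict(case_matrix.directions),
            "weights": "published",
            "promethee": {"flow_convention": "summed"},
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        report = workflow.run_benchmark(cfg_path)
        assert report.promethee.phi_["ResNet101"] == pytest.approx(
            150.8418215, abs=1e-3
        )

    def test_matrix_without_directions_rejected(self, tmp_path, case_matrix):
        matrix_path = tmp_path / "dm.csv"
        case_matrix.to_csv(matrix_path)
        with pytest.raises(ValueError, match="direction"):
            workflow.run_benchmark({"matrix": str(matrix_path)})

    def test_reports_byte_identical_across_runs(self, predictions_csv, tmp_path):
        cfg = {
            "predictions": str(predictions_csv),
            "complexity": {"good": 2.0, "bad": 80.0},
            "positive_label": "positive",
        }
        workflow.run_benchmark(cfg).save(tmp_path / "r1")
        workflow.run_benchmark(cfg).save(tmp_path / "r2")
        for name in ("report.json", "rankings.csv", "weights.csv"):
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()


@pytest.fixture(scope="module")
def rep():
    return workflow.reproduce_case_study()


class TestReproduceCaseStudy:

    def test_all_normalized_cells_match(self, rep):
        assert rep.summary["normalized_cells_matching_4dp"] == 190
        assert rep.summary["normalized_cells_total"] == 190

    def test_densenet_flow_second_best(self, rep):
        phi = rep.benchmark.promethee.phi_
        assert round(float(phi["DenseNet201"]), 2) == 133.24
        assert rep.benchmark.promethee.rank_["DenseNet201"] == 2

    def test_published_ranking_and_q_endpoints(self, rep):
        assert rep.summary["promethee_ranks_identical"] is True
        assert rep.summary["Q_endpoints"] == {"min": 0.0, "max": 1.0}
        assert rep.summary["max_abs_phi_delta"] <= 1e-3

    def test_vikor_rank_extremes(self, rep):
        ranks = rep.benchmark.vikor.rank_
        assert ranks["ResNet101"] == 1
        assert ranks["DenseNet201"] == 2
        assert ranks["SqueezeNet"] == 19


class TestCli:
    def test_simulate_metrics_rank_round_trip(self, tmp_path):
        runner = CliRunner()
        models = [
            {"model_id": "good", "sensitivity": 0.95, "specificity": 0.9, "n_params": 2.0},
            {"model_id": "bad", "sensitivity": 0.7, "specificity": 0.65, "n_params": 80.0},
        ]
        models_path = tmp_path / "models.yaml"
        models_path.write_text(yaml.safe_dump(models))
        preds_path = tmp_path / "preds.csv"
        result = runner.invoke(
            cli_main,
            [
                "simulate", "--models", str(models_path), "--n-pos", "100",
                "--n-neg", "100", "--folds", "5", "--seed", "4",
                "--out", str(preds_path),
            ],
        )
        assert result.exit_code == 0, result.output

        comp_path = tmp_path / "complexity.csv"
        pd.DataFrame(
            {"alternative": ["good", "bad"], "n_params": [2.0, 80.0]}
        ).to_csv(comp_path, index=False)
        out_path = tmp_path / "summary.csv"
        result = runner.invoke(
            cli_main,
            [
                "metrics", str(preds_path), "--complexity", str(comp_path),
                "--out", str(out_path),
            ],
        )
        assert result.exit_code == 0, result.output
        summary = pd.read_csv(out_path, index_col=0)
        assert set(summary.index) == {"good", "bad"}

    def test_reproduce_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["reproduce", "--outdir", str(tmp_path / "out")]
        )
        assert result.exit_code == 0, result.output
        assert "normalized_cells_matching_4dp: 190" in result.output
        report = json.loads((tmp_path / "out" / "report.json").read_text())
        assert report["promethee"]["rank"]["ResNet101"] == 1
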