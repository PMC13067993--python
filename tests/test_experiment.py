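"""Monte-Carlo harness tests: aggregation arithmetic, seed determinism,
CV gating by sample size, and output files."""

import numpy as np
import pandas as pd
import pytest

from arselect.dgp import get_condition
from arselect.experiment import (
    StudyConfig,
    aggregate,
    rankings_to_frame,
    render_markdown,
    replicate_seed,
    results_to_frame,
    run_cell,
    run_replicate,
    run_study,
)


@pytest.fixture(scope="module")
def tiny_config():
    return StudyConfig(
        conditions=[get_condition("white_noise")],
        sample_sizes=(50,),
        n_reps=4,
        master_seed=123,
        criteria=("AIC", "BIC"),
    )


class TestAggregation:
    def test_arithmetic_on_known_ranks(self, tiny_config):
        """ranks {1,1,2,1}: mean 1.25, proportion .75, SE(prop) .2165."""
        cond = get_condition("white_noise")
        reps = [run_replicate(cond, 50, replicate_seed(123, cond, 50, i), tiny_config) for i in range(4)]
        # overwrite the recorded ranks with a known pattern
        for rep, r in zip(reps, (1, 1, 2, 1)):
            rep.rankings["BIC"].rank_of_true = r
        res = aggregate(reps)
        s = res.criteria["BIC"]
        assert abs(s["mean_rank_true"] - 1.25) < 1e-12
        assert abs(s["proportion_correct"] - 0.75) < 1e-12
        assert abs(s["se_proportion"] - 0.21650635094610965) < 1e-10

    def test_perfect_selection_gives_zero_se(self, tiny_config):
        cond = get_condition("white_noise")
        reps = [run_replicate(cond, 50, replicate_seed(123, cond, 50, i), tiny_config) for i in range(4)]
        for rep in reps:
            rep.rankings["BIC"].rank_of_true = 1
        s = aggregate(reps).criteria["BIC"]
        assert s["proportion_correct"] == 1.0 and s["se_proportion"] == 0.0

    def test_binomial_se_matches_printed_precision(self):
        # p=.91, n=100 -> SE .0286, printed as .03
        assert round(np.sqrt(0.91 * 0.09 / 100), 2) == 0.03

    def test_single_replicate_has_missing_se(self):
        cfg = StudyConfig(
            conditions=[get_condition("white_noise")],
            sample_sizes=(50,),
            n_reps=1,
            master_seed=5,
            criteria=("BIC",),
        )
        res, _ = run_cell(get_condition("white_noise"), 50, cfg)
        s = res.criteria["BIC"]
        assert np.isnan(s["se_rank"]) and np.isnan(s["se_proportion"])

    def test_proportion_identity_from_rankings_frame(self, tiny_config):
        """proportion_correct re-derived from the raw long-format rankings."""
        res, reps = run_cell(get_condition("white_noise"), 50, tiny_config)
        frame = rankings_to_frame(reps)
        true_rows = frame[(frame.criterion == "BIC") & (frame.candidate == "white_noise")]
        recomputed = float((true_rows["rank"] == 1).mean())
        assert recomputed == res.criteria["BIC"]["proportion_correct"]


class TestReplicates:
    def test_identical_seed_identical_rankings(self, tiny_config):
        cond = get_condition("white_noise")
        seed = replicate_seed(123, cond, 50, 0)
        r1 = run_replicate(cond, 50, seed, tiny_config)
        r2 = run_replicate(cond, 50, seed, tiny_config)
        for crit in r1.rankings:
            assert r1.rankings[crit].order == r2.rankings[crit].order

    def test_all_criteria_ranked_over_nine_candidates(self, tiny_config):
        cond = get_condition("white_noise")
        r = run_replicate(cond, 50, replicate_seed(123, cond, 50, 1), tiny_config)
        for crit, ranking in r.rankings.items():
            assert sorted(ranking.ranks.values()) == list(range(1, 10))
            assert 1 <= ranking.rank_of_true <= 9

    def test_cv_gated_above_cv_max_T(self):
        cfg = StudyConfig(
            conditions=[get_condition("ar1_phi.3")],
            sample_sizes=(50,),
            n_reps=1,
            master_seed=9,
            criteria=("BIC", "LOOCV"),
            cv_max_T=30,
        )
        cond = get_condition("ar1_phi.3")
        r = run_replicate(cond, 50, replicate_seed(9, cond, 50, 0), cfg)
        assert "BIC" in r.rankings
        assert "LOOCV" not in r.rankings  # emitted as missing above the cutoff
        loocv_rows = [v for v in r.values if v.criterion == "LOOCV"]
        assert loocv_rows and all(v.missing for v in loocv_rows)


class TestStudy:
    def test_rerun_is_byte_identical(self, tmp_path, tiny_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_study(tiny_config, out_dir=d1)
        run_study(tiny_config, out_dir=d2)
        assert (d1 / "rankings.csv").read_bytes() == (d2 / "rankings.csv").read_bytes()
        assert (d1 / "results.csv").read_bytes() == (d2 / "results.csv").read_bytes()

    def test_results_frame_shape(self, tiny_config):
        results = run_study(tiny_config)
        frame = results_to_frame(results)
        assert set(frame["criterion"]) == {"AIC", "BIC"}
        assert (frame["n_reps"] == 4).all()
        assert ((frame["proportion_correct"] >= 0) & (frame["proportion_correct"] <= 1)).all()
        assert ((frame["mean_rank_true"] >= 1) & (frame["mean_rank_true"] <= 9)).all()

    def test_markdown_rendering_has_na_cells(self):
        cfg = StudyConfig(
            conditions=[get_condition("ar1_phi.3")],
            sample_sizes=(50, 300),
            n_reps=2,
            master_seed=11,
            criteria=("BIC", "BlockedCV"),
            cv_max_T=200,
        )
        text = render_markdown(run_study(cfg))
        assert "NA (NA)" in text  # CV cell at T=300
        assert "BIC" in text

    def test_yaml_config_roundtrip(self, tmp_path):
        cfg_path = tmp_path / "study.yaml"
        cfg_path.write_text(
            "labels: [white_noise, ar1_phi.3]\n"
            "sample_sizes: [50]\n"
            "n_reps: 2\n"
            "master_seed: 77\n"
            "criteria: [BIC]\n"
            "em_config: {n_restarts: 3}\n"
        )
        cfg = StudyConfig.from_yaml(cfg_path)
        assert [c.label for c in cfg.resolved_conditions()] == ["white_noise", "ar1_phi.3"]
        assert cfg.em_config.n_restarts == 3
        assert cfg.criteria == ("BIC",)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(n_reps=0)
        with pytest.raises(ValueError):
            StudyConfig(nonconverged="ignore")
        with pytest.raises(ValueError):
            StudyConfig(criteria=("BIC", "WAIC"))


class TestCLI:
    def test_generate_fit_select_pipeline(self, tmp_path):
        from click.testing import CliRunner

        from arselect.cli import main

        runner = CliRunner()
        series_path = tmp_path / "y.csv"
        r = runner.invoke(main, ["generate", "--label", "ar1_phi.3", "-T", "60", "--seed", "4", "--out", str(series_path)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["fit", "--candidate", "ar1", "--input", str(series_path)])
        assert r.exit_code == 0 and '"name": "ar1"' in r.output
        r = runner.invoke(main, ["select", "--input", str(series_path), "--criteria", "AIC,BIC"])
        assert r.exit_code == 0
        assert r.output.count("BIC,") == 9  # nine ranked candidates

    def test_study_command(self, tmp_path):
        from click.testing import CliRunner

        from arselect.cli import main

        runner = CliRunner()
        out = tmp_path / "study"
        r = runner.invoke(
            main,
            [
                "study",
                "--labels",
                "white_noise",
                "--sizes",
                "50",
                "--reps",
                "2",
                "--seed",
                "3",
                "--criteria",
                "BIC",
                "--out-dir",
                str(out),
            ],
        )
        assert r.exit_code == 0, r.output
        frame = pd.read_csv(out / "results.csv")
        assert len(frame) == 1 and frame.loc[0, "criterion"] == "BIC"
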