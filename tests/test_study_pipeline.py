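"""Pipeline tests: file dialects, end-to-end determinism, report structure,
questionnaire analysis, CLI."""

import json

import numpy as np
import pandas as pd
import pytest

import lapskill as lk
from lapskill.study_pipeline import FormatError, StageError

from conftest import make_trajectory


@pytest.fixture()
def simulated_trial():
    prof = lk.expert_profile(n_submovements=12)
    return lk.simulate_trajectory_pair(prof, 99)


class TestTrackingCsv:
    def test_round_trip_is_lossless(self, tmp_path, simulated_trial):
        left, right = simulated_trial
        path = tmp_path / "trial.csv"
        lk.write_tracking_csv(left, right, path)
        left2, right2 = lk.read_tracking_csv(path)
        for a, b in ((left, left2), (right, right2)):
            np.testing.assert_allclose(a.times, b.times, atol=1e-9)
            np.testing.assert_allclose(a.tilts, b.tilts, atol=1e-9)
            np.testing.assert_allclose(a.depths, b.depths, atol=1e-9)

    def test_missing_hand_is_explicit_error(self, tmp_path, simulated_trial):
        left, right = simulated_trial
        path = tmp_path / "trial.csv"
        lk.write_tracking_csv(left, right, path)
        df = pd.read_csv(path)
        df[df.hand == "L"].to_csv(tmp_path / "right_only.csv", index=False)
        with pytest.raises(FormatError, match="hand 'R'"):
            lk.read_tracking_csv(tmp_path / "right_only.csv")

    def test_bad_header_reports_line_one(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time,hand\n0,L\n")
        with pytest.raises(FormatError, match=":1:"):
            lk.read_tracking_csv(p)

    def test_non_numeric_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "time_s,hand,tilt1_deg,tilt2_deg,depth_mm,roll_deg\n"
            "0.0,L,1,2,50,0\n0.01,L,oops,2,50,0\n0.0,R,0,0,50,0\n"
        )
        with pytest.raises(FormatError, match=":3:"):
            lk.read_tracking_csv(p)


class TestMapTableCsv:
    def test_round_trip(self, tmp_path, reference_cohorts):
        nov, exp = reference_cohorts
        path = tmp_path / "maps.csv"
        lk.write_map_table(nov + exp, path)
        back = lk.read_map_table(path)
        assert [t.trial_id for t in back] == [t.trial_id for t in nov + exp]
        np.testing.assert_allclose(
            np.array([t.maps.as_array() for t in back]),
            np.array([t.maps.as_array() for t in nov + exp]),
            rtol=1e-8,
        )

    def test_duplicate_trial_id_rejected(self, tmp_path, reference_cohorts):
        nov, _ = reference_cohorts
        path = tmp_path / "maps.csv"
        lk.write_map_table([nov[0], nov[0]], path)
        with pytest.raises(FormatError, match="duplicate"):
            lk.read_map_table(path)


class TestRunConstructValidity:
    def test_default_run_structure(self):
        report = lk.run_construct_validity(lk.StudyConfig(seed=1))
        assert len(report.map_comparison) == 9
        c = report.classification
        assert c.total_novice + c.total_expert == 115
        assert len(report.wald_table) == 9
        assert report.provenance["config"]["seed"] == 1

    def test_same_seed_gives_byte_identical_reports(self):
        cfg = lk.StudyConfig(seed=7)
        a = json.dumps(lk.run_construct_validity(cfg).to_dict(), default=float)
        b = json.dumps(lk.run_construct_validity(cfg).to_dict(), default=float)
        assert a == b

    def test_different_seeds_differ(self):
        a = lk.run_construct_validity(lk.StudyConfig(seed=1))
        b = lk.run_construct_validity(lk.StudyConfig(seed=2))
        assert a.hotelling.statistic != b.hotelling.statistic

    def test_trajectory_tier_produces_identical_schema(self):
        cfg = lk.StudyConfig(
            seed=3, tier="trajectory", n_novice=8, n_expert=8,
            profiles=(lk.novice_profile(n_submovements=25, task_duration_cap=30),
                      lk.expert_profile(n_submovements=12, task_duration_cap=30)),
        )
        report = lk.run_construct_validity(cfg)
        d = report.to_dict()
        ref = lk.run_construct_validity(lk.StudyConfig(seed=3, n_novice=8,
                                                       n_expert=8)).to_dict()
        assert set(d) == set(ref)
        assert lk.validate_report_dict(d) == []

    def test_null_config_accuracy_near_chance(self, reference_params):
        """Identical group parameters: the classifier has nothing to learn,
        so pooled resubstitution accuracy stays near the larger-group share
        plus overfit, far below the separated-cohort regime."""
        nov_p, _ = reference_params
        null_exp = lk.GroupMAPParams(label="expert", n=56, means=nov_p.means,
                                     sds=nov_p.sds)
        null_nov = lk.GroupMAPParams(label="novice", n=59, means=nov_p.means,
                                     sds=nov_p.sds)
        accs, ps = [], []
        for seed in range(10):
            cfg = lk.StudyConfig(seed=seed, map_params=(null_nov, null_exp))
            r = lk.run_construct_validity(cfg)
            accs.append(r.classification.pct_overall)
            ps.append(r.hotelling.p)
        assert np.mean(accs) < 75.0
        assert min(ps) > 0.001 and np.mean(ps) > 0.2

    def test_partial_cohort_arguments_rejected(self, reference_cohorts):
        nov, _ = reference_cohorts
        with pytest.raises(ValueError):
            lk.run_construct_validity(lk.StudyConfig(), novice=nov)

    def test_stage_failure_names_stage(self, reference_cohorts):
        nov, exp = reference_cohorts
        with pytest.raises(StageError, match="compare"):
            lk.run_construct_validity(lk.StudyConfig(), novice=nov[:1], expert=exp)


class TestReportOutput:
    def test_write_report_files_and_schema(self, tmp_path):
        report = lk.run_construct_validity(lk.StudyConfig(seed=5))
        paths = lk.write_report(report, tmp_path / "out")
        d = json.loads(paths["report"].read_text())
        assert lk.validate_report_dict(d) == []
        cmp_csv = pd.read_csv(paths["map_comparison"])
        assert len(cmp_csv) == 9
        assert len(pd.read_csv(paths["wald"])) == 9

    def test_percentages_recomputable_from_counts(self):
        report = lk.run_construct_validity(lk.StudyConfig(seed=5))
        d = report.to_dict()["classification"]
        recomputed = round(
            100 * (d["correct_novice"] + d["correct_expert"])
            / (d["total_novice"] + d["total_expert"]), 1)
        assert d["pct_overall"] == recomputed

    def test_validator_catches_inconsistencies(self):
        d = lk.run_construct_validity(lk.StudyConfig(seed=5)).to_dict()
        d["classification"]["pct_overall"] = 12.3
        assert any("inconsistent" in p for p in lk.validate_report_dict(d))
        del d["hotelling"]
        assert any("hotelling" in p for p in lk.validate_report_dict(d))


class TestFormatP:
    @pytest.mark.parametrize("p,text", [
        (0.004, "<0.01"), (0.0049, "<0.01"), (0.005, "0.01"),
        (0.03, "0.03"), (0.5, "0.50"), (1.0, "1.00"),
    ])
    def test_journal_rounding(self, p, text):
        assert lk.format_p(p) == text


class TestQuestionnaireAnalysis:
    def test_point_mass_identical_groups_not_significant(self):
        item = lk.LikertItemParams(item="q", probs={
            "expert": (0, 0, 0, 1.0, 0), "trainee": (0, 0, 0, 1.0, 0)})
        df = lk.sample_likert_cohort([item], 20, seed=0)
        rows = lk.run_questionnaire_analysis(df)
        assert rows["mw_p"].iloc[0] >= 0.99

    def test_large_shift_detected(self):
        item = lk.LikertItemParams(item="q", probs={
            "expert": (0.0, 0.05, 0.15, 0.5, 0.3),
            "trainee": (0.5, 0.3, 0.15, 0.05, 0.0)})
        df = lk.sample_likert_cohort([item], 30, seed=1)
        rows = lk.run_questionnaire_analysis(df)
        assert rows["mw_p"].iloc[0] < 0.05
        assert rows["dichotomized_p"].iloc[0] < 0.05

    def test_dichotomization_buckets(self):
        """Score 3 falls in the low-moderate bucket, score 4 in the high
        bucket."""
        df = pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(8)],
            "group": ["expert"] * 4 + ["trainee"] * 4,
            "item": ["q"] * 8,
            "score": [3, 3, 3, 3, 4, 4, 4, 4],
        })
        rows = lk.run_questionnaire_analysis(df)
        assert rows["expert_pct_high"].iloc[0] == 0.0
        assert rows["trainee_pct_high"].iloc[0] == 100.0
        assert rows["dichotomized_method"].iloc[0] == "fisher"  # small expecteds

    def test_out_of_range_scores_rejected(self):
        df = pd.DataFrame({"respondent_id": ["a"], "group": ["expert"],
                           "item": ["q"], "score": [6]})
        with pytest.raises(ValueError):
            lk.run_questionnaire_analysis(df)

    def test_default_items_end_to_end(self):
        items = lk.default_questionnaire_params()
        df = lk.sample_likert_cohort(items, {"expert": 38, "trainee": 24}, seed=4)
        rows = lk.run_questionnaire_analysis(df)
        assert len(rows) == len(items)
        assert rows["mw_p"].between(0, 1).all()


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 9\ntier: map-level\nridge: 0.001\n")
        cfg = lk.StudyConfig.from_yaml(p)
        assert (cfg.seed, cfg.ridge) == (9, 0.001)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            lk.StudyConfig(tier="magic")
        with pytest.raises(ValueError):
            lk.StudyConfig(alpha=1.5)


class TestCli:
    def test_end_to_end_run_command(self, tmp_path):
        from click.testing import CliRunner

        from lapskill.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["run", "--seed", "4", "--out",
                                   str(tmp_path / "rep")])
        assert res.exit_code == 0, res.output
        d = json.loads((tmp_path / "rep" / "report.json").read_text())
        assert lk.validate_report_dict(d) == []

    def test_simulate_then_compare_and_classify(self, tmp_path):
        from click.testing import CliRunner

        from lapskill.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "--seed", "2", "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["compare", str(tmp_path / "map_table.csv")])
        assert res.exit_code == 0, res.output
        assert "Hotelling" in res.output
        res = runner.invoke(main, ["classify", str(tmp_path / "map_table.csv")])
        assert res.exit_code == 0, res.output
        assert "resubstitution" in res.output
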