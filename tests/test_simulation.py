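"""Simulation engine: data-generating mechanism, analytic oracles,
determinism, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from hctsens import (
    ScenarioConfig,
    estimate_rr,
    generate_replicate,
    population_truths,
    run_grid,
    run_scenario,
    scenario_grid,
    summary_table,
)
from hctsens.decision import RULES


class TestScenarioConfig:
    def test_default_arm_sizes(self):
        cfg = ScenarioConfig()
        assert (cfg.n_treated, cfg.n_internal, cfg.n_external) == (200, 100, 500)
        assert cfg.design.alpha == 2.0
        assert cfg.design.eta == 5.0

    def test_outcome_probabilities_poorer_external(self):
        cfg = ScenarioConfig(rr_ay=1.5)
        assert cfg.outcome_prob(0, 0) == pytest.approx(0.2)
        assert cfg.outcome_prob(0, 1) == pytest.approx(0.4)
        assert cfg.outcome_prob(1, 1) == pytest.approx(0.6)

    def test_outcome_probabilities_better_external(self):
        cfg = ScenarioConfig(direction="external_better")
        assert cfg.outcome_prob(0, 1) == pytest.approx(0.1)

    def test_invalid_probability_rejected_at_construction(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            ScenarioConfig(p_y_baseline=0.5, rr_uy=2.0, rr_ay=1.5)

    def test_invalid_confounder_prevalence_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(rr_su=0.5)


class TestGenerateReplicate:
    def test_deterministic_given_config_and_rep(self, small_cfg):
        a = generate_replicate(small_cfg, rep=3)
        b = generate_replicate(small_cfg, rep=3)
        pd.testing.assert_frame_equal(a, b)
        c = generate_replicate(small_cfg, rep=4)
        assert not a.equals(c)

    def test_design_constraints_hold(self, small_cfg):
        df = generate_replicate(small_cfg, rep=0)
        assert len(df) == small_cfg.n_trial + small_cfg.n_external
        assert ((df["s"] == 0) & (df["a"] == 1)).sum() == 0
        assert (df.loc[df["s"] == 1, "a"] == 1).sum() == small_cfg.n_treated

    def test_confounder_prevalence_matches_mechanism(self):
        cfg = ScenarioConfig(rr_su=1.5, n_reps=1, seed=77)
        frames = [
            generate_replicate(cfg, rep=r, keep_confounder=True) for r in range(40)
        ]
        df = pd.concat(frames)
        assert df.loc[df["s"] == 1, "u"].mean() == pytest.approx(0.5, abs=0.01)
        assert df.loc[df["s"] == 0, "u"].mean() == pytest.approx(1 / 3, abs=0.01)


class TestPopulationTruths:
    def test_mild_null_mixture_arithmetic(self):
        t = population_truths(ScenarioConfig(rr_su=1.5))
        assert t.p_internal == pytest.approx(0.30)
        assert t.p_external == pytest.approx(0.26667, abs=1e-5)
        assert t.rd == pytest.approx(1.125)
        assert t.hct_rr == pytest.approx(0.30 / 0.27222, abs=1e-4)

    def test_strong_null_pooled_risk(self):
        t = population_truths(ScenarioConfig(rr_su=3.0))
        assert t.p_pooled_control == pytest.approx(0.24444, abs=1e-5)
        assert t.hct_rr == pytest.approx(1.227, abs=1e-3)

    def test_no_confounding_means_no_bias(self):
        t = population_truths(ScenarioConfig(rr_su=1.0, rr_ay=1.5))
        assert t.rd == pytest.approx(1.0)
        assert t.hct_rr == pytest.approx(t.trial_rr)
        assert t.trial_rr == pytest.approx(1.5)


class TestRunScenario:
    def test_bitwise_reproducible(self, small_cfg):
        a = run_scenario(small_cfg)
        b = run_scenario(small_cfg)
        pd.testing.assert_frame_equal(a.summaries, b.summaries)
        assert a.rejection == b.rejection

    def test_medians_recover_population_truths(self):
        """Monte-Carlo medians of each estimated risk ratio sit near their
        closed-form population values."""
        cfg = ScenarioConfig(rr_su=2.0, rr_ay=1.5, n_reps=1500, seed=31)
        truths = population_truths(cfg)
        med = run_scenario(cfg).summaries["median"]
        assert med["rd"] == pytest.approx(truths.rd, abs=0.03)
        assert med["hct_rr"] == pytest.approx(truths.hct_rr, abs=0.03)
        assert med["trial_rr"] == pytest.approx(truths.trial_rr, abs=0.04)

    def test_scenario_median_matches_subject_level_estimation(self):
        """The count-based scenario path and the subject-table estimation
        path are the same estimator on the same draws."""
        cfg = ScenarioConfig(rr_su=1.5, n_reps=30, seed=3)
        oc = run_scenario(cfg)
        rrs = [
            estimate_rr(generate_replicate(cfg, rep=r), "hct_effect").rr
            for r in range(cfg.n_reps)
        ]
        assert float(np.median(rrs)) == pytest.approx(
            oc.summaries.loc["hct_rr", "median"], rel=1e-12
        )

    def test_no_confounding_keeps_all_rules_near_nominal_level(self):
        cfg = ScenarioConfig(rr_su=1.0, rr_ay=1.0, n_reps=5000, seed=19)
        oc = run_scenario(cfg)
        for rule in ("hct_only", "trial_only"):
            assert oc.rejection[rule]["rate"] == pytest.approx(0.05, abs=0.01)
        # sensitivity rules gate on the pooled test, so they cannot exceed it
        assert oc.rejection["effect_estimate"]["rate"] <= oc.rejection["hct_only"]["rate"]
        assert oc.rejection["statistical_significance"]["rate"] <= 0.06

    def test_better_external_outcomes_push_rd_below_null(self):
        cfg = ScenarioConfig(direction="external_better", n_reps=400, seed=8)
        truths = population_truths(cfg)
        assert truths.rd < 1.0
        oc = run_scenario(cfg)
        assert oc.summaries.loc["rd", "median"] == pytest.approx(truths.rd, abs=0.03)
        # the folding pipeline maps sub-null RD into a benchmark above 1
        assert oc.summaries.loc["rd_value", "median"] > 1.0

    def test_non_estimable_replicates_dropped_and_counted(self):
        cfg = ScenarioConfig(
            n_trial=30, eta=1.0, p_y_baseline=0.05, rr_uy=1.0, rr_su=1.5,
            n_reps=300, seed=55,
        )
        oc = run_scenario(cfg)
        assert oc.n_dropped > 0
        assert oc.n_used + oc.n_dropped == cfg.n_reps
        assert oc.warnings  # > 1% dropped triggers the loud warning


class TestGrid:
    def test_tidy_long_format(self):
        configs = scenario_grid(rr_su=(1.5, 2.0), rr_ay=(1.0,), n_reps=30, seed=2)
        df = run_grid(configs)
        assert set(df["rule"]) == set(RULES)
        assert len(df) == len(configs) * len(RULES)
        assert {"rr_su", "eta", "direction", "rr_ay", "rejection_rate", "mc_se"} <= set(
            df.columns
        )

    def test_summary_table_covers_all_quantities(self):
        cfg = ScenarioConfig(n_reps=30, seed=2)
        tab = summary_table([run_scenario(cfg)])
        assert len(tab) == 6
        assert {"median", "q2.5", "q97.5"} <= set(tab.columns)
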