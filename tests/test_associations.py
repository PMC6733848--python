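import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microgrowth.associations import (
    SeparationError,
    RankDeficientError,
    prune_collinear,
    fit_linear,
    fit_logistic,
    percent_change_from_ratio,
    describe_percent_change,
    run_growth_analysis,
    run_inflammation_analysis,
)
from microgrowth.simulate import CohortConfig, simulate_cohort


class TestPruneCollinear:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.x = rng.normal(size=200)
        self.covs = pd.DataFrame(
            {
                "same": self.x.copy(),
                "negated": -self.x,
                "noise": rng.normal(size=200),
                "category": rng.choice(["a", "b"], 200),
            }
        )

    def test_perfectly_correlated_dropped_noise_kept(self):
        retained, log = prune_collinear(self.x, self.covs)
        assert "same" not in retained
        assert "negated" not in retained  # absolute-value rule
        assert "noise" in retained
        assert "category" in retained
        assert set(log["covariate"]) == {"same", "negated"}


class TestFitLinear:
    def test_exact_linear_relation(self):
        x = np.linspace(-2, 2, 60)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + 1.0})
        res = fit_linear(df, "y", "x")
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p_value < 1e-20

    def test_log_outcome_reports_ratio_scale(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = np.exp(0.5 + np.log(0.8) * x + rng.normal(0, 0.3, 300))
        res = fit_linear(pd.DataFrame({"x": x, "y": y}), "y", "x", log_outcome=True)
        assert res.back_transformed == pytest.approx(0.8, abs=0.05)
        assert res.bt_ci_low < res.back_transformed < res.bt_ci_high

    def test_rank_deficient_design_names_aliased_column(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = rng.normal(size=50)
        df["alias"] = 2 * df["x"]
        with pytest.raises(RankDeficientError, match="alias|x"):
            fit_linear(df, "y", "x", ["alias"])

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            df = pd.DataFrame(
                {"x": rng.normal(size=60), "y": rng.normal(size=60)}
            )
            pvals.append(fit_linear(df, "y", "x").p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_ci_and_p_are_consistent(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            df = pd.DataFrame(
                {
                    "x": rng.normal(size=40),
                    "y": rng.normal(size=40),
                }
            )
            res = fit_linear(df, "y", "x")
            excludes_null = res.ci_low > 0 or res.ci_high < 0
            assert excludes_null == (res.p_value < 0.05)


class TestFitLogistic:
    def test_null_odds_ratio_near_one(self):
        rng = np.random.default_rng(5)
        ors = []
        for _ in range(40):
            df = pd.DataFrame(
                {
                    "x": rng.normal(size=250),
                    "y": rng.integers(0, 2, size=250),
                }
            )
            ors.append(fit_logistic(df, "y", "x").back_transformed)
        assert np.exp(np.mean(np.log(ors))) == pytest.approx(1.0, abs=0.05)

    def test_doubling_scale_halves_log_odds(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": y})
        r1 = fit_logistic(df, "y", "x")
        r2 = fit_logistic(df, "y", "x2")
        assert r1.beta == pytest.approx(2 * r2.beta, rel=1e-6)

    def test_complete_separation_raises(self):
        x = np.linspace(-1, 1, 80)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(int)})
        with pytest.raises(SeparationError):
            fit_logistic(df, "y", "x")


class TestPercentChange:
    @pytest.mark.parametrize(
        "ratio,expected_pct,text",
        [
            (0.88, -12.0, "12% decrease"),
            (0.64, -36.0, "36% decrease"),
            (0.86, -14.0, "14% decrease"),
            (0.68, -32.0, "32% decrease"),
            (1.0, 0.0, "0% change"),
            (1.06, 6.0, "6% increase"),
        ],
    )
    def test_ratio_translations(self, ratio, expected_pct, text):
        assert percent_change_from_ratio(ratio) == pytest.approx(expected_pct)
        assert describe_percent_change(ratio) == text

    def test_round_trip_through_log_scale(self):
        for ratio in (0.88, 0.64, 0.86, 0.68):
            beta_log = np.log(ratio)
            assert percent_change_from_ratio(np.exp(beta_log)) == pytest.approx(
                (ratio - 1) * 100
            )


class TestGrowthAnalysis:
    def test_duplicate_interval_rows_rejected(self, small_cohort):
        v = pd.concat(
            [small_cohort.visits, small_cohort.visits.iloc[[0]]],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="duplicate"):
            run_growth_analysis(v, "maz_true", "waz")

    def test_decision_rule_populates_per_interval_only_when_significant(
        self, small_cohort
    ):
        res = run_growth_analysis(small_cohort.visits, "maz_true", "waz")
        if res.interaction_p < 0.05:
            assert res.per_interval is not None
            assert set(res.per_interval) == {"6-12", "12-18"}
        else:
            assert res.per_interval is None

    def test_adjusted_close_to_unadjusted_with_independent_covariates(self):
        cfg = CohortConfig(n_children=400, n_otus=20, n_age_discriminatory=6, seed=21,
                           dropout_prob_per_visit=0.0)
        cohort = simulate_cohort(cfg)
        plain = run_growth_analysis(cohort.visits, "maz_true", "waz")
        adj = run_growth_analysis(
            cohort.visits, "maz_true", "waz",
            covariates=["maternal_age", "maternal_height", "child_sex_male"],
        )
        assert adj.pooled.beta == pytest.approx(plain.pooled.beta, abs=0.01)

    def test_sensitivity_fit_reported_alongside(self, small_cohort):
        res = run_growth_analysis(small_cohort.visits, "maz_true", "waz")
        assert res.sensitivity_pooled is not None
        # winsorized and raw fits agree in sign and rough magnitude
        assert np.sign(res.sensitivity_pooled.beta) == np.sign(res.pooled.beta)


class TestInflammationAnalysis:
    def test_high_cutoffs_are_strict(self):
        rng = np.random.default_rng(8)
        n = 80
        visits = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(n)] * 2,
                "visit_label": ["6mo"] * n + ["18mo"] * n,
                "x": np.tile(rng.normal(size=n), 2),
                "agp": 1.0,  # exactly at the AGP cutoff: never "high"
                "crp": np.concatenate(
                    [np.full(n // 2, 5.1), np.full(n - n // 2, 4.9)] * 2
                ),
            }
        )
        with pytest.raises(ValueError, match="classes"):
            # all AGP exactly 1.0 -> high_agp has a single class
            run_inflammation_analysis(visits, "x", "18mo", "18mo")

    def test_nonpositive_biomarkers_excluded(self):
        rng = np.random.default_rng(9)
        n = 60
        visits = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(n)],
                "visit_label": ["18mo"] * n,
                "x": rng.normal(size=n),
                "agp": np.concatenate([[0.0], np.exp(rng.normal(0, 0.3, n - 1))]),
                "crp": np.exp(rng.normal(1, 1, n)),
            }
        )
        res = run_inflammation_analysis(visits, "x", "18mo", "18mo")
        assert res["ln_agp"].n_used == n - 1

    def test_planted_shannon_effect_recovered_in_direction(self, small_cohort):
        res = run_inflammation_analysis(
            small_cohort.visits, "shannon_true", "18mo", "18mo"
        )
        assert res["ln_crp"].back_transformed < 1.0
        # the binary outcome is much noisier at this cohort size; its mean
        # behaviour over replicates is covered by the acceptance script
        assert res["high_crp"] is not None
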