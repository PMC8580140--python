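"""Lifespan statistics: robust regressions, ordinal models, Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from harold import cohort, stats


@pytest.fixture(scope="module")
def ages():
    return np.random.default_rng(0).uniform(18, 87, 300)


class TestAgeTerms:
    def test_standardized(self, ages):
        at = stats.age_terms(ages)
        for term in (at.linear, at.quadratic):
            assert abs(term.mean()) < 1e-8
            assert abs(term.std() - 1.0) < 1e-8

    def test_rescaling_age_leaves_results_unchanged(self, ages):
        rng = np.random.default_rng(1)
        y = 0.5 * stats.age_terms(ages).linear + rng.standard_normal(len(ages))
        res_years = stats.age_effect(y, stats.age_terms(ages))
        res_decades = stats.age_effect(y, stats.age_terms(ages / 10.0))
        assert res_years.block_F == pytest.approx(
            res_decades.block_F, abs=1e-6
        )
        pd.testing.assert_frame_equal(
            res_years.coefficients, res_decades.coefficients, atol=1e-6
        )


class TestRobustRegress:
    def test_noiseless_recovery(self, ages):
        at = stats.age_terms(ages)
        y = 2.0 * at.linear
        res = stats.robust_regress(
            y, pd.DataFrame({"age_lin": at.linear, "age_quad": at.quadratic}),
            standardize_y=False,
        )
        assert res.coefficients.loc["age_lin", "beta"] == pytest.approx(
            2.0, abs=1e-8
        )
        assert res.coefficients.loc["age_quad", "beta"] == pytest.approx(
            0.0, abs=1e-8
        )

    def test_hierarchical_gate(self, ages):
        rng = np.random.default_rng(2)
        at = stats.age_terms(ages)
        res_null = stats.age_effect(rng.standard_normal(len(ages)), at)
        assert res_null.posthoc_reported == res_null.block_significant
        res_strong = stats.age_effect(
            at.linear + 0.3 * rng.standard_normal(len(ages)), at
        )
        assert res_strong.block_significant and res_strong.posthoc_reported

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(3)
        wins = 0
        reps = 50
        for _ in range(reps):
            x = rng.uniform(-1, 1, 150)
            y = 1.0 * x + 0.5 * rng.standard_normal(150)
            out = rng.choice(150, 15, replace=False)
            y[out] += rng.choice([-1, 1], 15) * rng.uniform(5, 15, 15)
            X = pd.DataFrame({"x": (x - x.mean()) / x.std()})
            rob = stats.robust_regress(y, X, standardize_y=False)
            b_rob = rob.coefficients.loc["x", "beta"]
            b_ols = np.polyfit((x - x.mean()) / x.std(), y, 1)[0]
            true_b = 1.0 * x.std()
            wins += abs(b_rob - true_b) < abs(b_ols - true_b)
        assert wins / reps >= 0.7

    def test_collinear_design_reports_columns(self, ages):
        at = stats.age_terms(ages)
        X = pd.DataFrame({"a": at.linear, "b": at.linear})
        with pytest.raises(np.linalg.LinAlgError, match="b"):
            stats.robust_regress(np.ones(len(ages)) + at.linear, X)


class TestCompensationModels:
    def test_constant_ipsi_rejected(self, ages):
        at = stats.age_terms(ages)
        with pytest.raises(ValueError):
            stats.compensation_interaction(
                np.random.default_rng(4).standard_normal(len(ages)),
                np.ones(len(ages)), at,
            )

    def test_contra_equal_ipsi_collinear(self, ages):
        at = stats.age_terms(ages)
        rng = np.random.default_rng(5)
        ipsi = rng.standard_normal(len(ages))
        with pytest.raises(np.linalg.LinAlgError):
            stats.partial_compensation(
                rng.standard_normal(len(ages)), ipsi, ipsi.copy()
            )

    def test_independent_inputs_keep_nominal_error_rate(self):
        rng = np.random.default_rng(6)
        fp_int, fp_partial, reps = 0, 0, 200
        for _ in range(reps):
            n = 200
            ages_r = rng.uniform(18, 87, n)
            at = stats.age_terms(ages_r)
            y = rng.standard_normal(n)
            ipsi = rng.standard_normal(n)
            contra = rng.standard_normal(n)
            fp_int += stats.compensation_interaction(y, ipsi, at).block_p < 0.05
            fp_partial += (
                stats.partial_compensation(y, ipsi, contra).block_p < 0.05
            )
        assert abs(fp_int / reps - 0.05) < 0.035
        assert abs(fp_partial / reps - 0.05) < 0.035

    def test_partial_compensation_detects_conditional_benefit(self):
        rng = np.random.default_rng(7)
        hits, reps = 0, 30
        for _ in range(reps):
            n = 586
            ipsi = rng.standard_normal(n)
            contra = rng.standard_normal(n)
            y = -0.25 * ipsi * (contra < 0) + rng.standard_normal(n)
            hits += stats.partial_compensation(y, ipsi, contra).block_p < 0.05
        assert hits / reps >= 0.8


class TestOrdinalBoost:
    def test_compensation_scenario_or_above_one(self):
        rng = np.random.default_rng(8)
        ages_r = rng.uniform(18, 87, 100)
        at = stats.age_terms(ages_r)
        p = 1 / (1 + np.exp(-(at.linear - 0.2)))
        cats = np.where(rng.random(100) < p, "boost", "ambiguous")
        cats[rng.random(100) < 0.05] = "reduction"
        res = stats.ordinal_boost_regress(cats, at)
        assert res.odds_ratios.loc["age_lin", "OR"] > 1.0

    def test_null_or_ci_covers_one(self):
        rng = np.random.default_rng(9)
        covered = 0
        for _ in range(20):
            ages_r = rng.uniform(18, 87, 100)
            at = stats.age_terms(ages_r)
            cats = rng.choice(
                ["reduction", "ambiguous", "boost"], 100, p=[0.2, 0.5, 0.3]
            )
            res = stats.ordinal_boost_regress(cats, at)
            row = res.odds_ratios.loc["age_lin"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 18

    def test_binary_fallback_flagged(self):
        rng = np.random.default_rng(10)
        ages_r = rng.uniform(18, 87, 80)
        cats = rng.choice(["ambiguous", "boost"], 80)
        res = stats.ordinal_boost_regress(cats, stats.age_terms(ages_r))
        assert res.model == "binary-logistic"
        assert res.notes

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            stats.ordinal_boost_regress(
                np.array(["boost"] * 30),
                stats.age_terms(np.linspace(18, 87, 30)),
            )


class TestContinuousBF:
    def test_null_effect_favors_null(self):
        rng = np.random.default_rng(11)
        bfs = []
        for _ in range(40):
            n = 586
            z = rng.standard_normal(n)
            y = 0.3 * z + rng.standard_normal(n)
            Xr = pd.DataFrame({"z": z})
            Xf = pd.DataFrame({"z": z, "e": rng.standard_normal(n)})
            bfs.append(stats.bf_continuous_null(y, Xr, Xf))
        assert np.median(bfs) > 3.0

    def test_strong_effect_favors_alternative(self):
        rng = np.random.default_rng(12)
        n = 586
        z = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = 0.3 * z + 0.4 * e + rng.standard_normal(n)
        bf = stats.bf_continuous_null(
            y, pd.DataFrame({"z": z}), pd.DataFrame({"z": z, "e": e})
        )
        assert bf < 1.0 / 3.0

    def test_perfect_fit_drives_bf_to_zero(self):
        rng = np.random.default_rng(13)
        n = 100
        z = rng.standard_normal(n)
        y = rng.standard_normal(n)
        bf = stats.bf_continuous_null(
            y, pd.DataFrame({"z": z}), pd.DataFrame({"z": z, "y": y})
        )
        assert bf < 1e-6

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="nested"):
            stats.bf_continuous_null(
                rng.standard_normal(50),
                pd.DataFrame({"a": rng.standard_normal(50)}),
                pd.DataFrame({"b": rng.standard_normal(50)}),
            )


class TestDirectionalBF:
    def test_negative_slope_gives_evidence_against_compensation(self):
        rng = np.random.default_rng(15)
        ages_r = rng.uniform(18, 87, 100)
        at = stats.age_terms(ages_r)
        p = 1 / (1 + np.exp(1.0 * at.linear))
        cats = np.where(rng.random(100) < p, "boost", "ambiguous")
        bf, diag = stats.bf_directional_categorical(cats, at, seed=1)
        assert bf > 3.0
        assert diag["converged"]

    def test_positive_slope_gives_small_bf(self):
        rng = np.random.default_rng(16)
        ages_r = rng.uniform(18, 87, 100)
        at = stats.age_terms(ages_r)
        p = 1 / (1 + np.exp(-1.0 * at.linear))
        cats = np.where(rng.random(100) < p, "boost", "ambiguous")
        bf, _ = stats.bf_directional_categorical(cats, at, seed=2)
        assert bf < 1.0

    def test_zero_slope_usually_above_one(self):
        above = 0
        for r in range(10):
            rng = np.random.default_rng(100 + r)
            ages_r = rng.uniform(18, 87, 50)
            cats = np.where(rng.random(50) < 0.5, "boost", "ambiguous")
            bf, _ = stats.bf_directional_categorical(
                cats, stats.age_terms(ages_r), seed=r
            )
            above += bf > 1.0
        assert above > 5


class TestInterpretBF:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (4.0, "substantial"),
            (22.0, "strong"),
            (2.0, "anecdotal"),
            (1.0, "anecdotal (boundary)"),
            (0.4, "favors alternative"),
        ],
    )
    def test_bands(self, bf, label):
        assert stats.interpret_bf(bf) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            stats.interpret_bf(0.0)
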