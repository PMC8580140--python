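"""Synthetic-cohort generator: schedules, BOLD, RTs, determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from harold import cohort, glm, stats


class TestEventSchedules:
    def test_sensorimotor_counts_and_gaps(self):
        sch = cohort.generate_event_schedule("sensorimotor", seed=1)
        assert sch.n_trials == 128  # 120 bimodal + 8 unimodal
        conds = np.asarray(sch.conditions)
        assert np.sum(conds == "bimodal") == 120
        assert np.sum(conds == "unimodal_audio") == 4
        assert np.sum(conds == "unimodal_visual") == 4
        gaps = np.diff(sch.onsets)
        assert gaps.min() >= 2.0
        assert gaps.max() <= 26.0

    def test_free_selection_counts(self):
        sch = cohort.generate_event_schedule("free_selection", seed=1)
        assert sch.n_trials == 240
        types = [c.rsplit("_", 1)[-1] for c in sch.conditions]
        assert types.count("specified") == 120
        assert types.count("choice") == 120
        fingers = sch.fingers()
        for f in cohort.FINGERS:
            n_spec = sum(
                1 for fi, t in zip(fingers, types)
                if fi == f and t == "specified"
            )
            assert n_spec == 30

    @pytest.mark.parametrize("design", ["sensorimotor", "free_selection"])
    def test_constraints_hold_over_many_seeds(self, design):
        # EventSchedule.__post_init__ enforces every schedule invariant
        # (monotone onsets, SOA floor, no runs of four identical types),
        # so constructing without error is the property under test
        n = 1000 if design == "sensorimotor" else 400
        for seed in range(n):
            sch = cohort.generate_event_schedule(design, seed=seed)
            assert sch.onsets[-1] + 2.0 <= sch.run_length * sch.tr

    def test_no_four_identical_condition_types_in_a_row(self):
        for seed in range(50):
            sch = cohort.generate_event_schedule("free_selection", seed=seed)
            types = [c.rsplit("_", 1)[-1] for c in sch.conditions]
            run = 1
            for a, b in zip(types, types[1:]):
                run = run + 1 if a == b else 1
                assert run < 4

    def test_infeasible_packing_raises(self):
        with pytest.raises(cohort.DesignError, match="does not fit"):
            cohort.generate_event_schedule(
                "sensorimotor", seed=0, n_scans=60, n_trials=120
            )


class TestSubjectTruthAndBold:
    def test_truth_reproducible(self, tiny_spec):
        a = cohort.subject_truth(tiny_spec, 3)
        b = cohort.subject_truth(tiny_spec, 3)
        assert a.age == b.age
        np.testing.assert_array_equal(a.contra_pattern, b.contra_pattern)

    def test_bold_bit_identical_for_same_seed(self, tiny_spec, short_schedule):
        truth = cohort.subject_truth(tiny_spec, 0)
        s1 = cohort.simulate_bold(truth, short_schedule, tiny_spec)
        s2 = cohort.simulate_bold(truth, short_schedule, tiny_spec)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_ipsi_amplitude_rises_with_age(self, tiny_spec):
        law = tiny_spec.amplitude_params.ipsi
        assert law(80.0) > law(20.0)
        # contralateral falls
        claw = tiny_spec.amplitude_params.contra
        assert claw(80.0) < claw(20.0)

    def test_noiseless_bold_recovers_amplitudes(self, short_schedule):
        spec = cohort.CohortSpec.preset(
            "haroldnull", n_subjects=2, seed=5, n_voxels=8,
            n_scans=140, n_trials=56,
            noise_params=cohort.NoiseParams(0.0, 0.0, 0.0, 0.0),
            info_params=cohort.InfoParams(
                cohort.AgeLaw(0.0), cohort.AgeLaw(0.0)
            ),
        )
        truth = cohort.subject_truth(spec, 0)
        sess = cohort.simulate_bold(truth, short_schedule, spec)
        dm = glm.build_design_matrix(short_schedule)
        betas, _ = glm.fit_prewhitened_glm(sess.data, dm)
        i = dm.names.index("bimodal")
        np.testing.assert_allclose(
            betas.betas[i, :8], truth.contra_amp, atol=1e-8
        )
        np.testing.assert_allclose(
            betas.betas[i, 8:], truth.ipsi_amp, atol=1e-8
        )

    def test_noise_lag1_autocorrelation_matches_ar_coefficient(self):
        # generator AR(1) phi recovered as the sample lag-1 autocorrelation
        from conftest import ar1_noise

        rng = np.random.default_rng(0)
        x = ar1_noise(rng, 20000, 0.4)[:, 0]
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.4) < 0.05

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ValueError, match=r"AR\(1\)"):
            cohort.NoiseParams(ar_coef=1.2, innovation_sd=1.0)


class TestScenarios:
    def test_dedifferentiation_contra_pattern_declines_with_age(self):
        spec = cohort.CohortSpec.preset("dedifferentiation", n_subjects=2)
        law = spec.info_params.contra_pattern
        assert law(80.0) < law(20.0)
        assert spec.info_params.ipsi_pattern(80.0) == 0.0

    def test_compensation_ipsi_information_grows_with_age(self):
        spec = cohort.CohortSpec.preset("compensation", n_subjects=2)
        law = spec.info_params.ipsi_pattern
        assert law(80.0) > law(20.0) > 0.0
        assert spec.rt_params.coupling > 0.0


class TestRT:
    def test_rt_sd_increases_with_age_in_expectation(self, tiny_spec):
        law = tiny_spec.rt_params.sd
        assert law(85.0) > law(20.0)

    def test_degenerate_spec_shares_one_rt_distribution(self):
        spec = cohort.CohortSpec.preset(
            "haroldnull", n_subjects=4, seed=1,
            rt_params=cohort.RTParams(
                mean=cohort.AgeLaw(300.0), sd=cohort.AgeLaw(50.0),
                subject_sd_mean=0.0, subject_sd_sd=0.0,
            ),
        )
        truths = [cohort.subject_truth(spec, i) for i in range(4)]
        assert len({t.rt_mean for t in truths}) == 1
        assert len({t.rt_sd for t in truths}) == 1

    def test_too_few_trials_rejected(self, tiny_spec):
        truth = cohort.subject_truth(tiny_spec, 0)
        with pytest.raises(ValueError, match="two RT trials"):
            cohort.simulate_rt(truth, tiny_spec, n_trials=1)

    def test_compensation_coupling_gives_negative_partial_correlation(self):
        spec = cohort.CohortSpec.preset(
            "compensation", n_subjects=500, seed=9
        )
        tab = cohort.make_cohort_table(spec)
        at = stats.age_terms(tab["age"].to_numpy())
        X = np.column_stack([np.ones(500), at.linear, at.quadratic])
        ry = tab["rt_sd"] - X @ np.linalg.lstsq(X, tab["rt_sd"], rcond=None)[0]
        ri = (
            tab["ipsi_roi"]
            - X @ np.linalg.lstsq(X, tab["ipsi_roi"], rcond=None)[0]
        )
        assert np.corrcoef(ry, ri)[0, 1] < -0.05


class TestCohortTable:
    def test_deterministic(self, tiny_spec):
        t1 = cohort.make_cohort_table(tiny_spec)
        t2 = cohort.make_cohort_table(tiny_spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_age_laws_recovered_by_regression_on_truth(self):
        # regressing noise-free true amplitudes on age recovers the laws
        spec = cohort.CohortSpec.preset("haroldnull", n_subjects=2000, seed=4)
        tab = cohort.make_cohort_table(spec, measurement_noise=False)
        d = tab["age"] - 50.0
        X = np.column_stack([np.ones(len(tab)), d, d**2])
        coef, *_ = np.linalg.lstsq(X, tab["true_ipsi_amp"], rcond=None)
        law = spec.amplitude_params.ipsi
        assert abs(coef[0] - law.intercept) < 0.02
        assert abs(coef[1] - law.linear) < 0.001
        assert abs(coef[2] - law.quadratic) < 5e-5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cohort.CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            cohort.CohortSpec(age_range=(80.0, 30.0))
        with pytest.raises(ValueError):
            cohort.CohortSpec(scenario="bogus")
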