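"""GLM engine: HRF bases, high-pass, scaling, prewhitening, LSS."""

import numpy as np
import pytest

from harold import cohort, glm
from conftest import ar1_noise


class TestCanonicalHRF:
    def test_vanishes_at_origin(self):
        k = glm.canonical_hrf(0.1)
        assert abs(k[0, 0]) < 1e-12

    def test_positive_integral(self):
        k = glm.canonical_hrf(1.97)
        assert k[0].sum() > 0

    def test_peak_near_five_seconds(self):
        k = glm.canonical_hrf(0.1)[0]
        assert abs(0.1 * np.argmax(k) - 5.0) <= 0.5

    def test_three_kernels_with_derivatives(self):
        k = glm.canonical_hrf(1.97, "canonical+derivs")
        assert k.shape[0] == 3

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            glm.canonical_hrf(1.97, "fir")


class TestCosineHighpass:
    def test_column_count_rule(self):
        cols = glm.cosine_highpass_set(261, 1.97, 128.0)
        expected = int(np.floor(2 * 261 * 1.97 / 128.0)) + 1
        assert cols.shape == (261, expected)

    def test_orthonormal(self):
        cols = glm.cosine_highpass_set(261, 1.97)
        gram = cols.T @ cols
        np.testing.assert_allclose(gram, np.eye(cols.shape[1]), atol=1e-10)

    def test_slow_sinusoid_removed_fast_sinusoid_kept(self):
        n, tr = 261, 1.97
        t = np.arange(n) * tr
        cols = glm.cosine_highpass_set(n, tr, 128.0)
        P = np.eye(n) - cols @ cols.T  # residual-forming projector
        slow = np.sin(2 * np.pi * t / 300.0)  # below 1/128 Hz
        fast = np.sin(2 * np.pi * t / 64.0)  # above the cutoff
        assert np.linalg.norm(P @ slow) < 0.1 * np.linalg.norm(slow)
        assert np.linalg.norm(P @ fast) > 0.9 * np.linalg.norm(fast)

    def test_short_run_gives_empty_set_with_warning(self):
        with pytest.warns(RuntimeWarning, match="cutoff"):
            cols = glm.cosine_highpass_set(30, 2.0, 128.0)
        assert cols.shape[1] == 0


class TestGrandMeanScale:
    def test_constant_data(self):
        out = glm.grand_mean_scale(np.full((10, 4), 50.0))
        np.testing.assert_allclose(out, 100.0)

    def test_grand_mean_exactly_100(self):
        rng = np.random.default_rng(0)
        out = glm.grand_mean_scale(rng.uniform(10, 200, (50, 7)))
        assert abs(out.mean() - 100.0) < 1e-9

    def test_correlations_preserved(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(50, 150, (40, 5))
        out = glm.grand_mean_scale(data)
        np.testing.assert_allclose(
            np.corrcoef(data.T), np.corrcoef(out.T), atol=1e-12
        )

    def test_nonpositive_grand_mean_rejected(self):
        with pytest.raises(ValueError, match="grand mean"):
            glm.grand_mean_scale(np.full((5, 2), -1.0))


class TestPrewhitenedGLM:
    def test_white_noise_gives_near_zero_phi(self, short_design):
        rng = np.random.default_rng(2)
        data = 100 + rng.standard_normal((short_design.n_scans, 70))
        _, noise = glm.fit_prewhitened_glm(data, short_design)
        assert abs(noise.ar_coef) < 0.05

    def test_ar_04_recovered_and_whitened_residuals_white(self, short_design):
        rng = np.random.default_rng(3)
        n = short_design.n_scans
        data = 100 + ar1_noise(rng, n, 0.4, size=70)
        data += np.outer(short_design.matrix[:, 0], np.ones(70)) * 1.5
        betas, noise = glm.fit_prewhitened_glm(data, short_design)
        assert abs(noise.ar_coef - 0.4) < 0.05
        W = noise.whitening_matrix()
        resid = W @ data - (W @ short_design.matrix) @ betas.betas
        lag1 = np.mean(
            [np.corrcoef(resid[:-1, v], resid[1:, v])[0, 1] for v in range(70)]
        )
        assert abs(lag1) < 0.05

    def test_rank_deficient_design_names_columns(self, short_schedule):
        dm = glm.build_design_matrix(short_schedule)
        bad = glm.DesignMatrix(
            matrix=np.column_stack([dm.matrix, dm.matrix[:, 0]]),
            names=dm.names + ["bimodal_copy"],
            task_columns=dm.task_columns,
        )
        with pytest.raises(glm.RankDeficientDesignError) as err:
            bad.check_rank()
        assert "bimodal_copy" in err.value.columns

    def test_betas_unbiased_on_ar1_data(self):
        # mean bias below 2% of the true amplitude across replicates
        sch = cohort.generate_event_schedule(
            "sensorimotor", seed=2, n_scans=120, n_trials=40
        )
        dm = glm.build_design_matrix(sch)
        i = dm.names.index("bimodal")
        amp = 2.0
        rng = np.random.default_rng(11)
        est = []
        for _ in range(200):
            data = 100 + ar1_noise(rng, dm.n_scans, 0.3, size=8)
            data += np.outer(dm.matrix[:, i], np.full(8, amp))
            betas, _ = glm.fit_prewhitened_glm(data, dm)
            est.append(betas.betas[i].mean())
        bias = abs(np.mean(est) - amp) / amp
        assert bias < 0.02

    def test_filtering_then_fitting_equals_joint_fit(self, short_schedule):
        # projecting out the cosine set first, or including it as columns,
        # yields identical task betas (projection equivalence)
        rng = np.random.default_rng(4)
        dm = glm.build_design_matrix(short_schedule)
        n = dm.n_scans
        data = 100 + rng.standard_normal((n, 5))
        dct = glm.cosine_highpass_set(n, short_schedule.tr)
        P = np.eye(n) - dct @ dct.T
        task_cols = [j for j, nm in enumerate(dm.names)
                     if not nm.startswith("cosine")]
        joint, *_ = np.linalg.lstsq(dm.matrix, data, rcond=None)
        filt, *_ = np.linalg.lstsq(P @ dm.matrix[:, task_cols], P @ data,
                                   rcond=None)
        np.testing.assert_allclose(joint[task_cols], filt, atol=1e-8)


class TestLSS:
    def test_one_beta_vector_per_trial(self, short_schedule):
        rng = np.random.default_rng(5)
        data = 100 + rng.standard_normal((short_schedule.run_length, 4))
        betas = glm.lss_betas(data, short_schedule)
        assert betas.betas.shape == (short_schedule.n_trials, 4)

    def test_widely_spaced_noiseless_trials_recover_amplitudes(self):
        # SOA beyond the 32 s kernel support: zero overlap, exact recovery
        sch = cohort.EventSchedule(
            onsets=np.arange(8) * 34.0 + 4.0,
            conditions=["bimodal"] * 8,
            run_length=145,
            tr=2.0,
        )
        kernels = glm.canonical_hrf(2.0)
        amps = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5, 0.8, 1.2])
        sig = np.zeros(145)
        for onset, a in zip(sch.onsets, amps):
            sig += a * glm._convolve_onsets(
                np.array([onset]), 145, 2.0, kernels
            )[:, 0]
        with pytest.warns(RuntimeWarning, match="cutoff"):
            # no high-pass columns: the pure no-overlap identity
            betas = glm.lss_betas((100 + sig)[:, None], sch, cutoff=1e9)
        np.testing.assert_allclose(betas.betas[:, 0], amps, atol=1e-6)

    def test_lss_beats_naive_per_trial_ols_under_overlap(self):
        # SOA ~3 s: trial regressors overlap heavily; a simultaneous
        # one-regressor-per-trial OLS is near-collinear while LSS stays
        # stable, so LSS betas track the generating amplitudes better
        rng = np.random.default_rng(6)
        n_trials, tr = 200, 2.0
        onsets = 4.0 + np.arange(n_trials) * 3.0
        n = int(np.ceil((onsets[-1] + 30) / tr))
        sch = cohort.EventSchedule(
            onsets=onsets, conditions=["bimodal"] * n_trials,
            run_length=n, tr=tr,
        )
        kernels = glm.canonical_hrf(tr)
        cols = np.column_stack(
            [
                glm._convolve_onsets(np.array([o]), n, tr, kernels)[:, 0]
                for o in onsets
            ]
        )
        r_lss, r_naive = [], []
        for _ in range(3):
            amps = 2.0 + rng.standard_normal(n_trials)
            data = 100 + cols @ amps + 2.0 * rng.standard_normal(n)
            lss = glm.lss_betas(data[:, None], sch).betas[:, 0]
            naive, *_ = np.linalg.lstsq(
                np.column_stack([cols, np.ones(n)]), data, rcond=None
            )
            r_lss.append(np.corrcoef(lss, amps)[0, 1])
            r_naive.append(np.corrcoef(naive[:n_trials], amps)[0, 1])
        assert np.mean(r_lss) > np.mean(r_naive)

    def test_single_trial_rejected(self):
        sch = cohort.EventSchedule(
            onsets=np.array([4.0, 30.0]), conditions=["bimodal"] * 2,
            run_length=40, tr=2.0,
        )
        with pytest.raises(ValueError, match="two trials"):
            glm.lss_betas(np.ones((40, 1)) * 100, sch.__class__(
                onsets=np.array([4.0]), conditions=["bimodal"],
                run_length=40, tr=2.0,
            ))
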