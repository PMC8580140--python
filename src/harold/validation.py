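"""End-to-end validation computations for the pipeline.

Each function recomputes one headline quantity from scratch by running the
package on freshly generated synthetic data: analytic threshold
correspondences, decoder oracle agreement, greedy-search adequacy,
null-scenario calibration, compensation-scenario sensitivity,
signal-processing recovery and robust-regression bias.  The same
functions back the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are chosen so the whole battery runs in minutes on one CPU
(reduced voxel/scan counts for cohort-scale decoder runs; the full n=586
cohort for participant-level statistics); see docs/methods.md.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import boost as boost_mod
from . import cohort as coh
from . import glm, mvb, mvpa, stats

__all__ = [
    "threshold_bayes_factor",
    "mvpa_chance_pct",
    "mvb_oracle_max_gap",
    "greedy_adequacy_pct",
    "interaction_null_fpr_pct",
    "null_boost_or_coverage_pct",
    "compensation_boost_or",
    "rt_coupling_power_pct",
    "ar1_recovery",
    "permuted_mvpa_mean_acc_pct",
    "robust_beta_bias_pct",
]


def threshold_bayes_factor() -> float:
    """Bayes factor corresponding to the +/-3 log-evidence criterion."""
    return boost_mod.logdiff_to_bayes_factor(boost_mod.BOOST_THRESHOLD)


def mvpa_chance_pct() -> float:
    """Theoretical balanced four-class chance level (percent)."""
    return 100.0 / len(coh.FINGERS)


def mvb_oracle_max_gap(seed: int, n_instances: int = 10) -> float:
    """Max |fixed-hyperparameter F - closed-form ridge evidence| in nats.

    The oracle is the direct covariance-space Gaussian log density; the
    implementation path goes through the Woodbury weight-space identity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 301]))
    worst = 0.0
    for _ in range(n_instances):
        n, V = 64, 8
        X = rng.standard_normal((n, V))
        t = X @ (rng.standard_normal(V) * 0.4) + rng.standard_normal(n)
        alpha = float(rng.uniform(0.1, 2.0))
        sigma2 = float(rng.uniform(0.5, 2.0))
        f_impl = mvb.log_evidence_fixed(X, t, alpha, sigma2)
        S = sigma2 * np.eye(n) + alpha * (X @ X.T)
        _, logdet = np.linalg.slogdet(S)
        f_oracle = -0.5 * (
            n * np.log(2 * np.pi) + logdet + t @ np.linalg.solve(S, t)
        )
        worst = max(worst, abs(f_impl - f_oracle))
    return worst


def greedy_adequacy_pct(seed: int, n_instances: int = 100) -> float:
    """Percent of instances where greedy F is within 0.5 nats of the best
    exhaustive two-voxel subset (8-voxel, 64-scan problems)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 302]))
    ok = 0
    for _ in range(n_instances):
        n, V = 64, 8
        X = rng.standard_normal((n, V))
        w = np.zeros(V)
        w[rng.choice(V, 2, replace=False)] = rng.standard_normal(2) * 0.8
        t = X @ w + rng.standard_normal(n)
        prob = mvb.MVBProblem(
            target=t, predictors=X, confounds=np.empty((n, 0)),
            contrast=np.array([1.0]),
        )
        f_greedy = mvb.fit_mvb(prob).free_energy
        best = -np.inf
        for pair in itertools.combinations(range(V), 2):
            Xa = X[:, list(pair)]
            f, _, _ = mvb._optimize_subset(
                Xa.T @ Xa, Xa.T @ t, float(t @ t), n,
                np.zeros(2, dtype=np.intp), 1, None, float(t.var()),
            )
            best = max(best, f)
        ok += f_greedy >= best - 0.5
    return 100.0 * ok / n_instances


def interaction_null_fpr_pct(
    seed: int, reps: int = 1500, n_subjects: int = 586
) -> float:
    """False-positive rate (%) of the age x ipsilateral Wald test on
    null-scenario cohorts with no generated coupling."""
    fp = 0
    for r in range(reps):
        spec = coh.CohortSpec.preset(
            "haroldnull", n_subjects=n_subjects, seed=seed * 100003 + r
        )
        tab = coh.make_cohort_table(spec)
        at = stats.age_terms(tab["age"].to_numpy())
        res = stats.compensation_interaction(
            tab["rt_sd"].to_numpy(), tab["ipsi_roi"].to_numpy(), at
        )
        fp += res.block_p < stats.ALPHA
    return 100.0 * fp / reps


def _boost_or(table: pd.DataFrame) -> stats.StatResult:
    inc = table[table["included"]]
    at = stats.age_terms(inc["age"].to_numpy())
    return stats.ordinal_boost_regress(inc["category"].to_numpy(), at)


def null_boost_or_coverage_pct(
    seed: int,
    reps: int = 20,
    n_subjects: int = 30,
    n_voxels: int = 8,
    n_scans: int = 120,
    n_trials: int = 40,
    n_shuffles: int = 4,
) -> float:
    """Percent of null-scenario replicates whose boost-age OR 95% CI
    covers 1 (full BOLD -> GLM -> MVB -> ordinal-regression path)."""
    covered = 0
    for r in range(reps):
        spec = coh.CohortSpec.preset(
            "haroldnull", n_subjects=n_subjects, seed=seed * 499 + r,
            n_voxels=n_voxels, n_scans=n_scans, n_trials=n_trials,
        )
        table, _ = boost_mod.cohort_boost(
            spec, n_shuffles=n_shuffles, seed=seed * 499 + r
        )
        res = _boost_or(table)
        row = res.odds_ratios.loc["age_lin"]
        covered += row["ci_low"] <= 1.0 <= row["ci_high"]
    return 100.0 * covered / reps


def compensation_boost_or(
    seed: int,
    n_subjects: int = 100,
    n_voxels: int = 16,
    n_scans: int = 140,
    n_trials: int = 56,
    n_shuffles: int = 6,
) -> float:
    """Boost-age odds ratio on a compensation-scenario cohort."""
    spec = coh.CohortSpec.preset(
        "compensation", n_subjects=n_subjects, seed=seed,
        n_voxels=n_voxels, n_scans=n_scans, n_trials=n_trials,
    )
    table, _ = boost_mod.cohort_boost(spec, n_shuffles=n_shuffles, seed=seed)
    res = _boost_or(table)
    return float(res.odds_ratios.loc["age_lin", "OR"])


def rt_coupling_power_pct(
    seed: int, reps: int = 100, n_subjects: int = 586
) -> float:
    """Power (%) of the age x ipsilateral interaction test on
    compensation-scenario cohorts at the generator's coupling strength."""
    hits = 0
    for r in range(reps):
        spec = coh.CohortSpec.preset(
            "compensation", n_subjects=n_subjects, seed=seed * 20011 + r
        )
        tab = coh.make_cohort_table(spec)
        at = stats.age_terms(tab["age"].to_numpy())
        res = stats.compensation_interaction(
            tab["rt_sd"].to_numpy(), tab["ipsi_roi"].to_numpy(), at
        )
        hits += res.block_p < stats.ALPHA
    return 100.0 * hits / reps


def ar1_recovery(
    seed: int, phi: float = 0.4, n_voxels: int = 70
) -> tuple[float, float]:
    """(estimated AR coefficient, mean post-whitening residual lag-1)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    sch = coh.generate_event_schedule("sensorimotor", seed=seed)
    dm = glm.build_design_matrix(sch)
    n = dm.n_scans
    e = rng.standard_normal((n, n_voxels))
    noise = np.empty((n, n_voxels))
    noise[0] = e[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        noise[t] = phi * noise[t - 1] + e[t]
    data = 100 + noise + np.outer(dm.matrix[:, 0], np.full(n_voxels, 1.5))
    betas, nm = glm.fit_prewhitened_glm(data, dm)
    W = nm.whitening_matrix()
    resid = W @ data - (W @ dm.matrix) @ betas.betas
    lag1 = float(
        np.mean(
            [
                np.corrcoef(resid[:-1, v], resid[1:, v])[0, 1]
                for v in range(n_voxels)
            ]
        )
    )
    return float(nm.ar_coef), lag1


def permuted_mvpa_mean_acc_pct(seed: int, n_perms: int = 200) -> float:
    """Mean balanced accuracy (%) over label permutations (chance check)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 304]))
    n_per_class, n_vox = 20, 12
    X = rng.standard_normal((4 * n_per_class, n_vox))
    y = np.repeat(coh.FINGERS, n_per_class)
    accs = []
    for p in range(n_perms):
        yp = rng.permutation(y)
        accs.append(
            mvpa.decode_fingers(
                mvpa.TrialPatternSet(betas=X, labels=yp), seed=seed * 7 + p
            )
        )
    return float(np.mean(accs))


def robust_beta_bias_pct(
    seed: int, reps: int = 200, n_subjects: int = 586
) -> float:
    """Mean bias of the robust standardized age slope, % of the true value.

    The truth is the generator's standardized linear age effect on the
    (noise-free) ipsilateral amplitude, computed per replicate from the
    generating law; the estimate is the robust regression slope on the
    noisy ROI means.
    """
    biases = []
    for r in range(reps):
        spec = coh.CohortSpec.preset(
            "haroldnull", n_subjects=n_subjects, seed=seed * 30011 + r
        )
        tab = coh.make_cohort_table(spec)
        at = stats.age_terms(tab["age"].to_numpy())
        y = tab["ipsi_roi"].to_numpy()
        res = stats.robust_regress(
            y,
            pd.DataFrame({"age_lin": at.linear, "age_quad": at.quadratic}),
            standardize_y=False,
        )
        # truth: OLS of the noise-free generating amplitudes on the terms
        X = np.column_stack([np.ones(len(y)), at.linear, at.quadratic])
        true_beta = np.linalg.lstsq(
            X, tab["true_ipsi_amp"].to_numpy(), rcond=None
        )[0][1]
        biases.append(res.coefficients.loc["age_lin", "beta"] - true_beta)
    # normalize by the typical true slope magnitude
    spec = coh.CohortSpec.preset("haroldnull", n_subjects=n_subjects, seed=seed)
    tab = coh.make_cohort_table(spec)
    at = stats.age_terms(tab["age"].to_numpy())
    X = np.column_stack([np.ones(len(tab)), at.linear, at.quadratic])
    ref = np.linalg.lstsq(X, tab["true_ipsi_amp"].to_numpy(), rcond=None)[0][1]
    return 100.0 * float(abs(np.mean(biases)) / abs(ref))
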