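"""First-level GLM machinery for event-related BOLD time series.

Implements the estimation path used throughout the pipeline: canonical
double-gamma HRF (optionally with temporal and dispersion derivatives),
discrete-cosine high-pass filtering at 1/128 Hz, grand-mean scaling to 100,
AR(1)-plus-white-noise covariance estimation by restricted maximum
likelihood pooled over voxels, prewhitened ordinary least squares, and
least-squares-separate (LSS) single-trial betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nilearn.glm.first_level.hemodynamic_models import (
    spm_dispersion_derivative,
    spm_hrf,
    spm_time_derivative,
)
from numpy.typing import NDArray
from scipy.optimize import minimize_scalar

__all__ = [
    "DesignMatrix",
    "NoiseModel",
    "BetaSet",
    "RankDeficientDesignError",
    "canonical_hrf",
    "cosine_highpass_set",
    "grand_mean_scale",
    "build_design_matrix",
    "fit_prewhitened_glm",
    "lss_betas",
]

#: default high-pass cutoff, seconds (1/128 Hz)
DEFAULT_HIGHPASS_CUTOFF = 128.0

#: oversampling factor used when sampling HRF kernels onto the scan grid
_HRF_OVERSAMPLING = 16


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Raised when a design matrix is (numerically) column-rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(
            "design matrix is rank deficient; collinear or degenerate "
            f"columns: {columns}"
        )


@dataclass
class DesignMatrix:
    """Scans x columns design with named columns.

    ``task_columns`` indexes the columns carrying experimental conditions
    (HRF-convolved regressors), everything else is treated as confound
    (cosine high-pass set, nuisance, constant).
    """

    matrix: NDArray[np.floating]
    names: list[str]
    task_columns: list[int]
    basis: str = "canonical"
    tr: float = 1.97

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D (scans x columns)")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column names do not match design width")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def confound_columns(self) -> list[int]:
        task = set(self.task_columns)
        return [j for j in range(self.matrix.shape[1]) if j not in task]

    def check_rank(self) -> None:
        X = self.matrix
        scale = np.linalg.norm(X, axis=0)
        scale[scale == 0] = 1.0
        r = np.linalg.matrix_rank(X / scale)
        if r < X.shape[1]:
            # identify offending columns by incremental QR
            bad: list[str] = []
            kept = np.empty((X.shape[0], 0))
            for j in range(X.shape[1]):
                cand = np.column_stack([kept, X[:, j] / scale[j]])
                if np.linalg.matrix_rank(cand) == cand.shape[1]:
                    kept = cand
                else:
                    bad.append(self.names[j])
            raise RankDeficientDesignError(bad)


@dataclass
class NoiseModel:
    """AR(1)-plus-white-noise serial-correlation model for one session.

    The error covariance (up to a voxel-specific scale) is
    ``sigma2_white * I + sigma2_ar * K(phi)`` where ``K(phi)`` is the
    unit-variance AR(1) autocorrelation matrix ``phi**|i-j|``.
    ``ar_coef`` is the reported coefficient estimate: the lag-1
    autocorrelation of the fitted covariance, which equals ``phi`` when
    the AR component dominates and goes to 0 for white noise (where the
    raw ``phi`` is unidentified).
    """

    ar_coef: float
    sigma2_white: float
    sigma2_ar: float
    n_scans: int
    phi: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.phi is None:
            self.phi = self.ar_coef

    def covariance(self) -> NDArray[np.floating]:
        K = _ar1_corr(self.n_scans, self.phi)
        return self.sigma2_white * np.eye(self.n_scans) + self.sigma2_ar * K

    def whitening_matrix(self) -> NDArray[np.floating]:
        """Inverse matrix square root of the (normalized) covariance."""
        V = self.covariance()
        V /= np.trace(V) / self.n_scans
        vals, vecs = np.linalg.eigh(V)
        vals = np.clip(vals, 1e-10, None)
        return (vecs / np.sqrt(vals)) @ vecs.T


@dataclass
class BetaSet:
    """Regression coefficients per voxel plus residual variance."""

    betas: NDArray[np.floating]  # columns/trials x voxels
    names: list[str]
    residual_variance: NDArray[np.floating] = field(
        default_factory=lambda: np.empty(0)
    )

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]


def _n_basis(basis: str) -> int:
    if basis == "canonical":
        return 1
    if basis in ("canonical+derivs", "canonical+temporal+dispersion"):
        return 3
    raise ValueError(f"unsupported basis label: {basis!r}")


def _hrf_kernels(
    tr: float, n_basis: int, oversampling: int
) -> list[NDArray[np.floating]]:
    """HRF kernels normalized so the canonical peak equals 1.

    With this convention a condition amplitude reads directly as the peak
    response to an isolated event (percent signal change on data scaled
    to 100).
    """
    funcs = [spm_hrf, spm_time_derivative, spm_dispersion_derivative]
    peak = spm_hrf(tr, oversampling=oversampling).max()
    return [f(tr, oversampling=oversampling) / peak for f in funcs[:n_basis]]


def canonical_hrf(tr: float, basis: str = "canonical") -> NDArray[np.floating]:
    """Return HRF kernel(s) sampled on a TR grid.

    Parameters
    ----------
    tr : repetition time in seconds, > 0.
    basis : ``"canonical"`` for the double-gamma alone, or
        ``"canonical+derivs"`` to add its temporal and dispersion partial
        derivatives (three regressors per condition in the design).

    Returns
    -------
    kernels : (n_basis, n_taps) array; the double-gamma uses the standard
        parameters (response/undershoot delays 6 s/16 s, dispersions 1/1,
        ratio 6, 32 s support), vanishes at t=0 and is scaled to unit
        peak.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    return np.vstack(_hrf_kernels(tr, _n_basis(basis), oversampling=1))


def cosine_highpass_set(
    n_scans: int, tr: float, cutoff: float = DEFAULT_HIGHPASS_CUTOFF
) -> NDArray[np.floating]:
    """Discrete-cosine basis implementing a high-pass filter.

    Returns the orthonormal DCT columns (including the constant) whose
    periods exceed ``cutoff`` seconds; projecting them out of the data
    removes fluctuations slower than 1/cutoff Hz.  The column count follows
    the conventional rule ``floor(2 * run_seconds / cutoff) + 1``.
    """
    run_seconds = n_scans * tr
    if run_seconds <= cutoff:
        import warnings

        warnings.warn(
            "run shorter than high-pass cutoff: empty filter set",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.empty((n_scans, 0))
    n_cols = int(np.floor(2.0 * run_seconds / cutoff)) + 1
    t = np.arange(n_scans)
    cols = np.empty((n_scans, n_cols))
    cols[:, 0] = 1.0 / np.sqrt(n_scans)
    for k in range(1, n_cols):
        cols[:, k] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * k * (2 * t + 1) / (2 * n_scans)
        )
    return cols


def grand_mean_scale(data: NDArray[np.floating]) -> NDArray[np.floating]:
    """Scale a scans x voxels array to a grand mean of exactly 100."""
    data = np.asarray(data, dtype=float)
    gm = data.mean()
    if gm <= 0:
        raise ValueError(
            f"grand mean must be positive, got {gm:.4g}; input looks malformed"
        )
    return data * (100.0 / gm)


def _convolve_onsets(
    onsets: NDArray[np.floating],
    n_scans: int,
    tr: float,
    kernels: NDArray[np.floating],
) -> NDArray[np.floating]:
    """Convolve a delta train with HRF kernel(s) on an oversampled grid."""
    os = _HRF_OVERSAMPLING
    dt = tr / os
    n_fine = n_scans * os
    stick = np.zeros(n_fine)
    idx = np.round(np.asarray(onsets, dtype=float) / dt).astype(int)
    idx = idx[(idx >= 0) & (idx < n_fine)]
    np.add.at(stick, idx, 1.0)
    fine_kernels = _hrf_kernels(tr, kernels.shape[0], oversampling=os)
    out = np.empty((n_scans, kernels.shape[0]))
    for b, k in enumerate(fine_kernels):
        conv = np.convolve(stick, k)[:n_fine]
        out[:, b] = conv[::os]
    return out


def build_design_matrix(
    schedule,
    basis: str = "canonical",
    cutoff: float = DEFAULT_HIGHPASS_CUTOFF,
    nuisance: NDArray[np.floating] | None = None,
    nuisance_names: list[str] | None = None,
) -> DesignMatrix:
    """Assemble a DesignMatrix from an event schedule.

    One HRF-convolved regressor set per condition label (grouped by
    ``schedule.condition_groups()``), followed by optional nuisance columns
    and the cosine high-pass set (which includes the constant).
    """
    n_scans, tr = schedule.run_length, schedule.tr
    kernels = canonical_hrf(tr, basis)
    cols: list[NDArray[np.floating]] = []
    names: list[str] = []
    basis_tags = ["", "_tderiv", "_dderiv"][: kernels.shape[0]]
    for cond, onsets in schedule.condition_groups().items():
        reg = _convolve_onsets(np.asarray(onsets), n_scans, tr, kernels)
        for b, tag in enumerate(basis_tags):
            cols.append(reg[:, b])
            names.append(f"{cond}{tag}")
    task_columns = list(range(len(cols)))
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(
                nuisance_names[j] if nuisance_names else f"nuisance_{j}"
            )
    dct = cosine_highpass_set(n_scans, tr, cutoff)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"cosine_{k:02d}")
    dm = DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        task_columns=task_columns,
        basis=basis,
        tr=tr,
    )
    dm.check_rank()
    return dm


def _ar1_corr(n: int, phi: float) -> NDArray[np.floating]:
    """Unit-variance AR(1) autocorrelation matrix phi**|i-j|."""
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


def _reml_two_component(
    S: NDArray[np.floating],
    X: NDArray[np.floating],
    phi: float,
    tol: float = 1e-6,
    max_iter: int = 64,
) -> tuple[float, float, float]:
    """ReML fit of V = h_w*I + h_a*K(phi) given pooled residual moments.

    ``S`` is the pooled (voxel-averaged, variance-normalized) second-moment
    matrix of the data and ``X`` the design.  The two variance components
    are updated by Fisher scoring on the restricted log-likelihood;
    returns (h_white, h_ar, restricted log-lik up to a constant).
    """
    n = S.shape[0]
    # work in the eigenbasis of K(phi): V is diagonal there
    lam, Q = np.linalg.eigh(_ar1_corr(n, phi))
    lam = np.clip(lam, 1e-12, None)
    Xt = Q.T @ X
    St = Q.T @ S @ Q
    h = np.array([0.5, 0.5]) * np.trace(S) / n
    floor = 1e-10 * np.trace(S) / n
    ll_old = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        d = h[0] + h[1] * lam
        u = 1.0 / d
        Xu = Xt * u[:, None]
        M = Xt.T @ Xu
        try:
            Minv_Xu = np.linalg.solve(M, Xu.T)
        except np.linalg.LinAlgError:
            break
        # P (in eigenbasis) = diag(u) - u u' * (X M^-1 X')
        P = -(Xu @ Minv_Xu)
        P[np.diag_indices(n)] += u
        PS = P @ St
        _, logdet_M = np.linalg.slogdet(M)
        ll = -0.5 * (np.log(d).sum() + logdet_M + np.trace(PS))
        PK = P * lam[None, :]  # P @ Lambda
        tr_P, tr_PK = P.trace(), np.sum(np.diag(P) * lam)
        grad = 0.5 * np.array(
            [
                np.sum(P * PS.T) - tr_P,
                np.sum(PK * PS.T) - tr_PK,
            ]
        )
        PKT = lam[:, None] * P
        fisher = 0.5 * np.array(
            [
                [np.sum(P * P), np.sum(P * PKT)],
                [np.sum(P * PKT), np.sum(PK * PK.T)],
            ]
        )
        try:
            step = np.linalg.solve(fisher + 1e-8 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        while np.any(h + scale * step < floor) and scale > 1e-4:
            scale *= 0.5
        h_new = np.maximum(h + scale * step, floor)
        if abs(ll - ll_old) < tol and np.max(np.abs(h_new - h)) < tol * np.trace(S) / n:
            h = h_new
            break
        h = h_new
        ll_old = ll
    return float(h[0]), float(h[1]), float(ll)


def _restricted_loglik(
    S: NDArray[np.floating], X: NDArray[np.floating], phi: float
) -> tuple[float, float, float]:
    """Profile restricted log-likelihood over the two variances at fixed phi."""
    hw, ha, ll = _reml_two_component(S, X, phi)
    return ll, hw, ha


def fit_prewhitened_glm(
    data: NDArray[np.floating],
    design: DesignMatrix,
    phi_bounds: tuple[float, float] = (-0.9, 0.9),
) -> tuple[BetaSet, NoiseModel]:
    """Estimate betas under an AR(1)+white noise model with prewhitening.

    The serial-correlation model is fitted by restricted maximum likelihood
    pooled over all voxels (a common correlation structure, voxel-specific
    scales absorbed by normalization); the resulting whitening operator is
    applied to both design and data before ordinary least squares.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    X = design.matrix
    if data.shape[0] != X.shape[0]:
        raise ValueError("data and design disagree on scan count")
    design.check_rank()

    # OLS residuals for pooling (variance-normalized per voxel)
    beta_ols, *_ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ beta_ols
    rvar = resid.var(axis=0, ddof=min(X.shape[1], X.shape[0] - 2))
    rvar[rvar <= 0] = 1.0
    Y = data / np.sqrt(rvar)
    S = (Y @ Y.T) / data.shape[1]

    def neg_ll(phi: float) -> float:
        ll, _, _ = _restricted_loglik(S, X, phi)
        return -ll

    res = minimize_scalar(neg_ll, bounds=phi_bounds, method="bounded",
                          options={"xatol": 5e-4})
    phi_hat = float(res.x)
    _, hw, ha = _restricted_loglik(S, X, phi_hat)
    rho1 = ha * phi_hat / (hw + ha) if hw + ha > 0 else 0.0
    noise = NoiseModel(
        ar_coef=float(rho1), sigma2_white=hw, sigma2_ar=ha,
        n_scans=X.shape[0], phi=phi_hat,
    )
    W = noise.whitening_matrix()
    Xw, Yw = W @ X, W @ data
    betas, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    residw = Yw - Xw @ betas
    dof = max(X.shape[0] - X.shape[1], 1)
    beta_set = BetaSet(
        betas=betas,
        names=list(design.names),
        residual_variance=(residw**2).sum(axis=0) / dof,
    )
    return beta_set, noise


def lss_betas(
    data: NDArray[np.floating],
    schedule,
    basis: str = "canonical",
    cutoff: float = DEFAULT_HIGHPASS_CUTOFF,
    whitener: NDArray[np.floating] | None = None,
) -> BetaSet:
    """Least-squares-separate single-trial betas.

    One GLM per trial: a regressor for the target trial plus a single
    regressor aggregating every other trial (per basis function), plus the
    cosine high-pass set.  Returns one beta vector (trials x voxels), using
    the canonical-HRF coefficient of the target trial.
    """
    data = np.asarray(data, dtype=float)
    onsets = np.asarray(schedule.onsets, dtype=float)
    if len(onsets) < 2:
        raise ValueError("LSS needs at least two trials")
    n_scans, tr = schedule.run_length, schedule.tr
    kernels = canonical_hrf(tr, basis)
    dct = cosine_highpass_set(n_scans, tr, cutoff)
    if dct.shape[1] == 0:  # keep an intercept even with no filtering
        dct = np.full((n_scans, 1), 1.0 / np.sqrt(n_scans))
    if whitener is not None:
        data = whitener @ data
        dct = whitener @ dct
    betas = np.empty((len(onsets), data.shape[1]))
    for i in range(len(onsets)):
        target = _convolve_onsets(onsets[[i]], n_scans, tr, kernels)
        others = _convolve_onsets(
            np.delete(onsets, i), n_scans, tr, kernels
        )
        if whitener is not None:
            target = whitener @ target
            others = whitener @ others
        X = np.column_stack([target, others, dct])
        scale = np.linalg.norm(X, axis=0)
        scale[scale == 0] = 1.0
        if np.linalg.matrix_rank(X / scale) < X.shape[1]:
            raise RankDeficientDesignError([f"trial_{i}"])
        b, *_ = np.linalg.lstsq(X, data, rcond=None)
        betas[i] = b[0]
    return BetaSet(
        betas=betas, names=[f"trial_{i}" for i in range(len(onsets))]
    )
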