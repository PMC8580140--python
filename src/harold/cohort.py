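"""Seeded synthetic lifespan cohorts with known ground truth.

Emulates the two right-hand finger-response designs the pipeline analyzes:

* a *sensorimotor* detection task (120 bimodal audio/visual trials plus 8
  rare unimodal catch trials, SOAs 2-26 s, TR 1.97 s, 261 scans), and
* a *free-selection* task (240 trials over four fingers, half with the
  finger specified, half freely chosen among three cued fingers, blocks of
  20 trials separated by 4.2 s or 6.2 s gaps, 296 scans).

Mean activation follows a HAROLD-patterned lifespan law by construction:
ipsilateral amplitude rises with age and flattens quadratically while
contralateral amplitude falls.  Scenarios differ only in whether the
ipsilateral hemisphere carries *unique* task information:

``haroldnull``
    Ipsilateral voxels re-express the same latent task-plus-physiological
    signal the contralateral hemisphere already measures (redundant
    patterns) -- the univariate HAROLD effect exists but adding ipsilateral
    voxels cannot improve decoding.
``compensation``
    Ipsilateral voxels additionally carry a heterogeneous task-locked
    pattern whose magnitude grows with age (unique, age-increasing
    information), and reaction-time variability is negatively coupled to
    ipsilateral activity, increasingly so at older ages.
``dedifferentiation``
    Like ``haroldnull`` but the contralateral pattern magnitude declines
    with age.

Everything is reproducible bit-for-bit from ``(CohortSpec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import glm

__all__ = [
    "AgeLaw",
    "AmplitudeParams",
    "InfoParams",
    "NoiseParams",
    "RTParams",
    "CohortSpec",
    "EventSchedule",
    "SubjectTruth",
    "BOLDSession",
    "DesignError",
    "generate_event_schedule",
    "subject_truth",
    "simulate_bold",
    "simulate_rt",
    "make_cohort_table",
]

SENSORIMOTOR_SCANS = 261
FREE_SELECTION_SCANS = 296
DEFAULT_TR = 1.97
FINGERS = ("index", "middle", "ring", "little")

#: SOA limits for the sensorimotor design, seconds
SOA_MIN, SOA_MAX = 2.0, 26.0


class DesignError(ValueError):
    """Raised when a requested event schedule cannot fit the run."""


@dataclass(frozen=True)
class AgeLaw:
    """Quadratic lifespan law ``intercept + lin*(age-pivot) + quad*(age-pivot)**2``."""

    intercept: float
    linear: float = 0.0
    quadratic: float = 0.0
    pivot: float = 50.0

    def __call__(self, age: float | NDArray) -> float | NDArray:
        d = np.asarray(age, dtype=float) - self.pivot
        out = self.intercept + self.linear * d + self.quadratic * d * d
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AmplitudeParams:
    """Mean-activation age laws (GLM beta units on data scaled to 100)."""

    contra: AgeLaw = AgeLaw(1.8, -0.012)
    ipsi: AgeLaw = AgeLaw(0.55, 0.011, -0.00012)
    subject_sd_contra: float = 0.25
    subject_sd_ipsi: float = 0.15


@dataclass(frozen=True)
class InfoParams:
    """Pattern-separation magnitudes (voxel-loading SD) and age slopes."""

    contra_pattern: AgeLaw = AgeLaw(0.35)
    ipsi_pattern: AgeLaw = AgeLaw(0.0)
    finger_sep_contra: AgeLaw = AgeLaw(0.30)
    finger_sep_ipsi: AgeLaw = AgeLaw(0.10)


@dataclass(frozen=True)
class NoiseParams:
    """Temporal noise model per voxel plus ROI-shared physiological noise."""

    ar_coef: float = 0.3
    innovation_sd: float = 0.95
    drift_amplitude: float = 1.0
    shared_sd: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.innovation_sd < 0 or self.shared_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def process_sd(self) -> float:
        return self.innovation_sd / np.sqrt(1.0 - self.ar_coef**2)


@dataclass(frozen=True)
class RTParams:
    """Reaction-time laws (ms): participant mean/SD as functions of age."""

    mean: AgeLaw = AgeLaw(320.0, 1.3, 0.012)
    sd: AgeLaw = AgeLaw(65.0, 0.55)
    subject_sd_mean: float = 40.0
    subject_sd_sd: float = 18.0
    #: ms of RT-SD reduction per SD of (age-residual) ipsilateral
    #: amplitude at the cohort mean age; the coupling doubles at +1 SD of
    #: age and vanishes at -1 SD (compensation scenarios only)
    coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.subject_sd_mean < 0 or self.subject_sd_sd < 0:
            raise ValueError("RT subject-level SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_subjects: int = 100
    age_range: tuple[float, float] = (18.0, 87.0)
    seed: int = 0
    design: str = "sensorimotor"
    scenario: str = "haroldnull"
    n_voxels: int = 70
    n_scans: int | None = None
    n_trials: int | None = None
    tr: float = DEFAULT_TR
    amplitude_params: AmplitudeParams = field(default_factory=AmplitudeParams)
    info_params: InfoParams = field(default_factory=InfoParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    rt_params: RTParams = field(default_factory=RTParams)
    rt_trials: int = 50
    roi_noise_sd: float = 0.18

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least two subjects")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        if self.design not in ("sensorimotor", "free_selection"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.scenario not in (
            "haroldnull",
            "compensation",
            "dedifferentiation",
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def scans(self) -> int:
        if self.n_scans is not None:
            return self.n_scans
        return (
            SENSORIMOTOR_SCANS
            if self.design == "sensorimotor"
            else FREE_SELECTION_SCANS
        )

    @property
    def age_mean(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def age_sd(self) -> float:
        return (self.age_range[1] - self.age_range[0]) / np.sqrt(12.0)

    @staticmethod
    def preset(
        scenario: str,
        design: str = "sensorimotor",
        n_subjects: int = 100,
        seed: int = 0,
        **overrides,
    ) -> "CohortSpec":
        """Scenario preset with the matching information/coupling defaults."""
        spec = CohortSpec(
            n_subjects=n_subjects, seed=seed, design=design,
            scenario=scenario, **overrides,
        )
        if scenario == "compensation":
            spec = replace(
                spec,
                info_params=replace(
                    spec.info_params,
                    ipsi_pattern=AgeLaw(0.25, 0.005),
                ),
                # half the (per-SD-of-age) RT-SD age slope:
                # 0.55 ms/yr * age_sd ~ 11 ms/SD, halved
                rt_params=replace(
                    spec.rt_params,
                    coupling=0.5 * spec.rt_params.sd.linear * spec.age_sd,
                ),
            )
        elif scenario == "dedifferentiation":
            spec = replace(
                spec,
                info_params=replace(
                    spec.info_params, contra_pattern=AgeLaw(0.35, -0.003)
                ),
            )
        return spec


@dataclass
class EventSchedule:
    """Trial onsets and condition labels for one run."""

    onsets: NDArray[np.floating]
    conditions: list[str]
    run_length: int  # scans
    tr: float
    design: str = "sensorimotor"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) != len(self.conditions):
            raise ValueError("onsets and conditions disagree in length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.onsets[-1] + 2.0 > self.run_length * self.tr:
            raise ValueError("events do not fit within the run")
        if self.design == "sensorimotor":
            if np.any(np.diff(self.onsets) < SOA_MIN - 1e-9):
                raise ValueError("sensorimotor inter-onset gaps must be >= 2 s")
        if self.design == "free_selection":
            types = [c.rsplit("_", 1)[-1] for c in self.conditions]
            run = 1
            for a, b in zip(types, types[1:]):
                run = run + 1 if a == b else 1
                if run >= 4:
                    raise ValueError(
                        "free-selection schedule has a run of >=4 identical "
                        "condition types"
                    )

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def fingers(self) -> list[str]:
        """Executed finger per trial (free-selection only)."""
        if self.design != "free_selection":
            raise ValueError("fingers are defined for the free-selection design")
        return [c.rsplit("_", 1)[0] for c in self.conditions]

    def condition_groups(self) -> dict[str, NDArray[np.floating]]:
        """Onsets grouped by modelled condition.

        Free-selection trials are pooled by executed finger (specified and
        choice trials combined); sensorimotor trials keep their
        bimodal/unimodal labels.
        """
        groups: dict[str, list[float]] = {}
        if self.design == "free_selection":
            keys = self.fingers()
        else:
            keys = self.conditions
        for onset, key in zip(self.onsets, keys):
            groups.setdefault(key, []).append(onset)
        return {k: np.asarray(v) for k, v in sorted(groups.items())}

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-flavoured events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "duration": np.zeros_like(self.onsets),
                "trial_type": self.conditions,
            }
        )


@dataclass
class SubjectTruth:
    """Ground truth generating one participant's data."""

    index: int
    age: float
    contra_amp: float
    ipsi_amp: float
    contra_dev: float  # standardized age-residual of contralateral amplitude
    ipsi_dev: float  # standardized age-residual of ipsilateral amplitude
    contra_pattern: NDArray[np.floating]  # unique task loadings, contra
    ipsi_pattern: NDArray[np.floating]
    finger_patterns: dict[str, dict[str, NDArray[np.floating]]]
    rt_mean: float
    rt_sd: float
    seed_seq: np.random.SeedSequence


@dataclass
class BOLDSession:
    """One participant's two-ROI voxel time series plus its schedule."""

    data: NDArray[np.floating]  # scans x (2 * n_voxels)
    hemispheres: NDArray[np.str_]  # 'contra' / 'ipsi' per column
    schedule: EventSchedule
    tr: float
    confounds: NDArray[np.floating] | None = None

    def roi(self, hemisphere: str) -> NDArray[np.floating]:
        return self.data[:, self.hemispheres == hemisphere]


# ---------------------------------------------------------------------------
# event schedules
# ---------------------------------------------------------------------------

def _sensorimotor_schedule(
    rng: np.random.Generator, n_scans: int, tr: float, n_trials: int
) -> tuple[NDArray[np.floating], list[str]]:
    n_unimodal = max(2, int(round(8 * n_trials / 120))) if n_trials >= 8 else 0
    n_unimodal -= n_unimodal % 2  # split evenly audio/visual
    n_events = n_trials + n_unimodal
    start, tail = 4.0, 10.0
    run_seconds = n_scans * tr
    budget = run_seconds - start - tail
    if n_events * SOA_MIN > budget:
        raise DesignError(
            f"design does not fit run: {n_events} events need at least "
            f"{n_events * SOA_MIN:.0f} s, run offers {budget:.0f} s"
        )
    # gaps: 2 s floor plus a geometric number of 0.5 s null slots, clipped
    # to the 26 s ceiling; rejection-sample until the run is filled
    mean_extra = budget / n_events - SOA_MIN
    p = 1.0 / (1.0 + max(mean_extra, 0.05) / 0.5)
    for _ in range(500):
        gaps = SOA_MIN + 0.5 * (rng.geometric(p, size=n_events) - 1)
        gaps = np.minimum(gaps, SOA_MAX)
        if gaps.sum() <= budget:
            break
    else:
        # deterministic repair: shrink the longest gaps
        order = np.argsort(gaps)[::-1]
        for i in order:
            if gaps.sum() <= budget:
                break
            gaps[i] = SOA_MIN
        if gaps.sum() > budget:
            raise DesignError("design does not fit run after repair")
    onsets = start + np.cumsum(gaps) - gaps[0]
    conditions = ["bimodal"] * n_events
    if n_unimodal:
        uni_idx = rng.choice(n_events, size=n_unimodal, replace=False)
        half = n_unimodal // 2
        for j, i in enumerate(sorted(uni_idx)):
            conditions[i] = "unimodal_audio" if j < half else "unimodal_visual"
    return onsets, conditions


def _free_selection_types(
    rng: np.random.Generator, n_trials: int
) -> list[str]:
    """Sequence of specified/choice labels with no run of four or more."""
    half = n_trials // 2
    for _ in range(1000):
        remaining = {"specified": half, "choice": half}
        seq: list[str] = []
        dead = False
        for _ in range(n_trials):
            opts = [t for t, c in remaining.items() if c > 0]
            if len(seq) >= 3 and seq[-1] == seq[-2] == seq[-3]:
                opts = [t for t in opts if t != seq[-1]]
            if not opts:
                dead = True
                break
            weights = np.array([remaining[t] for t in opts], dtype=float)
            pick = opts[rng.choice(len(opts), p=weights / weights.sum())]
            seq.append(pick)
            remaining[pick] -= 1
        if not dead:
            return seq
    raise DesignError("could not build a constraint-satisfying type sequence")


def _free_selection_schedule(
    rng: np.random.Generator,
    n_scans: int,
    tr: float,
    n_trials: int,
    repeat_bias: float = 0.0,
) -> tuple[NDArray[np.floating], list[str]]:
    if n_trials % 40 != 0:
        raise DesignError(
            "free-selection trial count must be a multiple of 40 "
            "(blocks of 20, equal finger split of specified trials)"
        )
    n_blocks = n_trials // 20
    soa = 2.0
    start, tail = 4.0, 10.0
    max_len = start + n_trials * soa + (n_blocks - 1) * 6.2 + tail
    if max_len > n_scans * tr:
        raise DesignError(
            f"design does not fit run: needs up to {max_len:.0f} s, run is "
            f"{n_scans * tr:.0f} s"
        )
    types = _free_selection_types(rng, n_trials)
    # fingers for specified trials: equal split, shuffled
    n_spec = n_trials // 2
    spec_fingers = list(np.repeat(FINGERS, n_spec // 4))
    rng.shuffle(spec_fingers)
    conditions: list[str] = []
    prev_finger: str | None = None
    si = 0
    for t in types:
        if t == "specified":
            finger = spec_fingers[si]
            si += 1
        else:
            excluded = FINGERS[rng.integers(4)]
            cued = [f for f in FINGERS if f != excluded]
            w = np.ones(3)
            if repeat_bias and prev_finger in cued:
                w[cued.index(prev_finger)] += repeat_bias
            finger = cued[rng.choice(3, p=w / w.sum())]
        conditions.append(f"{finger}_{t}")
        prev_finger = finger
    onsets = np.empty(n_trials)
    t0 = start
    for i in range(n_trials):
        onsets[i] = t0
        t0 += soa
        if (i + 1) % 20 == 0 and i + 1 < n_trials:
            t0 += float(rng.choice([4.2, 6.2]))
    return onsets, conditions


def generate_event_schedule(
    design: str,
    seed: int,
    n_scans: int | None = None,
    tr: float = DEFAULT_TR,
    n_trials: int | None = None,
    repeat_bias: float = 0.0,
) -> EventSchedule:
    """Generate a seeded event schedule for either experimental design.

    ``n_trials`` defaults to the full designs (120 bimodal trials for the
    sensorimotor task, 240 trials for free selection); reduced counts give
    shorter, structurally identical runs for fast tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1001]))
    if design == "sensorimotor":
        n_scans = SENSORIMOTOR_SCANS if n_scans is None else n_scans
        n_trials = 120 if n_trials is None else n_trials
        onsets, conditions = _sensorimotor_schedule(rng, n_scans, tr, n_trials)
    elif design == "free_selection":
        n_scans = FREE_SELECTION_SCANS if n_scans is None else n_scans
        n_trials = 240 if n_trials is None else n_trials
        onsets, conditions = _free_selection_schedule(
            rng, n_scans, tr, n_trials, repeat_bias
        )
    else:
        raise ValueError(f"unknown design {design!r}")
    return EventSchedule(
        onsets=onsets,
        conditions=conditions,
        run_length=n_scans,
        tr=tr,
        design=design,
    )


# ---------------------------------------------------------------------------
# subject-level truth
# ---------------------------------------------------------------------------

def subject_truth(spec: CohortSpec, index: int) -> SubjectTruth:
    """Deterministic ground truth for one participant."""
    ss = np.random.SeedSequence([int(spec.seed), 7919, int(index)])
    rng = np.random.default_rng(ss)
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi))
    amp = spec.amplitude_params
    c_dev = float(rng.standard_normal())
    i_dev = float(rng.standard_normal())
    contra_amp = float(amp.contra(age)) + amp.subject_sd_contra * c_dev
    ipsi_amp = float(amp.ipsi(age)) + amp.subject_sd_ipsi * i_dev
    info = spec.info_params
    V = spec.n_voxels
    contra_pattern = max(float(info.contra_pattern(age)), 0.0) * (
        rng.standard_normal(V)
    )
    ipsi_pattern = max(float(info.ipsi_pattern(age)), 0.0) * (
        rng.standard_normal(V)
    )
    finger_patterns = {
        "contra": {
            f: max(float(info.finger_sep_contra(age)), 0.0)
            * rng.standard_normal(V)
            for f in FINGERS
        },
        "ipsi": {
            f: max(float(info.finger_sep_ipsi(age)), 0.0)
            * rng.standard_normal(V)
            for f in FINGERS
        },
    }
    rtp = spec.rt_params
    z_age = (age - spec.age_mean) / spec.age_sd
    rt_mean = float(rtp.mean(age)) + rtp.subject_sd_mean * float(
        rng.standard_normal()
    )
    rt_sd = float(rtp.sd(age)) + rtp.subject_sd_sd * float(
        rng.standard_normal()
    )
    if rtp.coupling:
        rt_sd -= rtp.coupling * (1.0 + z_age) * i_dev
    rt_sd = max(rt_sd, 5.0)
    rt_mean = max(rt_mean, 120.0)
    return SubjectTruth(
        index=index,
        age=age,
        contra_amp=contra_amp,
        ipsi_amp=ipsi_amp,
        contra_dev=c_dev,
        ipsi_dev=i_dev,
        contra_pattern=contra_pattern,
        ipsi_pattern=ipsi_pattern,
        finger_patterns=finger_patterns,
        rt_mean=rt_mean,
        rt_sd=rt_sd,
        seed_seq=ss,
    )


def _child_seed(truth: SubjectTruth, key: int) -> np.random.SeedSequence:
    """Deterministic per-purpose child seed (no spawn-counter mutation)."""
    entropy = list(np.atleast_1d(truth.seed_seq.entropy))
    return np.random.SeedSequence([int(e) for e in entropy] + [int(key)])


def _ar1_series(
    rng: np.random.Generator, n: int, phi: float, innovation_sd: float,
    size: int = 1,
) -> NDArray[np.floating]:
    """Stationary AR(1) series, shape (n, size)."""
    e = rng.standard_normal((n, size)) * innovation_sd
    out = np.empty((n, size))
    if abs(phi) < 1:
        out[0] = e[0] / np.sqrt(1.0 - phi**2)
    else:  # pragma: no cover - rejected upstream
        raise ValueError("non-stationary AR parameter")
    for t in range(1, n):
        out[t] = phi * out[t - 1] + e[t]
    return out


def _drift(
    rng: np.random.Generator, n_scans: int, tr: float, amplitude: float
) -> NDArray[np.floating]:
    """Slow drift: random mix of cosines with periods above 128 s."""
    if amplitude == 0:
        return np.zeros(n_scans)
    dct = glm.cosine_highpass_set(n_scans, tr, cutoff=glm.DEFAULT_HIGHPASS_CUTOFF)
    if dct.shape[1] <= 1:
        return np.zeros(n_scans)
    coef = rng.standard_normal(dct.shape[1] - 1)
    d = dct[:, 1:] @ coef
    return amplitude * d / max(d.std(), 1e-12)


def simulate_bold(
    truth: SubjectTruth, schedule: EventSchedule, spec: CohortSpec
) -> BOLDSession:
    """Synthesize one participant's two-ROI BOLD session.

    Both hemispheres load on a shared latent ``u(t) = s(t) + eta(t)`` where
    ``s`` is the HRF-convolved event train and ``eta`` ROI-shared
    physiological noise; unique (scenario-dependent) information enters as
    heterogeneous voxel loadings on the clean ``s(t)``.
    """
    if schedule.design != spec.design:
        raise ValueError("schedule design does not match cohort spec")
    rng = np.random.default_rng(_child_seed(truth, 11))
    n, V = schedule.run_length, spec.n_voxels
    kernels = glm.canonical_hrf(schedule.tr, "canonical")
    groups = schedule.condition_groups()
    regs = {
        cond: glm._convolve_onsets(on, n, schedule.tr, kernels)[:, 0]
        for cond, on in groups.items()
    }
    s_act = sum(regs.values())
    noise = spec.noise_params
    if noise.shared_sd > 0:
        eta = _ar1_series(
            rng, n, noise.ar_coef, noise.shared_sd * np.sqrt(1 - noise.ar_coef**2)
        )[:, 0]
    else:
        eta = np.zeros(n)
    u = s_act + eta

    data = np.empty((n, 2 * V))
    hemis = np.array(["contra"] * V + ["ipsi"] * V)
    for h, (mean_amp, pattern) in enumerate(
        [
            (truth.contra_amp, truth.contra_pattern),
            (truth.ipsi_amp, truth.ipsi_pattern),
        ]
    ):
        hemi = "contra" if h == 0 else "ipsi"
        sl = slice(h * V, (h + 1) * V)
        # redundant component: uniform loading on the shared latent
        sig = mean_amp * u[:, None] @ np.ones((1, V))
        # unique component: heterogeneous loadings on the clean signal
        sig += np.outer(s_act, pattern)
        if spec.design == "free_selection":
            for f in FINGERS:
                if f in regs:
                    sig += np.outer(
                        regs[f], truth.finger_patterns[hemi][f]
                    )
        vox_noise = (
            _ar1_series(rng, n, noise.ar_coef, noise.innovation_sd, size=V)
            if noise.innovation_sd > 0
            else np.zeros((n, V))
        )
        drift = _drift(rng, n, schedule.tr, noise.drift_amplitude)
        data[:, sl] = 100.0 + sig + vox_noise + drift[:, None]
    return BOLDSession(
        data=data, hemispheres=hemis, schedule=schedule, tr=schedule.tr
    )


def simulate_rt(
    truth: SubjectTruth,
    spec: CohortSpec,
    n_trials: int | None = None,
    seed: int | None = None,
) -> NDArray[np.floating]:
    """Trial-level reaction times (ms) for one participant."""
    n_trials = spec.rt_trials if n_trials is None else n_trials
    if n_trials < 2:
        raise ValueError("need at least two RT trials")
    if truth.rt_sd <= 0:
        raise ValueError("generated RT SD must be positive")
    if seed is None:
        rng = np.random.default_rng(_child_seed(truth, 12))
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 13, truth.index])
        )
    rts = truth.rt_mean + truth.rt_sd * rng.standard_normal(n_trials)
    return np.clip(rts, 120.0, None)


def make_cohort_table(
    spec: CohortSpec, measurement_noise: bool = True
) -> pd.DataFrame:
    """Participant-level cohort table without BOLD synthesis.

    ROI means are the true generating amplitudes plus (optional) Gaussian
    estimation noise of SD ``spec.roi_noise_sd``; RT summaries are computed
    from sampled trials.  This is the fast path used for statistical
    calibration; the full path runs the GLM on simulated sessions.
    """
    rows = []
    for i in range(spec.n_subjects):
        truth = subject_truth(spec, i)
        rng = np.random.default_rng(_child_seed(truth, 13))
        c_obs, i_obs = truth.contra_amp, truth.ipsi_amp
        if measurement_noise and spec.roi_noise_sd > 0:
            c_obs += spec.roi_noise_sd * rng.standard_normal()
            i_obs += spec.roi_noise_sd * rng.standard_normal()
        rts = simulate_rt(truth, spec)
        rows.append(
            {
                "participant": i,
                "age": truth.age,
                "contra_roi": c_obs,
                "ipsi_roi": i_obs,
                "true_contra_amp": truth.contra_amp,
                "true_ipsi_amp": truth.ipsi_amp,
                "true_ipsi_dev": truth.ipsi_dev,
                "rt_mean": float(np.mean(rts)),
                "rt_sd": float(np.std(rts, ddof=1)),
                "true_rt_mean": truth.rt_mean,
                "true_rt_sd": truth.rt_sd,
                "scenario": spec.scenario,
            }
        )
    return pd.DataFrame(rows)
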