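"""Four-class finger decoding from single-trial betas (classical MVPA).

A one-vs-one linear SVM ensemble decodes which finger was pressed from
trial-wise activity patterns.  Betas are normalized per voxel to [-1, 1]
across trials before classification; performance is balanced accuracy
(mean of per-class recalls, averaged over four random cross-validation
folds), which handles the class imbalance created by free finger choices.
Because folds come from a single run, serially correlated noise makes
training and test patterns non-independent and can bias absolute accuracy
upward; only *differences* between ROI models (the boost) are interpreted.
Participants whose bilateral accuracy is at or below four-class chance
(25%) are excluded from the boost analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "TrialPatternSet",
    "CHANCE_LEVEL_PCT",
    "normalize_patterns",
    "decode_fingers",
    "accuracy_boost",
    "chance_filter",
]

#: theoretical balanced four-class chance level, percent
CHANCE_LEVEL_PCT = 25.0


@dataclass
class TrialPatternSet:
    """Trials x voxels beta matrix with finger labels and fold assignment."""

    betas: NDArray[np.floating]
    labels: NDArray[np.str_]
    folds: NDArray[np.intp] | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.betas.shape[0] != len(self.labels):
            raise ValueError("labels length must equal trial count")
        if self.folds is not None:
            self.folds = np.asarray(self.folds, dtype=np.intp)
            if len(self.folds) != self.betas.shape[0]:
                raise ValueError("fold assignment length must equal trials")
            counts = np.bincount(self.folds)
            if np.any(counts == 0):
                raise ValueError("every fold must be nonempty")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]


def normalize_patterns(pattern_set: TrialPatternSet) -> TrialPatternSet:
    """Affinely map each voxel's trial values onto [-1, 1].

    Constant voxels carry no trial information and are mapped to 0 (with a
    warning).
    """
    B = pattern_set.betas
    lo = B.min(axis=0)
    hi = B.max(axis=0)
    span = hi - lo
    constant = span <= 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant voxel(s) mapped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    scaled = 2.0 * (B - lo) / safe_span - 1.0
    scaled[:, constant] = 0.0
    return replace(pattern_set, betas=scaled)


def _random_folds(
    n: int, k: int, rng: np.random.Generator
) -> NDArray[np.intp]:
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.intp)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def decode_fingers(
    pattern_set: TrialPatternSet, folds: int = 4, seed: int = 0
) -> float:
    """Balanced decoding accuracy (%) of the four fingers.

    One-vs-one linear SVM (C=1); folds are assigned randomly (seeded).  If
    a random draw leaves a class absent from some training fold, the data
    are refolded with stratification (with a warning).
    """
    labels = pattern_set.labels
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < folds) or len(classes) < 2:
        raise ValueError(
            "need at least as many trials per class as folds "
            f"(counts: {dict(zip(classes, counts))})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 555]))
    if pattern_set.folds is not None:
        assignment = pattern_set.folds
    else:
        assignment = _random_folds(pattern_set.n_trials, folds, rng)
    # degenerate draw: some class missing from a training split
    for f in np.unique(assignment):
        train_labels = labels[assignment != f]
        if len(np.unique(train_labels)) < len(classes):
            warnings.warn(
                "class absent from a training fold; refolding with "
                "stratification",
                RuntimeWarning,
                stacklevel=2,
            )
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            assignment = np.empty(pattern_set.n_trials, dtype=np.intp)
            for ff, (_, test_idx) in enumerate(
                skf.split(pattern_set.betas, labels)
            ):
                assignment[test_idx] = ff
            break
    accs = []
    for f in np.unique(assignment):
        train, test = assignment != f, assignment == f
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(pattern_set.betas[train], labels[train])
        pred = clf.predict(pattern_set.betas[test])
        accs.append(balanced_accuracy_score(labels[test], pred))
    return 100.0 * float(np.mean(accs))


def accuracy_boost(bilateral_acc: float, contralateral_acc: float) -> float:
    """Signed accuracy difference (bilateral - contralateral), percent.

    Positive values mean adding ipsilateral voxels improved finger
    decoding (a boost).
    """
    for a in (bilateral_acc, contralateral_acc):
        if not 0.0 <= a <= 100.0:
            raise ValueError("accuracies must lie in [0, 100]")
    return float(bilateral_acc - contralateral_acc)


def chance_filter(bilateral_acc: float) -> bool:
    """Include a participant iff bilateral accuracy exceeds chance (25%)."""
    if not 0.0 <= bilateral_acc <= 100.0:
        raise ValueError("accuracy must lie in [0, 100]")
    return bilateral_acc > CHANCE_LEVEL_PCT
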