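"""Band-power features and linear-SVM evaluation of movement-type prediction.

Each selected (channel, band) pair yields one feature per trial: the signal is
band-pass filtered with a zero-phase 4th-order Butterworth filter at the
band's edges and the mean squared amplitude over the premovement epoch is the
feature. Prediction is evaluated with a linear (maximum-margin) SVM under
seeded stratified fivefold cross-validation, with feature standardization fit
on training folds only. Session transfer freezes the bands selected on the
first session and re-evaluates them verbatim on later sessions; feature-set
comparison contrasts motor+prefrontal against motor-only features on matched
folds with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import butter, sosfiltfilt
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import EpochSet
from .spectral import FS_ANALYSIS, SelectedBand


@dataclass
class FeatureMatrix:
    """Per-trial mean band-power features (trials x features, linear power).

    Rows align with *kept* trials only; ``feature_meta[j]`` is the
    :class:`~premovement.spectral.SelectedBand` behind column ``j``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_meta: list[SelectedBand]
    session_id: str = "session1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels must align with trials")
        if self.values.shape[1] != len(self.feature_meta):
            raise ValueError("feature_meta must describe every column")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def subset(self, columns: Sequence[int]) -> "FeatureMatrix":
        cols = list(columns)
        return FeatureMatrix(
            values=self.values[:, cols],
            labels=self.labels.copy(),
            feature_meta=[self.feature_meta[j] for j in cols],
            session_id=self.session_id,
        )


@dataclass
class CVResult:
    """Fivefold cross-validation outcome for one session."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    n_trials: int
    fold_assignment: np.ndarray
    chance_level: float
    exceeds_chance: bool
    session_id: str = "session1"


@dataclass
class ComparisonResult:
    """Motor+prefrontal (case 1) vs motor-only (case 2) accuracy comparison."""

    session_ids: list[str]
    case1_accuracies: np.ndarray
    case2_accuracies: np.ndarray
    mean_case1: float
    mean_case2: float
    paired_t_p: float


# ---------------------------------------------------------------------------
# Band-power features
# ---------------------------------------------------------------------------

def bandpass_power(
    x: np.ndarray,
    band: SelectedBand | tuple[float, float],
    fs: float = FS_ANALYSIS,
) -> np.ndarray:
    """Mean power of ``x`` within a frequency band.

    Zero-phase (forward-backward) 4th-order Butterworth band-pass at the band
    edges; edge transients are mitigated by the filter's reflection padding.
    Returns the mean squared filtered amplitude over the last axis; for a
    unit-amplitude in-band sinusoid this approaches A^2/2 = 0.5.
    """
    f_lo, f_hi = (band.f_lo, band.f_hi) if isinstance(band, SelectedBand) else band
    nyq = fs / 2.0
    if not (0.0 < f_lo < f_hi < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < f_lo < f_hi < {nyq:g} Hz, got [{f_lo}, {f_hi}]"
        )
    x = np.asarray(x, dtype=float)
    sos = butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, x, axis=-1)
    return np.mean(y**2, axis=-1)


def build_features(es: EpochSet, bands: Sequence[SelectedBand]) -> FeatureMatrix:
    """One mean band-power feature per selected band, for every kept trial."""
    bands = list(bands)
    if not bands:
        raise ValueError("no selected bands to build features from")
    kept = np.asarray(es.kept_mask, dtype=bool)
    if kept.sum() < 4:
        raise ValueError("need at least 2 kept trials per class")
    cols = []
    for b in bands:
        if b.channel not in es.channel_labels:
            raise KeyError(
                f"selected band references channel {b.channel!r} absent from session "
                f"{es.session_id!r}"
            )
        ch = es.channel_labels.index(b.channel)
        cols.append(bandpass_power(es.epochs[kept, ch, :], b))
    return FeatureMatrix(
        values=np.stack(cols, axis=1),
        labels=es.labels[kept],
        feature_meta=bands,
        session_id=es.session_id,
    )


# ---------------------------------------------------------------------------
# Cross-validated linear SVM
# ---------------------------------------------------------------------------

def binomial_chance_level(n_trials: int, alpha: float = 0.05) -> float:
    """Upper bound of the (1-alpha) binomial interval around 0.5 accuracy.

    Operationalizes the "chance level" an observed accuracy must exceed to be
    considered above chance for a balanced two-class problem at ``n_trials``.
    """
    return float(stats.binom.ppf(1.0 - alpha / 2.0, n_trials, 0.5) / n_trials)


def crossval_svm(fm: FeatureMatrix, k: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of a linear maximum-margin SVM.

    The partition is seeded and stratified by class so every training fold
    contains both classes. Features are standardized with statistics from the
    training folds only (no test leakage); the classifier is a linear SVM
    with fixed regularization C=1.
    """
    labels = np.asarray(fm.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {list(classes)}")
    if counts.min() < k:
        raise ValueError(
            f"need at least {k} trials per class for {k}-fold CV, got {counts.min()}"
        )
    y = (labels == classes[1]).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = np.zeros(k)
    fold_of = np.full(fm.n_trials, -1, dtype=int)
    for f_idx, (tr, te) in enumerate(skf.split(fm.values, y)):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(fm.values[tr], y[tr])
        fold_acc[f_idx] = clf.score(fm.values[te], y[te])
        fold_of[te] = f_idx
    mean_acc = float(fold_acc.mean())
    chance = binomial_chance_level(fm.n_trials)
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=mean_acc,
        n_trials=fm.n_trials,
        fold_assignment=fold_of,
        chance_level=chance,
        exceeds_chance=bool(mean_acc > chance),
        session_id=fm.session_id,
    )


def session_transfer(
    later_sessions: Sequence[EpochSet],
    bands: Sequence[SelectedBand],
    k: int = 5,
    seed: int = 0,
) -> list[CVResult]:
    """Evaluate bands frozen from the first session on later sessions.

    Channels and band edges are reused verbatim; only the classifier is refit
    per session via cross-validation. Each later session gets its own seeded
    fold partition (seed offset by its position for independence).
    """
    results = []
    for offset, es in enumerate(later_sessions):
        fm = build_features(es, bands)
        results.append(crossval_svm(fm, k=k, seed=seed + offset + 1))
    return results


def compare_feature_sets(
    fm_full: Sequence[FeatureMatrix],
    fm_motor: Sequence[FeatureMatrix],
    k: int = 5,
    seed: int = 0,
) -> ComparisonResult:
    """Per-session accuracy comparison of two nested feature sets, matched folds.

    ``fm_full`` (case 1: motor + prefrontal features) and ``fm_motor``
    (case 2: motor-only) must hold the same sessions with identical trials
    and labels; each session pair is evaluated with the same fold seed so the
    partitions match. The two mean accuracies are compared across sessions
    with a two-sided paired t-test; identical per-session accuracies give
    p = 1 by convention (the t statistic is undefined at zero variance).
    """
    fm_full, fm_motor = list(fm_full), list(fm_motor)
    if len(fm_full) != len(fm_motor):
        raise ValueError("the two cases must cover the same sessions")
    if len(fm_full) < 2:
        raise ValueError("paired t-test needs at least 2 sessions")
    acc1, acc2, sessions = [], [], []
    for s_idx, (f1, f2) in enumerate(zip(fm_full, fm_motor)):
        if f1.session_id != f2.session_id or f1.n_trials != f2.n_trials or not np.array_equal(f1.labels, f2.labels):
            raise ValueError("case 1 and case 2 must share trial sets per session")
        s_seed = seed + s_idx
        acc1.append(crossval_svm(f1, k=k, seed=s_seed).mean_accuracy)
        acc2.append(crossval_svm(f2, k=k, seed=s_seed).mean_accuracy)
        sessions.append(f1.session_id)
    acc1, acc2 = np.array(acc1), np.array(acc2)
    diffs = acc1 - acc2
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(acc1, acc2).pvalue)
    return ComparisonResult(
        session_ids=sessions,
        case1_accuracies=acc1,
        case2_accuracies=acc2,
        mean_case1=float(acc1.mean()),
        mean_case2=float(acc2.mean()),
        paired_t_p=p,
    )
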