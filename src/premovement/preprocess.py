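"""Bring raw multichannel recordings to analysis form.

Stages: unify the sampling rate at 200 Hz, drop bad channels, locate movement
onsets from an EMG channel when no event file is provided, cut onset-locked
premovement epochs (-2..0 s), reject artifact-contaminated trials, and compute
the EMG onset/preonset power-ratio quality check that certifies the muscle was
quiescent before onset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter, resample_poly

from .spectral import EPOCH_SAMPLES, FS_ANALYSIS

logger = logging.getLogger(__name__)

#: Sampling rates the acquisition system may deliver (Hz).
SUPPORTED_RATES = (200, 400, 1600)

#: Premovement analysis window relative to movement onset (s), half-open
#: [start, stop): the onset sample itself is excluded so features use
#: strictly pre-onset data.
EPOCH_WINDOW = (-2.0, 0.0)


@dataclass
class Recording:
    """A multichannel signal block (channels x samples, microvolts)."""

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    area_of_channel: dict[str, str] = field(default_factory=dict)
    session_id: str = "session1"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN/inf")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class EventOnsets:
    """Movement onset times (s) with per-trial class labels.

    ``source`` records whether onsets were provided externally or detected
    from the EMG channel; EMG-detected onsets carry no class label.
    """

    onsets: list[tuple[float, str | None]]
    source: str = "provided"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.onsets]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("onset times must be strictly increasing")
        if any(t < 2.0 for t in times):
            warnings.warn(
                "some onsets fall within 2 s of recording start; "
                "their trials will be flagged invalid at epoching",
                stacklevel=2,
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.onsets], dtype=float)

    @property
    def labels(self) -> list[str | None]:
        return [c for _, c in self.onsets]

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class EpochSet:
    """Onset-locked premovement trials: (trials x channels x 400 samples).

    ``kept_mask`` False means the trial is excluded from every downstream
    computation (invalid epoch window or artifact rejection).
    """

    epochs: np.ndarray
    labels: np.ndarray
    kept_mask: np.ndarray
    channel_labels: list[str]
    area_of_channel: dict[str, str] = field(default_factory=dict)
    session_id: str = "session1"
    onset_times: np.ndarray | None = None
    fs: float = FS_ANALYSIS

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials x channels x samples)")
        if self.epochs.shape[-1] != EPOCH_SAMPLES:
            raise ValueError(
                f"epochs must have {EPOCH_SAMPLES} samples (2 s at {FS_ANALYSIS:g} Hz)"
            )
        if not (len(self.labels) == len(self.kept_mask) == self.epochs.shape[0]):
            raise ValueError("labels/kept_mask must align with trials")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def kept_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels[self.kept_mask]:
            key = "unknown" if lab is None else str(lab)
            out[key] = out.get(key, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Sampling-rate unification
# ---------------------------------------------------------------------------

def downsample_to_200(rec: Recording) -> Recording:
    """Downsample a recording to the 200 Hz analysis rate.

    Uses polyphase decimation with a delay-compensated linear-phase FIR
    anti-alias filter cutting at the output Nyquist (100 Hz), which is flat
    through the analysed 1-80 Hz band and introduces no net phase shift.
    A recording already at 200 Hz passes through unchanged.
    """
    fs = int(round(rec.fs))
    if fs not in SUPPORTED_RATES:
        raise ValueError(
            f"unsupported sampling rate {rec.fs:g} Hz; expected one of {SUPPORTED_RATES}"
        )
    if fs == 200:
        return rec
    q = fs // 200
    out = resample_poly(rec.signal, up=1, down=q, axis=1)
    logger.info(
        "downsampled %s from %d Hz to 200 Hz (%d -> %d samples)",
        rec.session_id, fs, rec.n_samples, out.shape[1],
    )
    return replace(rec, signal=out, fs=200.0)


def exclude_channels(rec: Recording, bad: Sequence[str]) -> Recording:
    """Drop named channels (abnormal signals); area map updated consistently."""
    unknown = [b for b in bad if b not in rec.channel_labels]
    if unknown:
        raise KeyError(f"cannot exclude unknown channels: {unknown}")
    if not bad:
        return rec
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in set(bad)]
    labels = [rec.channel_labels[i] for i in keep]
    areas = {lab: a for lab, a in rec.area_of_channel.items() if lab in set(labels)}
    logger.info("excluded %d channels from %s", len(bad), rec.session_id)
    return replace(
        rec,
        signal=rec.signal[keep],
        channel_labels=labels,
        area_of_channel=areas,
    )


# ---------------------------------------------------------------------------
# EMG onset detection
# ---------------------------------------------------------------------------

def detect_emg_onsets(
    emg: np.ndarray,
    fs: float,
    k: float = 4.0,
    smooth_s: float = 0.5,
    sustain_s: float = 0.2,
    refractory_s: float = 5.0,
) -> EventOnsets:
    """Detect movement onsets from a single EMG channel.

    The rectified signal is smoothed with a trailing ``smooth_s`` moving
    average; baseline statistics are robust (median and scaled MAD of the
    envelope, dominated by quiet periods for sparse self-paced movements).
    A burst is a crossing of ``median + k * 1.4826 * MAD`` sustained for at
    least ``sustain_s``; the reported onset is refined by backtracking from
    the crossing to where the envelope first rose above a one-robust-SD
    hysteresis level, undoing the smoothing delay. Successive onsets are
    separated by at least ``refractory_s`` (the protocol's minimum
    inter-movement interval). If crossings exist but no 2-s stretch of the
    envelope stays below threshold, there is no trustworthy quiet baseline
    and an error is raised.
    """
    emg = np.asarray(emg, dtype=float).ravel()
    if emg.size < 10 * fs:
        raise ValueError("EMG signal must be at least 10 s long")
    n_smooth = max(1, int(round(smooth_s * fs)))
    env = lfilter(np.full(n_smooth, 1.0 / n_smooth), [1.0], np.abs(emg))
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    thr = med + k * 1.4826 * mad
    thr_low = med + 1.4826 * mad
    above = env > thr
    n = env.size
    if not above.any():
        logger.info("EMG envelope never crosses threshold; no onsets")
        return EventOnsets(onsets=[], source="emg_detected")
    # with crossings present, require a contiguous quiet baseline (>= 2 s)
    run, best = 0, 0
    for q in ~above:
        run = run + 1 if q else 0
        best = max(best, run)
    if best < 2 * fs:
        raise ValueError("no baseline-quiet segment found in EMG signal")
    n_sustain = max(1, int(round(sustain_s * fs)))
    n_refr = int(round(refractory_s * fs))
    n_back = int(round(1.0 * fs))  # cap the backtracking at 1 s
    onsets: list[tuple[float, str | None]] = []
    i = 0
    while i < n - n_sustain:
        if above[i] and np.all(above[i : i + n_sustain]):
            j = i
            while j > max(0, i - n_back) and env[j - 1] > thr_low:
                j -= 1
            onsets.append((j / fs, None))
            i += n_refr
        else:
            i += 1
    logger.info("detected %d EMG onsets", len(onsets))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return EventOnsets(onsets=onsets, source="emg_detected")


# ---------------------------------------------------------------------------
# Epoching and trial rejection
# ---------------------------------------------------------------------------

def epoch_trials(
    rec: Recording,
    events: EventOnsets,
    window: tuple[float, float] = EPOCH_WINDOW,
) -> EpochSet:
    """Cut onset-locked premovement epochs from a 200 Hz recording.

    The sample convention is half-open ``[t + window[0], t + window[1])``:
    for the default -2..0 s window the epoch holds the 400 samples strictly
    before the onset sample. Onsets without full window coverage are kept in
    the trial list but flagged invalid (``kept_mask`` False) and logged.
    """
    if rec.fs != FS_ANALYSIS:
        raise ValueError(f"epoching requires a {FS_ANALYSIS:g} Hz recording, got {rec.fs:g} Hz")
    n_win = int(round((window[1] - window[0]) * rec.fs))
    if n_win != EPOCH_SAMPLES:
        raise ValueError(f"window must span {EPOCH_SAMPLES} samples, got {n_win}")
    times = events.times
    labels = events.labels
    n_trials = len(times)
    epochs = np.zeros((n_trials, rec.n_channels, EPOCH_SAMPLES))
    kept = np.ones(n_trials, dtype=bool)
    for t_idx, t in enumerate(times):
        start = int(round((t + window[0]) * rec.fs))
        stop = start + EPOCH_SAMPLES
        if start < 0 or stop > rec.n_samples:
            kept[t_idx] = False
            logger.warning(
                "trial %d (onset %.3f s, %s) lacks full epoch coverage; flagged invalid",
                t_idx, t, rec.session_id,
            )
            continue
        epochs[t_idx] = rec.signal[:, start:stop]
    return EpochSet(
        epochs=epochs,
        labels=np.array(labels, dtype=object),
        kept_mask=kept,
        channel_labels=list(rec.channel_labels),
        area_of_channel=dict(rec.area_of_channel),
        session_id=rec.session_id,
        onset_times=times,
    )


def reject_artifact_trials(es: EpochSet, k: float = 8.0) -> EpochSet:
    """Flag artifact-contaminated trials using robust amplitude statistics.

    A trial is rejected when, on any channel, its peak absolute amplitude
    exceeds ``median + k * MAD`` of that channel's per-trial peaks (computed
    over currently kept trials), or when any channel is flat (zero
    peak-to-peak) within the trial. Raises if fewer than two trials per class
    survive, since every downstream stage needs at least two.
    """
    if es.n_trials == 0:
        raise ValueError("no trials to screen")
    peaks = np.max(np.abs(es.epochs), axis=2)  # (T, C)
    ptp = np.ptp(es.epochs, axis=2)
    kept = es.kept_mask.copy()
    if not kept.any():
        raise ValueError("no valid trials before artifact screening")
    med = np.median(peaks[kept], axis=0)
    mad = np.median(np.abs(peaks[kept] - med), axis=0)
    too_big = np.any(peaks > med + k * mad, axis=1)
    flat = np.any(ptp == 0.0, axis=1)
    reject = kept & (too_big | flat)
    new_kept = kept & ~reject
    n_rej = int(reject.sum())
    logger.info(
        "artifact screening %s: rejected %d of %d valid trials (%.1f%%)",
        es.session_id, n_rej, int(kept.sum()),
        100.0 * n_rej / max(1, int(kept.sum())),
    )
    out = replace(es, kept_mask=new_kept)
    counts = out.kept_counts()
    if not counts or min(counts.values()) < 2:
        raise ValueError(
            f"artifact rejection left fewer than 2 trials per class: {counts}"
        )
    return out


# ---------------------------------------------------------------------------
# EMG quality control
# ---------------------------------------------------------------------------

@dataclass
class EmgRatioResult:
    """Per-trial EMG onset/preonset power ratios (dB) and their summary."""

    per_trial_db: np.ndarray
    mean_db: float
    sd_db: float


def emg_power_ratio(pre: np.ndarray, onset: np.ndarray) -> EmgRatioResult:
    """Onset/preonset EMG power ratio per trial, in dB.

    ``ratio = 10 * log10(mean(onset^2) / mean(pre^2))`` per trial; a quiescent
    pre-movement muscle gives large positive ratios. ``pre`` and ``onset`` are
    (trials x samples) arrays for the -2..0 s and 0..1 s windows.
    """
    pre = np.atleast_2d(np.asarray(pre, dtype=float))
    onset = np.atleast_2d(np.asarray(onset, dtype=float))
    if pre.shape[0] != onset.shape[0]:
        raise ValueError("pre/onset trial counts differ")
    p_pre = np.mean(pre**2, axis=1)
    p_on = np.mean(onset**2, axis=1)
    if np.any(p_pre == 0.0):
        raise ValueError("zero pre-window EMG power; ratio undefined")
    ratios = 10.0 * np.log10(p_on / p_pre)
    return EmgRatioResult(
        per_trial_db=ratios,
        mean_db=float(np.mean(ratios)),
        sd_db=float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0,
    )


def emg_onset_preonset_ratio(
    emg: np.ndarray,
    fs: float,
    onset_times: Sequence[float],
    pre_window: tuple[float, float] = EPOCH_WINDOW,
    onset_window: tuple[float, float] = (0.0, 1.0),
) -> EmgRatioResult:
    """Extract per-trial pre/onset EMG windows around each onset and compute ratios."""
    emg = np.asarray(emg, dtype=float).ravel()
    pres, ons = [], []
    for t in onset_times:
        a = int(round((t + pre_window[0]) * fs))
        b = int(round((t + pre_window[1]) * fs))
        c = int(round((t + onset_window[0]) * fs))
        d = int(round((t + onset_window[1]) * fs))
        if a < 0 or d > emg.size:
            logger.warning("onset %.3f s lacks full EMG QC windows; skipped", t)
            continue
        pres.append(emg[a:b])
        ons.append(emg[c:d])
    if not pres:
        raise ValueError("no onset has full pre/onset EMG windows")
    return emg_power_ratio(np.stack(pres), np.stack(ons))
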