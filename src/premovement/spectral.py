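"""Trial power spectra, the electrode/band selection criterion, and its bootstrap null.

The premovement analysis works on 2-s epochs sampled at 200 Hz (400 samples),
giving a 0.5-Hz frequency grid. Each trial's spectrum is a Hamming-windowed
periodogram; class spectra are trial averages of linear power, displayed in dB.
An electrode/band is *selected* when the between-class spectral difference
exceeds ``threshold_db`` (default 3 dB) over a contiguous range of at least
``min_width_hz`` (default 4 Hz) anywhere within 1-80 Hz.

Selection significance is assessed with a bootstrap null: epoch start times are
drawn at random from the same recording (no locking to movement onsets), split
into two pseudo-classes of the original sizes, and the identical criterion is
re-applied; the number of electrodes selected per iteration forms the null
distribution of chance selections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal.windows import hamming

logger = logging.getLogger(__name__)

#: Analysis sampling rate after unification (Hz).
FS_ANALYSIS = 200.0
#: Samples in the premovement window (-2..0 s at 200 Hz).
EPOCH_SAMPLES = 400
#: Frequency resolution of the 2-s window (Hz).
FREQ_RES = FS_ANALYSIS / EPOCH_SAMPLES
#: Analysed frequency range (Hz), inclusive.
FMIN, FMAX = 1.0, 80.0
#: Floor applied to zero linear power before taking dB.
DB_FLOOR = -300.0

#: Canonical EEG/ECoG frequency bands (Hz). Gamma is capped at 70 Hz; higher
#: frequencies are unresolvable at the 200 Hz unified rate.
CANONICAL_BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 70.0),
}


def band_frequencies() -> np.ndarray:
    """The analysed frequency grid: 1.0 to 80.0 Hz in 0.5-Hz steps."""
    k_lo = int(round(FMIN / FREQ_RES))
    k_hi = int(round(FMAX / FREQ_RES))
    return np.arange(k_lo, k_hi + 1) * FREQ_RES


_BAND_SLICE = slice(int(round(FMIN / FREQ_RES)), int(round(FMAX / FREQ_RES)) + 1)


@dataclass
class PowerSpectrum:
    """A (possibly multi-channel) power spectral density in dB.

    ``psd_db`` has shape ``(..., n_freqs)``; the leading axis, when present,
    indexes channels. ``n_trials`` records how many trials were averaged
    (1 for a single-trial spectrum).
    """

    freqs: np.ndarray
    psd_db: np.ndarray
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd_db = np.asarray(self.psd_db, dtype=float)
        if self.psd_db.shape[-1] != self.freqs.shape[0]:
            raise ValueError("psd_db last axis must match freqs")
        if not np.all(np.isfinite(self.psd_db)):
            raise ValueError("psd_db must be finite")

    @property
    def psd_linear(self) -> np.ndarray:
        return 10.0 ** (self.psd_db / 10.0)


@dataclass
class SpectralContrast:
    """Class-wise trial-averaged spectra and their difference, per channel.

    ``diff_db = psd(class_a) - psd(class_b)`` in dB, so positive values mean
    more power for ``class_a``. Swapping class roles negates ``diff_db``.
    """

    freqs: np.ndarray
    psd_a_db: np.ndarray  # (n_channels, n_freqs)
    psd_b_db: np.ndarray
    class_a: str
    class_b: str
    channel_labels: list[str]
    area_of_channel: dict[str, str] = field(default_factory=dict)
    n_trials_a: int = 0
    n_trials_b: int = 0

    @property
    def diff_db(self) -> np.ndarray:
        return self.psd_a_db - self.psd_b_db

    def swapped(self) -> "SpectralContrast":
        return SpectralContrast(
            freqs=self.freqs,
            psd_a_db=self.psd_b_db,
            psd_b_db=self.psd_a_db,
            class_a=self.class_b,
            class_b=self.class_a,
            channel_labels=list(self.channel_labels),
            area_of_channel=dict(self.area_of_channel),
            n_trials_a=self.n_trials_b,
            n_trials_b=self.n_trials_a,
        )


@dataclass(frozen=True)
class SelectedBand:
    """A channel/frequency-range pair passing the selection criterion."""

    channel: str
    area: str
    f_lo: float
    f_hi: float
    peak_diff_db: float
    favored_class: str

    def __post_init__(self) -> None:
        if not (FMIN <= self.f_lo < self.f_hi <= FMAX):
            raise ValueError(
                f"band edges must satisfy {FMIN} <= f_lo < f_hi <= {FMAX}, "
                f"got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width_hz(self) -> float:
        return self.f_hi - self.f_lo


@dataclass
class BootstrapResult:
    """Null distribution of chance electrode selections.

    ``p_value`` uses the add-one rule ``(r + 1) / (n_iterations + 1)`` with
    ``r`` the number of iterations whose null count reaches the observed
    count, so the smallest reportable value at 500 iterations is
    1/501 < 0.002 and p is never exactly zero.
    """

    n_iterations: int
    null_counts: np.ndarray
    observed_count: int
    p_value: float


# ---------------------------------------------------------------------------
# Periodogram
# ---------------------------------------------------------------------------

def periodogram(x: np.ndarray, fs: float = FS_ANALYSIS) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hamming-windowed periodogram over the full frequency grid.

    Parameters
    ----------
    x
        Signal(s), shape ``(..., n_samples)``.
    fs
        Sampling rate in Hz.

    Returns
    -------
    freqs, psd
        ``freqs`` from 0 to Nyquist; ``psd`` in linear power density units
        (amplitude^2 / Hz), normalized by the window energy so that
        ``sum(psd) * df`` equals the window-weighted mean square of the
        signal (Parseval).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    w = hamming(n, sym=False)
    xw = x * w
    spec = np.fft.rfft(xw, axis=-1)
    scale = 1.0 / (fs * np.sum(w**2))
    psd = (np.abs(spec) ** 2) * scale
    # one-sided: double everything except DC (and Nyquist for even n)
    if n % 2 == 0:
        psd[..., 1:-1] *= 2.0
    else:
        psd[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def _to_db(power: np.ndarray) -> np.ndarray:
    """10*log10 with zero-power bins floored at DB_FLOOR (logged)."""
    power = np.asarray(power, dtype=float)
    floor_lin = 10.0 ** (DB_FLOOR / 10.0)
    n_floored = int(np.count_nonzero(power < floor_lin))
    if n_floored:
        logger.info("flooring %d zero/near-zero power bins at %g dB", n_floored, DB_FLOOR)
    return 10.0 * np.log10(np.maximum(power, floor_lin))


def trial_psd_linear(epochs: np.ndarray, fs: float = FS_ANALYSIS) -> tuple[np.ndarray, np.ndarray]:
    """Linear-power periodograms restricted to the 1-80 Hz analysis band.

    ``epochs`` has shape ``(..., 400)``; returns ``(freqs, psd)`` with psd
    shaped ``(..., n_band_freqs)``.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[-1] != EPOCH_SAMPLES:
        raise ValueError(
            f"epochs must have {EPOCH_SAMPLES} samples (2 s at {FS_ANALYSIS:g} Hz), "
            f"got {epochs.shape[-1]}"
        )
    if fs != FS_ANALYSIS:
        raise ValueError(f"trial PSDs are defined at {FS_ANALYSIS:g} Hz, got {fs:g}")
    freqs, psd = periodogram(epochs, fs)
    return freqs[_BAND_SLICE], psd[..., _BAND_SLICE]


def compute_trial_psd(epoch: np.ndarray) -> PowerSpectrum:
    """Single-trial PSD of one epoch (``(n_channels, 400)`` or ``(400,)``), in dB."""
    freqs, psd = trial_psd_linear(epoch)
    return PowerSpectrum(freqs=freqs, psd_db=_to_db(psd), n_trials=1)


def average_psd(
    trial_spectra: Sequence[PowerSpectrum] | np.ndarray,
    kept_mask: np.ndarray | None = None,
) -> PowerSpectrum:
    """Average trial spectra in the *linear power* domain, then convert to dB.

    Averaging dB values would estimate a geometric mean; the arithmetic mean
    of linear power is the standard PSD estimator.

    Parameters
    ----------
    trial_spectra
        Either a sequence of single-trial :class:`PowerSpectrum` or an array
        of linear power with trials on the first axis.
    kept_mask
        Boolean per-trial mask; excluded trials have zero influence.
    """
    if isinstance(trial_spectra, np.ndarray):
        power = np.asarray(trial_spectra, dtype=float)
        freqs = band_frequencies()
        if power.shape[-1] != freqs.shape[0]:
            raise ValueError("power array last axis must match the analysis grid")
    else:
        spectra = list(trial_spectra)
        if not spectra:
            raise ValueError("no trial spectra given")
        freqs = spectra[0].freqs
        for s in spectra[1:]:
            if not np.array_equal(s.freqs, freqs):
                raise ValueError("trial spectra are on different frequency grids")
        power = np.stack([s.psd_linear for s in spectra], axis=0)
    n_total = power.shape[0]
    if kept_mask is None:
        kept_mask = np.ones(n_total, dtype=bool)
    kept_mask = np.asarray(kept_mask, dtype=bool)
    if kept_mask.shape[0] != n_total:
        raise ValueError("kept_mask length must match number of trials")
    n_kept = int(kept_mask.sum())
    if n_kept < 2:
        raise ValueError(f"need at least 2 kept trials to average, got {n_kept}")
    mean_power = power[kept_mask].mean(axis=0)
    return PowerSpectrum(freqs=freqs, psd_db=_to_db(mean_power), n_trials=n_kept)


def compute_contrast(epochset, class_a: str | None = None, class_b: str | None = None) -> SpectralContrast:
    """Class-wise trial-averaged spectra for an :class:`~premovement.preprocess.EpochSet`.

    Class roles default to the sorted order of the labels present, so the
    contrast sign convention is deterministic.
    """
    labels = np.asarray(epochset.labels)
    kept = np.asarray(epochset.kept_mask, dtype=bool)
    present = sorted(set(labels[kept].tolist()))
    if class_a is None or class_b is None:
        if len(present) != 2:
            raise ValueError(f"expected exactly 2 classes among kept trials, got {present}")
        class_a, class_b = present
    freqs, power = trial_psd_linear(epochset.epochs)  # (T, C, F)
    out = {}
    counts = {}
    for cls in (class_a, class_b):
        sel = kept & (labels == cls)
        if sel.sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 kept trials")
        out[cls] = _to_db(power[sel].mean(axis=0))
        counts[cls] = int(sel.sum())
    return SpectralContrast(
        freqs=freqs,
        psd_a_db=out[class_a],
        psd_b_db=out[class_b],
        class_a=class_a,
        class_b=class_b,
        channel_labels=list(epochset.channel_labels),
        area_of_channel=dict(epochset.area_of_channel),
        n_trials_a=counts[class_a],
        n_trials_b=counts[class_b],
    )


# ---------------------------------------------------------------------------
# Selection criterion
# ---------------------------------------------------------------------------

def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def select_bands(
    contrast: SpectralContrast,
    threshold_db: float = 3.0,
    min_width_hz: float = 4.0,
    mode: str = "strict",
    region_db: float | None = None,
) -> list[SelectedBand]:
    """Apply the electrode/band selection criterion to a spectral contrast.

    ``mode="strict"`` (default): a band is a maximal contiguous run of bins
    whose between-class difference exceeds ``threshold_db`` throughout, with
    edge-to-edge width of at least ``min_width_hz`` (on the 0.5-Hz grid a run
    of 9 bins spans 4 Hz and passes).

    ``mode="peak"`` is the looser reading: the run only needs to exceed
    ``region_db`` (default ``threshold_db / 2``) throughout, provided it
    contains at least one bin above ``threshold_db``.

    One :class:`SelectedBand` is emitted per qualifying run per channel per
    contrast sign; channels with no qualifying run emit nothing.
    """
    if mode not in ("strict", "peak"):
        raise ValueError(f"unknown selection mode {mode!r}")
    freqs = np.asarray(contrast.freqs)
    diff = np.atleast_2d(contrast.diff_db)
    if diff.shape[-1] != freqs.shape[0]:
        raise ValueError("contrast frequency grids do not match")
    run_db = threshold_db if mode == "strict" else (
        threshold_db / 2.0 if region_db is None else region_db
    )
    bands: list[SelectedBand] = []
    for ch in range(diff.shape[0]):
        label = contrast.channel_labels[ch] if contrast.channel_labels else str(ch)
        area = contrast.area_of_channel.get(label, "")
        for signed, favored in ((diff[ch], contrast.class_a), (-diff[ch], contrast.class_b)):
            for a, b in _runs_above(signed > run_db):
                if freqs[b] - freqs[a] < min_width_hz:
                    continue
                peak = float(np.max(signed[a : b + 1]))
                if peak <= threshold_db:
                    continue  # only relevant in peak mode
                bands.append(
                    SelectedBand(
                        channel=label,
                        area=area,
                        f_lo=float(freqs[a]),
                        f_hi=float(freqs[b]),
                        peak_diff_db=peak,
                        favored_class=favored,
                    )
                )
    bands.sort(key=lambda b: (b.channel, b.f_lo))
    return bands


def canonical_band_overlap(band: SelectedBand) -> set[str]:
    """Canonical bands (delta..gamma) the selected range intersects with positive measure."""
    out = set()
    for name, (lo, hi) in CANONICAL_BANDS.items():
        if band.f_lo < hi and band.f_hi > lo:
            out.add(name)
    return out


# ---------------------------------------------------------------------------
# Bootstrap null
# ---------------------------------------------------------------------------

def _draw_starts(
    rng: np.random.Generator, n: int, t_max: float, epoch_s: float
) -> np.ndarray:
    """Draw n epoch start times in [0, t_max], non-overlapping when feasible.

    Non-overlapping placement uses the spacing construction: draw n uniform
    points in the shrunk interval, sort, and add i*epoch_s, which is the
    uniform distribution over non-overlapping configurations. When the
    recording is too short, falls back to unconstrained uniform draws with a
    warning.
    """
    slack = t_max - (n - 1) * epoch_s
    if slack >= 0:
        u = np.sort(rng.uniform(0.0, slack, size=n))
        return u + np.arange(n) * epoch_s
    warnings.warn(
        "recording too short for non-overlapping bootstrap epochs; "
        "falling back to overlapping draws",
        stacklevel=2,
    )
    return rng.uniform(0.0, t_max, size=n)


def bootstrap_selection_null(
    rec,
    n_trials_per_class: tuple[int, int],
    observed_count: int,
    n_iter: int = 500,
    seed: int = 0,
    threshold_db: float = 3.0,
    min_width_hz: float = 4.0,
    mode: str = "strict",
    channels: Sequence[str] | None = None,
) -> BootstrapResult:
    """Random-epoch-sampling null for the electrode selection criterion.

    Each iteration draws epoch start times uniformly at random from the
    recording (ignoring movement onsets), splits them into two pseudo-classes
    of the original sizes, re-runs the full average-and-select procedure over
    all channels, and records the number of distinct electrodes selected.

    Parameters
    ----------
    rec
        A :class:`~premovement.preprocess.Recording` at 200 Hz.
    n_trials_per_class
        The observed (class A, class B) trial counts to replicate.
    observed_count
        Number of distinct electrodes selected on the real, onset-locked data.
    seed
        Seeds the draw of start times and the pseudo-class split.
    """
    if rec.fs != FS_ANALYSIS:
        raise ValueError(f"bootstrap requires a {FS_ANALYSIS:g} Hz recording, got {rec.fs:g} Hz")
    n_a, n_b = int(n_trials_per_class[0]), int(n_trials_per_class[1])
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 trials per pseudo-class")
    if channels is None:
        ch_idx = np.arange(len(rec.channel_labels))
        ch_labels = list(rec.channel_labels)
    else:
        ch_idx = np.array([rec.channel_labels.index(c) for c in channels])
        ch_labels = list(channels)
    sig = rec.signal[ch_idx]
    n_samples = sig.shape[1]
    epoch_s = EPOCH_SAMPLES / FS_ANALYSIS
    t_max = n_samples / FS_ANALYSIS - epoch_s
    if t_max <= 0:
        raise ValueError("recording shorter than one epoch")
    n_tot = n_a + n_b
    rng = np.random.default_rng(seed)
    freqs = band_frequencies()
    null_counts = np.zeros(n_iter, dtype=int)
    dummy_contrast = SpectralContrast(
        freqs=freqs,
        psd_a_db=np.zeros((len(ch_labels), freqs.size)),
        psd_b_db=np.zeros((len(ch_labels), freqs.size)),
        class_a="A",
        class_b="B",
        channel_labels=ch_labels,
    )
    for it in range(n_iter):
        starts = _draw_starts(rng, n_tot, t_max, epoch_s)
        i0 = np.minimum(np.round(starts * FS_ANALYSIS).astype(int), n_samples - EPOCH_SAMPLES)
        # (n_tot, C, 400)
        epochs = np.stack([sig[:, i : i + EPOCH_SAMPLES] for i in i0], axis=0)
        _, power = trial_psd_linear(epochs)
        perm = rng.permutation(n_tot)
        mean_a = power[perm[:n_a]].mean(axis=0)
        mean_b = power[perm[n_a:]].mean(axis=0)
        dummy_contrast.psd_a_db = _to_db(mean_a)
        dummy_contrast.psd_b_db = _to_db(mean_b)
        bands = select_bands(dummy_contrast, threshold_db, min_width_hz, mode=mode)
        null_counts[it] = len({b.channel for b in bands})
    r = int(np.count_nonzero(null_counts >= observed_count))
    p_value = (r + 1) / (n_iter + 1)
    return BootstrapResult(
        n_iterations=n_iter,
        null_counts=null_counts,
        observed_count=int(observed_count),
        p_value=float(p_value),
    )
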