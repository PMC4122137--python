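# Methods

This note records the models, estimators, parameters and design choices
behind the `premovement` pipeline, and what the synthetic benchmark does and
does not establish about real recordings.

## Analysis model

The pipeline predicts one of two self-paced movement types from the
premovement window only: the half-open interval [−2 s, 0 s) before movement
(EMG) onset, at a unified 200 Hz sampling rate — 400 samples per trial and
channel. The onset sample itself is excluded so no post-onset information
leaks into the features. All spectral analysis is confined to 1–80 Hz; with
2-s windows the frequency resolution is 0.5 Hz.

### Spectral estimation

Each trial's spectrum is a single Hamming-windowed periodogram (no Welch
segmenting or multitapering): with window $w_n$ and epoch $x_n$,

$$\hat P(f_k) = \frac{2\,|\mathrm{FFT}(x w)_k|^2}{f_s \sum_n w_n^2},$$

one-sided, so that $\sum_k \hat P(f_k)\,\Delta f$ equals the
window-weighted mean square of the signal (Parseval; tested at 10⁻⁶
relative tolerance). Class spectra are **arithmetic means of linear power**
across kept trials, converted to dB afterwards; averaging dB values would
estimate a geometric mean instead and bias the contrast. Zero-power bins
are floored at −300 dB rather than −∞ to keep arithmetic finite; flooring
is logged.

### Selection criterion

A channel/band is selected when the between-class contrast
$|\Delta(f)| > 3$ dB over a contiguous run of bins spanning ≥ 4 Hz. Width
is measured edge-to-edge on the 0.5 Hz grid, so a run of 9 consecutive bins
spans exactly 4 Hz and passes. The criterion wording admits a looser
reading — a > 3 dB peak inside a broader region of pronounced difference —
which is available as `mode="peak"` (region threshold defaulting to half
the peak threshold); the strict reading is the default and is what every
test and the bootstrap use. One `SelectedBand` is emitted per qualifying
run per channel and contrast sign, so a channel can contribute several
bands and either class can be the favored one.

### Bootstrap null

Significance of the selection count is assessed by re-running the identical
average-and-select procedure on epochs whose start times are drawn
uniformly at random from the same session, ignoring onsets. Non-overlapping
placement is used when the recording is long enough (the spacing
construction: uniform draws in the shrunk interval plus fixed offsets,
which is the uniform law over non-overlapping configurations); otherwise
the sampler falls back to unconstrained draws with a warning. Each
iteration splits the drawn epochs at random into two pseudo-classes of the
observed class sizes. The p-value uses the add-one rule
$(r+1)/(B+1)$ so a finite null can never yield $p = 0$; at the default
$B = 500$ the smallest reportable value is $1/501 \approx 0.002$. Null
counting is per-recording (number of distinct electrodes selected in that
iteration), not pooled across recordings.

### Features and classifier

One feature per selected band: the epoch is band-pass filtered with a
zero-phase (forward–backward) 4th-order Butterworth filter at the selected
edges — the effective order is therefore 8 with exactly zero phase
distortion, and the filter's odd-reflection padding limits edge
transients — and the mean squared filtered amplitude over the 400 samples
is the feature, in linear power units.

Classification is a linear SVM (maximum margin, fixed C = 1; no
hyperparameter search) on features standardized with training-fold
statistics only. Cross-validation is stratified fivefold with a seeded
shuffle; stratification guarantees both classes in every training fold for
any session with ≥ 5 trials per class (which also makes a "training fold
missing a class" repair path unreachable — the precondition is enforced
instead). Chance level is operationalized as the upper bound of the 95%
binomial interval around 0.5 at the session's trial count,
$\mathrm{binom.ppf}(0.975, n, 0.5)/n$; a session "exceeds chance" when its
mean fold accuracy is above that bound. Accuracies are reported both as
fractions and as percentages rounded to one decimal.

Session transfer freezes the session-1 bands (channels and edges verbatim)
and refits the classifier per later session. The motor+prefrontal vs
motor-only comparison evaluates both feature sets with identical fold
partitions per session (same seed, same labels) and compares the
per-session accuracy pairs with a two-sided paired t-test; identical
accuracy vectors are reported as p = 1 by convention since the t statistic
is undefined at zero variance.

## Preprocessing choices

- **Downsampling** (400 or 1600 → 200 Hz) uses polyphase decimation
  (`scipy.signal.resample_poly`) with a delay-compensated linear-phase FIR
  anti-alias filter cutting at the output Nyquist (100 Hz). This keeps the
  analysed 1–80 Hz band flat (band power preserved within 2%, tested) and
  introduces no net phase shift, which matters because features are
  computed from short premovement windows.
- **EMG onset detection** (used when no event file is provided): trailing
  0.5-s moving average of the rectified signal; threshold = envelope median
  + 4·1.4826·MAD; a burst must stay above threshold ≥ 200 ms; onsets are
  refined by backtracking from the crossing to a one-robust-SD hysteresis
  level, undoing the smoothing delay; successive onsets ≥ 5 s apart
  (the protocol's minimum inter-movement interval). If crossings exist but
  the envelope never stays below threshold for 2 s, there is no usable
  quiet baseline and detection errors out rather than guessing.
- **Artifact rejection**: a trial is dropped when any channel's peak
  absolute amplitude exceeds the channel's across-trial median + 8·MAD of
  peaks, or when any channel is flat within the trial. Robust statistics
  were chosen because amplitude artifacts are exactly the contaminant that
  ruins mean/SD thresholds. Rejection counts are logged; fewer than two
  surviving trials per class is an error because every downstream stage
  needs at least two.
- **EMG quality control**: per trial,
  $10\log_{10}(\overline{x^2}_{[0,1\,\mathrm{s}]} / \overline{x^2}_{[-2,0\,\mathrm{s}]})$,
  aggregated as mean ± SD. Large positive values certify the muscle was
  quiescent during the premovement window, i.e. the decoded signal is not
  EMG leakage.

## Synthetic data generator

The generator emulates the study structure the pipeline targets:
5-minute-scale sessions of two interleaved movement classes ("hand",
"elbow"), self-paced onsets with inter-movement gaps drawn from a normal
distribution clipped at the 5 s protocol minimum (defaults 8 ± 1.5 s; the
published per-subject behavior table spans ≈ 6.6–13.8 s means and 18–49
movements per session), channels split into prefrontal / premotor+SMA /
sensorimotor thirds, and recording at 200, 400 or 1600 Hz.

- **Background** is Gaussian $1/f^{\alpha}$ noise (α = 1.5 by default, a
  typical ECoG spectral slope), synthesized in the frequency domain with
  the density flattened below 1 Hz, scaled to ≈ 30 µV RMS.
- **Planted effects** add independent band-limited Gaussian noise to the
  favored class's premovement window only, with spectral density
  $(10^{m/10}-1)$ × background inside [f_lo, f_hi]. Because generator and
  estimator share the same PSD convention, the measured trial-averaged
  contrast converges to exactly $m$ dB (calibrated by Monte-Carlo:
  6.00 ± 0.25 dB at 40 trials/class across sampling rates). Effects are
  broadband noise, not sinusoids, because selections are frequency
  *ranges*; the default window coincides with the analysis epoch.
- **EMG channel**: white-noise baseline (10 µV RMS) plus a 1-s burst at
  each onset with cosine-tapered (50 ms ramp) envelope and gain 10,
  giving onset/preonset ratios around 16–20 dB — the order of magnitude a
  compliant subject produces. The fast taper was chosen over a full-width
  raised cosine because real EMG onsets are abrupt; a slow rise would make
  sub-100-ms onset detection physically impossible for any detector.
- An optional amplitude-spike contaminant (`spike_trials`) plants a 50 ms
  high-amplitude transient in a chosen trial's premovement window, used to
  exercise artifact rejection.
- The published per-subject behavior table is available as
  `SUBJECT_PROFILES`; `emulate_table2_session` reproduces its per-session
  movement counts exactly and draws per-class intervals from the printed
  mean ± SD. Because each class's own interval stream nearly fills a
  session, the two class trains are generated independently and merged on
  one timeline with a 2.5 s minimum gap — realized per-class interval means
  stay within two SDs of the printed values.

All randomness flows from one seeded generator; identical configs produce
bit-identical datasets, and every seed used in a pipeline run is recorded
in its report.

**What the benchmark does not show.** The generator has no volume
conduction, no electrode geometry, no epileptiform activity beyond the
optional spike, no non-stationarity within sessions, and its effects are
exactly premovement-locked. Passing tests therefore demonstrate that the
pipeline recovers effects of a known size under its own assumptions — not
that those effect sizes occur in patients. The published headline accuracies
(74.0% overall; 80.3%/70.1%/69.3% by session; 76.0% vs 67% for the
motor+prefrontal vs motor-only cases; 13 selected electrodes) were computed
on undeposited patient recordings and are reproduced here only
directionally: the benchmark reproduces the *protocol* (first-session
selection, frozen-band transfer, area comparison) and the one bound that is
reproducible by construction, the bootstrap p-value floor 1/501 < 0.002.

## Problem sizes used in tests

The test suite and acceptance script run the method at desk scale, chosen
as the smallest sizes at which each property is statistically decisive:
40 channels × 40 trials/class for the bootstrap floor (the full 500
iterations); 50 seeds at 40 trials/class for selection recovery; 100
permutations/seeds for chance calibration, information addition and
session transfer; 50 seeds per magnitude for accuracy monotonicity.
Planted magnitudes are 6 dB where a selection must succeed (twice the
criterion threshold), 3 dB where accuracies must stay away from ceiling so
differences remain visible.

## Known limitations

- The EDF writer is minimal (16-bit, 1-s records, fixed header dates for
  reproducibility); it is validated round-trip against MNE's reader but
  does not implement EDF+ annotations.
- No time-resolved (sliding-window) decoding, no nonlinear kernels, no
  feature-interaction modeling, and no high-gamma (> 80 Hz) analysis — the
  unified 200 Hz rate makes the latter unresolvable by design.
- `detect_emg_onsets` assumes sparse movements (quiet majority of the
  recording); sustained contractions violate its baseline model and raise
  an error instead of returning unreliable onsets.
- With a single recorded session, session transfer and the area comparison
  are skipped (the paired test needs ≥ 2 sessions).
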