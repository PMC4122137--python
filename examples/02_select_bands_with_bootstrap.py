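"""Electrode/band selection and its bootstrap significance check.

Applies the selection criterion -- a between-class PSD difference greater
than 3 dB sustained over at least 4 Hz -- to a session with one planted
effect, then asks how often a 500-iteration random-epoch null (epoch start
times drawn uniformly, split into pseudo-classes of the original sizes)
selects any electrode at all. The add-one p-value has floor 1/501 < 0.002.
"""

from premovement import (
    EventOnsets,
    PlantedEffect,
    SyntheticConfig,
    bootstrap_selection_null,
    canonical_band_overlap,
    compute_contrast,
    downsample_to_200,
    epoch_trials,
    exclude_channels,
    generate_dataset,
    select_bands,
)

config = SyntheticConfig(
    n_channels=12,
    trials_per_session_per_class=40,
    planted_effects=[
        PlantedEffect(channel=9, f_lo=15.0, f_hi=25.0,
                      class_with_higher_power="hand", magnitude_db=6.0)
    ],
    rng_seed=3,
)
dataset = generate_dataset(config)
rec = exclude_channels(downsample_to_200(dataset.recordings[0]), ["EMG"])
epochs = epoch_trials(rec, EventOnsets(onsets=list(dataset.events[0])))

bands = select_bands(compute_contrast(epochs, class_a="hand", class_b="elbow"))
print("selected bands (criterion: >3 dB over >=4 Hz, 1-80 Hz):")
for b in bands:
    waves = "/".join(sorted(canonical_band_overlap(b)))
    print(f"  {b.channel} ({b.area}): {b.f_lo:.1f}-{b.f_hi:.1f} Hz, "
          f"peak {b.peak_diff_db:.1f} dB, favors {b.favored_class} [{waves}]")

observed = len({b.channel for b in bands})
boot = bootstrap_selection_null(rec, (40, 40), observed_count=observed,
                                n_iter=500, seed=3)
print(f"\nbootstrap: {observed} electrode(s) observed; null selected "
      f">= {observed} in {int((boot.null_counts >= observed).sum())}/500 "
      f"iterations -> p = {boot.p_value:.4g}")
print("p at the 1/501 floor means no random-epoch split ever produced a "
      "spectral difference passing the criterion.")
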