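"""Generate a synthetic ECoG/EMG session and inspect the planted spectral effect.

Builds one session of two-class self-paced movements (hand grasping vs elbow
flexion) with a 6 dB beta-band (15-25 Hz) power effect planted on a
sensorimotor channel, then measures the between-class PSD contrast with the
pipeline's own estimator. The printed band-mean contrast should sit near the
planted 6 dB; channels without an effect should hover near 0 dB.
"""

import numpy as np

from premovement import (
    EventOnsets,
    PlantedEffect,
    SyntheticConfig,
    compute_contrast,
    downsample_to_200,
    epoch_trials,
    exclude_channels,
    generate_dataset,
)

config = SyntheticConfig(
    n_channels=6,
    fs=200,
    trials_per_session_per_class=40,
    planted_effects=[
        PlantedEffect(channel=4, f_lo=15.0, f_hi=25.0,
                      class_with_higher_power="hand", magnitude_db=6.0)
    ],
    rng_seed=11,
)
dataset = generate_dataset(config)
rec = dataset.recordings[0]
print(f"session: {rec.n_channels} channels (incl. EMG), "
      f"{rec.duration:.0f} s at {rec.fs:g} Hz, "
      f"{len(dataset.events[0])} movements")

rec = exclude_channels(downsample_to_200(rec), ["EMG"])
epochs = epoch_trials(rec, EventOnsets(onsets=list(dataset.events[0])))
contrast = compute_contrast(epochs, class_a="hand", class_b="elbow")

band = (contrast.freqs >= 15.0) & (contrast.freqs <= 25.0)
print("\nband-mean PSD contrast (hand - elbow) in 15-25 Hz, per channel:")
for ch, label in enumerate(contrast.channel_labels):
    tag = " <- planted 6 dB effect" if ch == 4 else ""
    print(f"  {label}: {contrast.diff_db[ch][band].mean():+6.2f} dB{tag}")
print("\nA value near +6 dB on ch04 confirms the generator plants effects in "
      "the same units the analysis measures; other channels show only "
      "sampling noise.")
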