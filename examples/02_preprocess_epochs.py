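"""Epoch a continuous recording and apply the two artifact-rejection rules.

A 60 s two-node recording is cut into 2 s epochs; one epoch receives a 150 uV
pulse (amplitude rule: reject if any |sample| > 100 uV) and one is made
theta-dominant (spectral rule: reject if theta/alpha power ratio > 1).
"""

import numpy as np

from srcnet import reject_amplitude, reject_theta_alpha, segment_epochs, select_epochs

fs = 1000.0
rng = np.random.default_rng(0)
t = np.arange(int(60 * fs)) / fs
# alpha-dominant background: 10 Hz oscillation + broadband noise
continuous = 10 * np.cos(2 * np.pi * 10 * t) + rng.normal(0, 2, (2, t.size))

epochs = segment_epochs(continuous, fs, epoch_seconds=2.0)
print(f"segmented: {epochs.n_epochs} epochs of {epochs.n_samples} samples")

epochs.data[5, 0, 300:350] += 150.0            # high-amplitude pulse artifact
epochs.data[9] = 10 * np.cos(2 * np.pi * 6 * t[:2000]) + rng.normal(0, 2, (2, 2000))

kept, amp_mask = reject_amplitude(epochs, limit=100.0)
print(f"amplitude rule removed epochs: {np.where(~amp_mask)[0].tolist()}")
kept, ratio_mask = reject_theta_alpha(kept, threshold=1.0)
removed = np.where(amp_mask)[0][~ratio_mask]
print(f"theta/alpha rule removed epochs: {removed.tolist()}")

final = select_epochs(kept, k=25, seed=7)
print(f"kept {kept.n_epochs} clean epochs; randomly selected {final.n_epochs} "
      "for connectivity analysis (seeded, reproducible)")
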