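"""Generate a phase-coupled signal pair and verify the analytic PLV expectation.

Two cosines share a carrier; their phase difference is Gaussian with standard
deviation sigma, so the expected phase-locking value is exp(-sigma^2/2).
"""

import numpy as np

from srcnet import generate_phase_coupled_pair, instantaneous_phase, plv_pair

for sigma in (0.0, 0.5, 1.0, 2.0):
    x, y = generate_phase_coupled_pair(fs=256, duration=120, f0=24,
                                       jitter_sigma=sigma, seed=42)
    px, py = instantaneous_phase(x), instantaneous_phase(y)
    plv = plv_pair(px[128:-128], py[128:-128])  # trim Hilbert edges
    print(f"sigma={sigma:3.1f}  empirical PLV={plv:.4f}  "
          f"analytic exp(-sigma^2/2)={np.exp(-sigma**2 / 2):.4f}")

print("\nEmpirical PLV tracks the closed-form wrapped-normal expectation;"
      "\nsigma=0 is perfect locking (PLV=1), large sigma decorrelates the pair.")
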