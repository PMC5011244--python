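"""Decompose the noisy two-tone benchmark signal with improved CEEMDAN.

Builds y(t) = cos(4*pi*t) + sin(15*pi*t) on 1024 samples, adds white
noise at exactly 5 dB SNR, decomposes it, and prints each mode's
standard deviation and correlation with the noisy input.  The two tones
should appear as two adjacent modes with correlations far above the
noise modes'.
"""

import numpy as np

from specmode import (BENCHMARK_ENSEMBLE_NOISE, EnsembleConfig,
                      add_noise_snr, correlative_coefficient,
                      improved_ceemdan, simulated_signal)

clean = simulated_signal(1024)
noisy = add_noise_snr(clean, snr_db=5.0, seed=1)

cfg = EnsembleConfig(ensemble_size=100,
                     noise_strength=BENCHMARK_ENSEMBLE_NOISE, seed=1001)
dec = improved_ceemdan(noisy, cfg)

print(f"{dec.n_modes} modes; completeness error "
      f"{np.max(np.abs(dec.reconstruct() - noisy)):.2e}")
print(f"{'mode':>4} {'std':>8} {'corr with input':>16}")
for i, imf in enumerate(dec.imfs, start=1):
    mu = correlative_coefficient(imf, noisy)
    print(f"{i:>4} {np.std(imf):8.4f} {mu:16.4f}")
# Expected: modes 1-3 are noise (corr < 0.4 despite large std); the two
# tones concentrate in two mid-index modes with corr ~0.6-0.8.
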