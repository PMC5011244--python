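"""Shared fixtures.

The benchmark fixture runs the full two-tone denoising study (four
decomposition methods, ten noise seeds, ensemble size 100) once per
session; several acceptance checks and the filter-bank property tests
read from it.  Everything else is generated per test from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from specmode import (BENCHMARK_ENSEMBLE_NOISE, EnsembleConfig, add_noise_snr,
                      decompose, simulated_signal)

BENCH_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def clean_signal() -> np.ndarray:
    return simulated_signal(1024)


@pytest.fixture(scope="session")
def noisy_signals(clean_signal) -> dict[int, np.ndarray]:
    return {s: add_noise_snr(clean_signal, 5.0, s) for s in BENCH_SEEDS}


@pytest.fixture(scope="session")
def benchmark_decomps(noisy_signals):
    """Decompositions of the 5 dB noisy benchmark for every method/seed.

    Study conditions: N = 1024, ensemble size 100, added ensemble noise
    at 5 dB SNR relative to the analyzed signal.
    """
    out: dict[tuple[str, int], object] = {}
    for seed, x in noisy_signals.items():
        cfg = EnsembleConfig(ensemble_size=100,
                             noise_strength=BENCHMARK_ENSEMBLE_NOISE,
                             seed=seed + 1000)
        for method in ("emd", "eemd", "ceemdan", "iceemdan"):
            out[(method, seed)] = decompose(x, method, cfg)
    return out
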