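# specmode

Decomposition-based signal denoising and chemometric calibration for
near-infrared (NIR) spectroscopy: ensemble empirical mode decomposition
with adaptive noise, correlation-threshold selection of sensitive
intrinsic mode functions (IMFs), and concentration calibration by
PSO-optimized support vector regression with a PLS baseline.

It is written for chemometricians and signal-processing practitioners
who need to quantify an analyte (the worked case: glucose, mg/dL) from
noisy transmission spectra, and for anyone who wants a tested,
reproducible Python implementation of the EMD / EEMD / CEEMD / CEEMDAN /
improved-CEEMDAN family with the classical envelope and boundary
conventions.

## The method

A measured signal x(n) is decomposed into IMFs by sifting (cubic-spline
envelope means, classical symmetrized boundaries, Rilling stop
criterion).  The noise-assisted variants perturb the signal with a bank
of white-noise realizations w^i so that the decomposition behaves as a
near-dyadic filter bank; the *improved CEEMDAN* variant estimates each
stage's residue as the ensemble-average local mean

    r_k = ⟨ M( r_{k-1} + β_{k-1} · E_k(w^i) / std(E_k(w^i)) ) ⟩,
    IMF_k = r_{k-1} − r_k,           β_k = ε0 · std(r_k),

with M(z) = z − E_1(z) and E_k(·) the k-th EMD mode, so the modes sum
back to the input exactly.  Sensitive modes are those whose correlation
μ_i with the measured signal exceeds the adaptive threshold

    μ_h = max(μ) / (10 · max(μ) − 3),

after dropping the first three (noise-dominated) modes; the denoised
signal is the sum of kept modes.  Calibration fits ε-SVR with the
kernel K(xi, xj) = exp(−‖xi−xj‖²/(2γ²)), the triple (ε, C, γ) selected
by particle swarm optimization (bounds ε∈[0,0.2], C∈[1,10⁸], γ∈[0.01,2])
with cross-validated RMS prediction error as fitness, and is evaluated
by leave-one-out cross-validation:
R = sqrt(1 − SSres/SStot), RMSEP = sqrt(Σ(ŷ−y)²/(n−1)).

## Worked example

```python
from specmode import RunConfig, run_pipeline

report, selection, dec = run_pipeline(RunConfig(method="iceemdan", seed=1))
print(f"threshold mu_h = {selection.threshold:.5f}")
print(f"kept modes     = {list(selection.kept)} of {dec.n_modes}")
print(f"SNR  = {report.snr_db:6.2f} dB   (input was 5 dB)")
print(f"RMSE = {report.rmse:6.4f}")
print(f"rho  = {report.rho:6.4f}")
```

prints

```
threshold mu_h = 0.16542
kept modes     = [5, 6, 7, 8, 9] of 9
SNR  =  18.31 dB   (input was 5 dB)
RMSE = 0.1269
rho  = 0.9941
```

The pipeline built the two-tone test signal y(t) = cos(4πt) + sin(15πt)
on 1024 samples, added white noise at exactly 5 dB SNR, decomposed it
with improved CEEMDAN (100 noise realizations), and kept the modes whose
correlation with the noisy input exceeds μ_h ≈ 0.165 — the two tones
(modes 6–7, correlations ≈ 0.67/0.76) plus neighbours carrying split
tone energy.  The reconstruction raises the SNR from 5 dB to ≈ 18 dB,
i.e. about 13 dB of noise suppression; ρ is the correlation with the
clean signal.  More narrative scripts live in `examples/` (per-mode
inspection, method comparison, the glucose calibration study).

There is also a thin CLI:

```sh
specmode simulate signal --seed 1 --out work/
specmode decompose work/noisy.csv work/dec.csv --method iceemdan
specmode select work/dec.csv work/noisy.csv work/denoised.csv --report work/sel.json
specmode bench --seeds 10 --out work/bench/
specmode study --seed 1 --out work/study.json
```

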