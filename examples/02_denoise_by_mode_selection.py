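"""Denoise the benchmark signal: select sensitive modes and reconstruct.

Runs the full pipeline (improved CEEMDAN -> correlation threshold ->
sum of kept modes) and scores the reconstruction against the clean
signal.  SNR near 18 dB means the 5 dB input noise was suppressed by
about 13 dB.
"""

from specmode import RunConfig, run_pipeline

report, selection, dec = run_pipeline(RunConfig(method="iceemdan", seed=1))

print(f"threshold mu_h = {selection.threshold:.5f}")
print(f"kept modes     = {list(selection.kept)} of {dec.n_modes}")
print(f"SNR  = {report.snr_db:6.2f} dB   (input was 5 dB)")
print(f"RMSE = {report.rmse:6.4f}")
print(f"rho  = {report.rho:6.4f}   (correlation with the clean signal)")
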