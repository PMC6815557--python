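"""Denoise a contaminated ECG trace with the db6 wavelet recipe.

Builds a 10-second synthetic trace (repeated beats), adds baseline wander,
powerline interference and white noise, and reports the error to the clean
trace before and after denoising.
"""

import numpy as np

from ecgbeat import NoiseSpec, add_noise, denoise_db6, template_signal

fs = 360.0
clean = np.tile(template_signal(0), 15)  # ~10 s of normal beats
rng = np.random.default_rng(7)
noisy = add_noise(
    clean,
    NoiseSpec(baseline_amp=0.3, baseline_hz=0.3, powerline_amp=0.1,
              powerline_hz=60.0, white_sd=0.05),
    rng, fs=fs,
)
denoised = denoise_db6(noisy, fs)

rmse = lambda x: float(np.sqrt(np.mean((x - clean) ** 2)))
print(f"RMSE to clean trace before denoising: {rmse(noisy):.4f} mV")
print(f"RMSE to clean trace after denoising:  {rmse(denoised):.4f} mV")
print("-> the deep approximation band (baseline drift) is zeroed and the")
print("   two finest detail bands are soft-thresholded (white noise),")
print("   so the residual error drops while beat morphology is preserved.")
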