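"""Preprocess epochs into feature vectors: bandpass, decimate, flatten.

A 667 ms epoch at 240 Hz holds 160 samples per channel; after the order-8
Butterworth bandpass (0.1-10 Hz) and decimation by 12, each of the 64
channels keeps 14 samples, giving an 896-element feature vector.
"""

from p300speller import PreprocessConfig, SimulationConfig, generate_dataset, preprocess_dataset

cfg = PreprocessConfig()
print(f"window: {cfg.window_ms} ms -> {cfg.window_samples} samples")
print(f"decimation factor r = floor(fs / 2 f_high) = {cfg.decimation_factor}")
print(f"samples kept per channel: {cfg.samples_per_channel}")

ds = generate_dataset(SimulationConfig(beta=2, seed=7))
X, labels, index = preprocess_dataset(ds, cfg)
print(f"feature matrix: {X.shape} ({X.shape[0]} epochs x {X.shape[1]} features)")
print(f"labels: {labels.count('target')} target / {labels.count('nontarget')} non-target")
print(f"first epoch coordinates (selection, sequence, code): {index[0]}")
# Expect 360 rows of length 896 = 14 x 64, with 60 target epochs (2 of the
# 12 flashes per sequence hit the spelled symbol's row/column).
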