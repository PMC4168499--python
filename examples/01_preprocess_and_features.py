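"""Clean a noisy heart-rate channel and extract its feature case.

Builds a 4 Hz heart-rate series with dropouts (NaN samples) and spiky
measurement noise, runs the pre-processing chain (artifact replacement ->
causal IIR low-pass -> running average) and prints the per-channel feature
vector used by the decision-level pipeline.
"""

import numpy as np

from physiofuse import (
    ChannelSeries,
    build_channel_case,
    iir_lowpass,
    replace_artifacts,
    running_average,
)

rng = np.random.default_rng(42)
fs = 4.0
t = np.arange(int(600 * fs)) / fs  # 10 minutes

# resting heart rate with a slow autonomic oscillation and sensor noise
hr = 70 + 3 * np.sin(2 * np.pi * 0.1 * t) + rng.normal(0, 1.0, t.size)
hr[rng.choice(t.size, 25, replace=False)] = np.nan  # dropouts

raw = ChannelSeries(name="HR", samples=hr, fs=fs)
repaired, n_replaced = replace_artifacts(raw)
filtered = iir_lowpass(repaired, cutoff=0.5, order=4)
smooth = running_average(filtered, window=5)

print(f"replaced {n_replaced} missing samples by the previous valid value")
print(f"noise SD before/after smoothing: "
      f"{np.std(np.diff(repaired.samples)):.3f} / {np.std(np.diff(smooth.samples)):.3f}")

case = build_channel_case(smooth)
print("\nHR feature case (time statistics + LF/HF spectral features):")
for name, value in case.as_dict().items():
    print(f"  {name:<16} {value:10.4f}")
print("\nLF/HF > 1 reflects the dominant slow (0.1 Hz) oscillation; the "
      "mean near 70 bpm and small SD describe a resting baseline.")
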