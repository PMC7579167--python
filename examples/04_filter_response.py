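"""Inspect the zero-phase band-pass used on the GSR channel.

The GSR signal is low-passed at 0.5 Hz (sensor noise) and high-passed at
0.05 Hz (tonic baseline removal), both as zero-phase order-2 Butterworth
filters. Because the filter runs forward and backward, the effective gain at
each frequency is the squared single-pass magnitude. This script compares
the predicted gain with the gain measured on pure sine probes.

Run:  python examples/04_filter_response.py
"""
import numpy as np

from stressmap.preprocess import (
    PreprocessConfig,
    highpass_tonic_removal,
    lowpass,
    zero_phase_gain,
)

FS = 4.0
cfg = PreprocessConfig()
t = np.arange(0, 600.0, 1.0 / FS)
mid = slice(len(t) // 4, 3 * len(t) // 4)


def measured_gain(filt, freq):
    x = np.sin(2 * np.pi * freq * t)
    y = filt(x)
    i = 2 * np.mean(y[mid] * x[mid])
    q = 2 * np.mean(y[mid] * np.cos(2 * np.pi * freq * t)[mid])
    return float(np.hypot(i, q))


print(f"{'filter':>9} {'f (Hz)':>7} {'predicted':>10} {'measured':>10}")
for name, cutoff, filt in (
    ("lowpass", cfg.lowpass_cutoff_hz, lambda x: lowpass(x, FS, cfg)),
    ("highpass", cfg.highpass_cutoff_hz,
     lambda x: highpass_tonic_removal(x, FS, cfg)),
):
    for freq in (0.01, 0.05, 0.2, 0.5, 1.0):
        pred = float(np.asarray(
            zero_phase_gain(cutoff, FS, cfg.filter_order, name, freq)).item())
        meas = measured_gain(filt, freq)
        print(f"{name:>9} {freq:7.2f} {pred:10.4f} {meas:10.4f}")

dc = np.max(np.abs(highpass_tonic_removal(np.full(2400, 5.0), FS)))
print(f"\nresidual after high-passing a constant 5 uS signal: {dc:.2e} uS")
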