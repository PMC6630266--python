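"""Spectrogram + PCA features and the six time-domain features of a burst.

A detected segment is framed into 200 ms windows (100 ms step), each
Hamming-weighted and Fourier-transformed; the 10-500 Hz magnitude image is
min-max normalised and its frequency axis reduced to 8 principal
components. Printed: the per-component variance contribution table (the
generator's analogue of a variance-contribution report) and one window's
time-domain features.
"""

import numpy as np

from emgfall import (
    apply_filter,
    compute_spectrogram,
    design_bandpass,
    fit_pca,
    generate_dataset,
    time_domain_features,
)

recordings = generate_dataset(n_subjects=3, reps_per_gesture=2, seed=11, noise="easy")
filtered = [apply_filter(r, design_bandpass(1500.0)) for r in recordings]

# pool normalised spectrogram frames over every annotated burst and channel
frames = []
for rec in filtered:
    for start, end in rec.bursts:
        for ch in range(rec.n_channels):
            frames.append(compute_spectrogram(rec.samples[start:end, ch], rec.fs_hz).magnitudes)
frames = np.vstack(frames)
print(f"pooled {frames.shape[0]} frames x {frames.shape[1]} frequency bins")

model = fit_pca(frames, k=8)
print("\ncomponent  variance%  cumulative%")
for row in model.variance_table():
    print(f"{row['component']:9d}  {row['variance_pct']:8.1f}  {row['cumulative_pct']:10.1f}")

rec = filtered[0]
start, _ = rec.bursts[0]
window = rec.samples[start : start + 300, 0]
f = time_domain_features(window)
print(f"\ntime-domain features of one 200 ms window (channel 1 of {rec.rec_id}):")
print(f"  MAV={f.mav:.3f}  VAR={f.var:.3f}  WL={f.wl:.1f}  RMS={f.rms:.3f}  ZC={f.zc}  SSC={f.ssc:.3f}")
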