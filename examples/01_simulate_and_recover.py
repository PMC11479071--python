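"""Render a synthetic radar scene and recover its HRV from the raw frames.

Builds a one-minute scene with a known beat sequence (mean RR 828 ms,
SDNN 37 ms), runs the full chain — phase compensation, movement
screening, bin selection, peak detection, RR construction — and compares
the recovered indices with the ground truth.
"""

import numpy as np

from pulsebeam import AcquisitionConfig, SceneParams, evaluate, generate_rr_series, render_cube

cfg = AcquisitionConfig(window_s=60.0)  # one minute at 250 frames/s
params = SceneParams(seed=1)
truth = generate_rr_series(params, cfg.window_s)
cube = render_cube(truth, params, cfg)
print(f"scene: {cube.n_bins} fast-time bins x {cube.n_frames} frames "
      f"({cube.duration_s:.0f} s at {cube.fps:.0f} fps)")

indices, details = evaluate(cube, return_details=True)
print(f"selected fast-time bin MP = {details['vital'].mp_bin} "
      f"(target placed at bin {cube.nearest_bin(params.target_range_m)})")
print(f"detected beats: {len(details['peaks'])} (truth: {len(truth.beat_times_s)})")
print()
print(f"{'index':12s} {'recovered':>10s} {'truth':>10s}")
print(f"{'mean RR ms':12s} {indices.mean_rr_ms:10.2f} {truth.rr_true_ms.mean():10.2f}")
print(f"{'SDNN ms':12s} {indices.sdnn_ms:10.2f} {truth.rr_true_ms.std(ddof=1):10.2f}")
print(f"{'RMSSD ms':12s} {indices.rmssd_ms:10.2f} "
      f"{np.sqrt(np.mean(np.diff(truth.rr_true_ms) ** 2)):10.2f}")
print(f"{'LF/HF':12s} {indices.lf_hf:10.2f}")
print()
print("recovered mean RR should sit within a few ms of truth; SDNN within a")
print("few percent — residual error is peak-timing noise plus the 4 ms frame")
print("quantisation of the 250 fps slow-time axis.")
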