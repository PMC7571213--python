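"""Simulate a treadmill trial: a 100 Hz reference stream, a jittery ~30 Hz
device stream, and the ground-truth ledger of everything injected."""

import numpy as np

from gaitconcord import GaitWorldConfig, ObservationModelConfig, simulate_trial

world = GaitWorldConfig()  # slow regime: 1.28 s stride, 0.48 m steps
device = ObservationModelConfig(
    system_id="device",
    nominal_rate=30.0,
    interframe_jitter_sd=14.92,  # ms, device-like clock jitter
    position_noise_sd=2.0,       # mm
    gap_probability=0.01,
    temporal_lag=0.37,           # s, unknown to the pipeline
)
ref, (dev,), truth = simulate_trial(world, [device], seed=1)

print(f"reference: {ref.n_frames} frames at 100 Hz, markers {ref.joint_names}")
dt = np.diff(dev.timestamps) * 1000
print(f"device:    {dev.n_frames} frames, inter-frame {dt.mean():.2f} ± {dt.std():.2f} ms")
print(f"walking bout: {truth.walking_window[0]:.1f}–{truth.walking_window[1]:.1f} s")
print(f"ground truth: {truth.heel_strike_times['left'].size} left heel strikes, "
      f"step length {truth.step_length_m.mean():.3f} m, "
      f"step width {truth.step_width_m.mean():.3f} m")
# The device stream is what a markerless camera would deliver: same walk,
# its own clock, its own frame, plus noise — the pipeline must undo all of it.
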