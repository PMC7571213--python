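"""Bring a jittery device stream onto the 100 Hz reference grid and find
its temporal lag from the jump protocol."""

from gaitconcord import (
    GaitWorldConfig,
    ObservationModelConfig,
    fill_gaps_quadratic,
    resample_uniform,
    simulate_trial,
    synchronize,
)

world = GaitWorldConfig()
device = ObservationModelConfig(
    system_id="device", nominal_rate=30.0, interframe_jitter_sd=14.92,
    position_noise_sd=2.0, gap_probability=0.01, temporal_lag=0.37,
)
ref, (dev,), truth = simulate_trial(world, [device], seed=2)

ref100 = resample_uniform(ref, 100.0)
dev100 = resample_uniform(dev, 100.0)          # long gaps stay missing
dev100, unfilled = fill_gaps_quadratic(dev100, max_gap_frames=10)

result = synchronize(ref100, dev100, ref_marker="STRN", dev_marker="pelvis")
print(f"gaps left unfilled: {len(unfilled)}")
print(f"estimated lag {result.lag_seconds:.2f} s ({result.lag_samples} samples), "
      f"peak correlation {result.peak_correlation:.2f}")
print(f"injected lag  {truth.device_lags['device']:.2f} s")
# The cross-correlation of the second derivative of the vertical pelvis /
# sternum channels locks onto the six jump spikes; the lag comes back to
# within one 10 ms sample.
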