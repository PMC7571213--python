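"""Detect heel strikes / toe offs and compute the four spatio-temporal
gait parameters, then compare against the simulator's ground truth."""

from gaitconcord import (
    AxisConvention,
    GaitEventTable,
    GaitWorldConfig,
    detect_heel_strikes,
    detect_toe_offs,
    relative_ap_signal,
    simulate_trial,
    step_length,
    step_time,
    step_width,
    stride_time,
    virtual_sacrum_channel,
)

world = GaitWorldConfig()
ref, _, truth = simulate_trial(world, [], seed=3)
conv = AxisConvention()
sacrum = virtual_sacrum_channel(ref, "reference")  # mean of RPSI and LPSI

t0, t1 = truth.walking_window
keep = (ref.timestamps >= t0) & (ref.timestamps <= t1)
t = ref.timestamps[keep]
hs = {}
for side, heel in (("left", "LHEE"), ("right", "RHEE")):
    rel = relative_ap_signal(ref.joint(heel)[keep], sacrum[keep], conv)
    hs[side] = detect_heel_strikes(rel, t)
    print(f"{side}: {hs[side].size} heel strikes "
          f"(truth {truth.heel_strike_times[side].size})")

table = GaitEventTable.from_times(100.0, heel_strikes=hs)
al, ar = ref.joint("LANK"), ref.joint("RANK")
print(f"step length  {step_length(al, ar, table).mean():.3f} m "
      f"(injected {truth.step_length_m.mean():.3f})")
print(f"step width   {step_width(al, ar, table, convention=conv).mean():.3f} m "
      f"(injected {truth.step_width_m.mean():.3f})")
print(f"step time    {step_time(table).mean():.3f} s, "
      f"stride time {stride_time(table).mean():.3f} s "
      f"(injected {truth.stride_time_s.mean():.2f})")
# Heel strikes are AP maxima of the sacrum-relative heel signal; every
# parameter follows from the events plus the ankle trajectories.
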