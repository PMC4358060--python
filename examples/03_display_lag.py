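"""Measure end-to-end display lag with the simulated two-spot rig.

Imposes a 196.7 ms motion-to-photon lag on a head oscillation, films the
two spots at 120 fps with digitisation noise, and recovers the lag by
normalized cross-correlation with sub-frame parabolic refinement.
"""

import vectionsim as vs

trace = vs.generate_head_trace(frequency=0.5, half_amplitude=21.8,
                               duration=20.0, sample_rate=80.0,
                               freq_jitter=0.05, amp_jitter=0.05,
                               crosstalk=0.0, seed=7)

for imposed in (196.7, 37.9):
    spots = vs.simulate_two_spot_video(trace, lag_ms=imposed,
                                       camera_fps=120.0, gain=1.0,
                                       noise_sd=0.2, seed=1)
    m = vs.estimate_lag(spots)
    print(f"imposed lag {imposed:6.1f} ms -> estimated "
          f"{m.lag_ms:6.1f} ms (peak r = {m.peak_correlation:.4f})")

print()
print("Reading: one camera frame at 120 fps is 8.3 ms; the estimator")
print("recovers both a rendering-dominated lag and a sensor-only lag to")
print("sub-frame accuracy from the correlation peak.")
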