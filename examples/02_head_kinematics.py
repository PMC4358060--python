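"""Generate a head-oscillation trace, log it to ASCII and analyze it.

Simulates one 30 s active trial of yaw head oscillation (nominal 0.53 Hz,
+/-21.8 deg with 5% cycle jitter), writes/reads the plain-text log, and
recovers amplitude and frequency from the detected turning points.
"""

import tempfile
from pathlib import Path

import vectionsim as vs

trace = vs.generate_head_trace(frequency=0.53, half_amplitude=21.8,
                               duration=30.0, sample_rate=80.0,
                               freq_jitter=0.05, amp_jitter=0.05,
                               crosstalk=2.0, seed=42)

log = Path(tempfile.gettempdir()) / "head_trace.log"
vs.write_head_log(trace, log)
trace = vs.read_head_log(log)
print(f"logged {trace.n_samples} samples at {trace.sample_rate:.0f} Hz "
      f"to {log}")

peaks, troughs = vs.detect_turning_points(trace)
summary = vs.summarize_kinematics(trace, peaks, troughs)
print(f"turning points: {len(peaks)} peaks, {len(troughs)} troughs")
print(f"mean peak-to-peak amplitude: {summary.mean_p2p_amplitude:.1f} deg "
      f"(SD {summary.sd_p2p_amplitude:.1f})")
print(f"mean oscillation frequency:  {summary.mean_frequency:.3f} Hz "
      f"(SD {summary.sd_frequency:.3f})")
print()
print("Reading: the analyzer recovers the generator's nominal 43.6 deg")
print("peak-to-peak range and 0.53 Hz rate from the jittered trace.")
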