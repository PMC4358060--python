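"""Yaw-dominant head-oscillation traces and turning-point kinematics.

Seated observers instructed to oscillate the head in yaw produce a
quasi-sinusoidal trace: nearly periodic, but with cycle-to-cycle drift in
both period and excursion, and small pitch/roll crosstalk.  The generator
here emulates that regime; the analyzer implements the study's kinematics
pipeline — locate turning points from the sign changes of the derivative of
yaw orientation, then summarise the mean peak-to-peak amplitude and the
oscillation frequency from consecutive-peak and consecutive-trough
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import AliasingError, AnalysisError, ConfigurationError

__all__ = [
    "HeadTrace",
    "KinematicsSummary",
    "generate_head_trace",
    "draw_cycle_parameters",
    "detect_turning_points",
    "summarize_kinematics",
    "decimate_trace",
]


@dataclass
class HeadTrace:
    """Uniformly sampled Euler head-orientation time series (degrees).

    ``t`` must be strictly increasing with spacing 1/``sample_rate``.
    """

    t: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        n = len(self.t)
        if not (len(self.yaw) == len(self.pitch) == len(self.roll) == n):
            raise ConfigurationError("trace channels must have equal length")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ConfigurationError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sample_rate)) > 1e-9:
                raise ConfigurationError(
                    "timestamps must be uniform at 1/sample_rate"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass
class KinematicsSummary:
    """Turning-point summary of one yaw oscillation trace."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    mean_p2p_amplitude: float
    sd_p2p_amplitude: float
    mean_frequency: float
    sd_frequency: float


def _draw_cycles(rng: np.random.Generator, frequency: float,
                 half_amplitude: float, duration: float,
                 freq_jitter: float, amp_jitter: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the per-cycle frequencies/half-amplitudes of a jittered trace.

    Returns ``(starts, freqs, amps)`` where ``starts`` has one more entry
    than the cycle arrays (cycle *i* spans ``[starts[i], starts[i+1])``).
    Jitter is lognormal with unit mean, so the expected cycle frequency and
    amplitude equal the nominal inputs.
    """
    n_cycles = int(np.ceil(duration * frequency
                           * (1.0 + 5.0 * freq_jitter))) + 3
    if freq_jitter > 0:
        freqs = frequency * np.exp(freq_jitter * rng.standard_normal(n_cycles)
                                   - 0.5 * freq_jitter**2)
    else:
        freqs = np.full(n_cycles, frequency)
    if amp_jitter > 0:
        amps = half_amplitude * np.exp(amp_jitter * rng.standard_normal(n_cycles)
                                       - 0.5 * amp_jitter**2)
    else:
        amps = np.full(n_cycles, half_amplitude)
    starts = np.concatenate(([0.0], np.cumsum(1.0 / freqs)))
    while starts[-1] < duration:            # extremely jittered draws
        extra_f = frequency * np.exp(freq_jitter * rng.standard_normal()
                                     - 0.5 * freq_jitter**2) \
            if freq_jitter > 0 else frequency
        starts = np.append(starts, starts[-1] + 1.0 / extra_f)
        freqs = np.append(freqs, extra_f)
        amps = np.append(amps, half_amplitude)
    return starts, freqs, amps


def draw_cycle_parameters(frequency: float, half_amplitude: float,
                          duration: float, freq_jitter: float,
                          amp_jitter: float, seed: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Realized per-cycle parameters of the trace :func:`generate_head_trace`
    would produce for the same arguments and seed (ground truth for
    round-trip analyses)."""
    return _draw_cycles(np.random.default_rng(seed), frequency,
                        half_amplitude, duration, freq_jitter, amp_jitter)


def generate_head_trace(frequency: float = 0.53,
                        half_amplitude: float = 21.8,
                        duration: float = 30.0,
                        sample_rate: float = 80.0,
                        freq_jitter: float = 0.05,
                        amp_jitter: float = 0.05,
                        crosstalk: float = 2.0,
                        seed: int = 0,
                        t0: float = 0.0) -> HeadTrace:
    """Simulate a yaw-dominant quasi-sinusoidal head oscillation.

    Yaw is built cycle by cycle: cycle ``i`` has period ``1/f_i`` and
    half-excursion ``A_i``, each lognormally jittered around the nominal
    values by the fractional ``freq_jitter`` / ``amp_jitter``, and carries a
    full sine so the trace is continuous through zero at cycle boundaries.
    Pitch and roll are slow low-amplitude sinusoids bounded by ``crosstalk``
    degrees, standing in for the small off-axis residuals of real head
    movement.  With both jitters and crosstalk zero, yaw is exactly
    ``A sin(2 pi f t)``.  Deterministic given ``seed``.
    """
    if min(frequency, half_amplitude, duration, sample_rate) <= 0:
        raise ConfigurationError(
            "frequency, half_amplitude, duration and sample_rate must be > 0"
        )
    if freq_jitter < 0 or amp_jitter < 0 or crosstalk < 0:
        raise ConfigurationError("jitters and crosstalk must be >= 0")
    if sample_rate < 2.0 * frequency:
        raise AliasingError(
            f"sample_rate {sample_rate} Hz cannot represent a {frequency} Hz "
            "oscillation (Nyquist)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = t0 + np.arange(n) / sample_rate
    starts, freqs, amps = _draw_cycles(rng, frequency, half_amplitude,
                                       duration, freq_jitter, amp_jitter)
    rel = t - t0
    idx = np.searchsorted(starts, rel, side="right") - 1
    phase = (rel - starts[idx]) * freqs[idx]
    yaw = amps[idx] * np.sin(2.0 * np.pi * phase)

    if crosstalk > 0:
        fp, fr = rng.uniform(0.08, 0.3, size=2)
        php, phr = rng.uniform(0, 2 * np.pi, size=2)
        ap, ar = crosstalk * rng.uniform(0.4, 1.0, size=2)
        pitch = ap * np.sin(2 * np.pi * fp * rel + php)
        roll = ar * np.sin(2 * np.pi * fr * rel + phr)
    else:
        pitch = np.zeros(n)
        roll = np.zeros(n)
    return HeadTrace(t, yaw, pitch, roll, sample_rate)


def decimate_trace(trace: HeadTrace, rate: float = 10.0) -> HeadTrace:
    """Down-sample a trace to a lower logging rate (default 10 Hz)."""
    step = trace.sample_rate / rate
    if step < 1 or abs(step - round(step)) > 1e-9:
        raise ConfigurationError(
            "target rate must divide the trace sample rate"
        )
    k = int(round(step))
    return HeadTrace(trace.t[::k], trace.yaw[::k], trace.pitch[::k],
                     trace.roll[::k], rate)


def _smooth(y: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return y
    return uniform_filter1d(y, size=window_samples, mode="nearest")


def _merge_close(idx: np.ndarray, values: np.ndarray, min_gap: int,
                 keep_max: bool) -> list[int]:
    """Greedy merge of candidate extrema closer than ``min_gap`` samples,
    keeping the larger excursion."""
    kept: list[int] = []
    for i in idx:
        if kept and i - kept[-1] < min_gap:
            better = values[i] > values[kept[-1]] if keep_max \
                else values[i] < values[kept[-1]]
            if better:
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return kept


def detect_turning_points(trace: HeadTrace,
                          smooth_window: float = 0.125,
                          min_separation: float = 0.47
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Locate yaw peaks and troughs as turning points of the derivative.

    Yaw is optionally smoothed with a moving average of ``smooth_window``
    seconds, then turning points are taken where the finite-difference
    derivative changes sign (strict local extrema of the smoothed yaw).
    Detections of the same type closer than ``min_separation`` seconds are
    merged keeping the larger excursion, and peak/trough alternation is
    enforced the same way.  Returns (peak_indices, trough_indices) into the
    trace; a constant trace yields two empty arrays.
    """
    if trace.n_samples < 3:
        raise AnalysisError("need at least 3 samples to detect turning points")
    y = _smooth(trace.yaw, int(round(smooth_window * trace.sample_rate)))
    d = np.diff(y)
    interior = np.arange(1, len(y) - 1)
    peaks = interior[(d[:-1] > 0) & (d[1:] <= 0)]
    troughs = interior[(d[:-1] < 0) & (d[1:] >= 0)]
    gap = max(1, int(round(min_separation * trace.sample_rate)))
    peaks = _merge_close(peaks, y, gap, keep_max=True)
    troughs = _merge_close(troughs, y, gap, keep_max=False)

    # enforce alternation: between two peaks there must be a trough & v.v.
    events = sorted([(i, +1) for i in peaks] + [(i, -1) for i in troughs])
    cleaned: list[tuple[int, int]] = []
    for i, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            j = cleaned[-1][0]
            better = y[i] > y[j] if kind > 0 else y[i] < y[j]
            if better:
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))
    pk = np.array([i for i, k in cleaned if k > 0], dtype=int)
    tr = np.array([i for i, k in cleaned if k < 0], dtype=int)
    return pk, tr


def summarize_kinematics(trace: HeadTrace, peaks: np.ndarray,
                         troughs: np.ndarray) -> KinematicsSummary:
    """Amplitude and frequency summary from detected turning points.

    Peak-to-peak amplitude is the mean absolute yaw difference between each
    turning point and the next (opposite-type) one, measured on the raw
    trace at the detected samples.  Frequency is the reciprocal of the mean
    of the pooled consecutive-peak and consecutive-trough intervals.
    """
    peaks = np.asarray(peaks, dtype=int)
    troughs = np.asarray(troughs, dtype=int)
    if len(peaks) < 2 or len(troughs) < 2:
        raise AnalysisError(
            f"need >= 2 peaks and >= 2 troughs, got {len(peaks)} peaks "
            f"and {len(troughs)} troughs"
        )
    events = np.sort(np.concatenate([peaks, troughs]))
    p2p = np.abs(np.diff(trace.yaw[events]))
    intervals = np.concatenate([np.diff(trace.t[peaks]),
                                np.diff(trace.t[troughs])])
    freqs = 1.0 / intervals
    return KinematicsSummary(
        peak_times=trace.t[peaks],
        trough_times=trace.t[troughs],
        mean_p2p_amplitude=float(np.mean(p2p)),
        sd_p2p_amplitude=float(np.std(p2p, ddof=1)) if len(p2p) > 1 else 0.0,
        mean_frequency=float(1.0 / np.mean(intervals)),
        sd_frequency=float(np.std(freqs, ddof=1)) if len(freqs) > 1 else 0.0,
    )
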