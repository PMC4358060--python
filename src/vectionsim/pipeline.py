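"""End-to-end orchestration of the synthetic vection study.

:func:`run_study` reproduces the study's full analysis chain on synthetic
inputs: per-subject head-oscillation traces for each active coupling
condition, turning-point kinematics with one-way repeated-measures ANOVAs
on amplitude and frequency, the two-spot latency measurement, a generated
2x3 rating table, and the within-subject statistics (two-way ANOVA on
strength and onset latency, follow-up active-vs-passive t-tests per
coupling, and the pooled oscillating-vs-radial contrast per viewing block).

All randomness descends from a single root seed; each stage derives its own
child seed by hashing the stage name, so any stage can be re-run in
isolation and still match the full pipeline.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .errors import VectionSimError
from .head_motion import (HeadTrace, detect_turning_points,
                          generate_head_trace, summarize_kinematics)
from .latency import estimate_lag, simulate_two_spot_video
from .observers import (COUPLINGS, VIEWINGS, EffectConfig, RatingTable,
                        generate_ratings, playback_design)
from .scene import SceneConfig
from .stats import paired_t, pooled_oscillation_contrast, rm_anova_twoway, \
    rm_anova_oneway

__all__ = ["HeadConfig", "LatencyConfig", "StudyConfig", "run_study",
           "stage_seed"]


@dataclass(frozen=True)
class HeadConfig:
    """Head-oscillation generator parameters (study defaults)."""

    frequency: float = 0.53          # Hz, measured mean oscillation rate
    half_amplitude: float = 21.8     # deg, half of the 43.6 deg mean p2p range
    duration: float = 30.0           # s per trial
    sample_rate: float = 80.0        # Hz, display-update-rate logging
    freq_jitter: float = 0.05
    amp_jitter: float = 0.05
    crosstalk: float = 2.0           # deg bound on pitch/roll residuals


@dataclass(frozen=True)
class LatencyConfig:
    """Two-spot rig parameters."""

    lag_ms: float = 196.7            # simulated end-to-end system lag
    camera_fps: float = 120.0
    gain: float = 1.0
    noise_sd: float = 0.2            # deg digitisation noise
    duration: float = 20.0           # s of filmed oscillation


@dataclass(frozen=True)
class StudyConfig:
    """Complete configuration of one synthetic study run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    latency: LatencyConfig = field(default_factory=LatencyConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    n_subjects: int = 7
    seed: int = 0


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage child seed from the root seed."""
    return int(np.random.SeedSequence(
        [int(root_seed), zlib.crc32(stage.encode())]
    ).generate_state(1)[0] % (2**31))


def _config_hash(config: StudyConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ttest_dict(r) -> dict:
    return {"t": r.t, "df": r.df, "p": r.p, "mean_difference": r.mean_difference}


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study; returns a JSON-serialisable report.

    The report carries a provenance block (config hash, seed, package
    version) sufficient to reproduce every number in it; the same config
    and seed always yield a byte-identical JSON serialisation.
    """
    report: dict = {
        "provenance": {
            "package": "vectionsim",
            "version": __version__,
            "seed": config.seed,
            "config_sha256_16": _config_hash(config),
            "config": asdict(config),
        }
    }

    # --- active head-movement kinematics, per subject x coupling ---------
    h = config.head
    amp = np.empty((config.n_subjects, len(COUPLINGS)))
    freq = np.empty_like(amp)
    kin_summaries = {}
    for i in range(config.n_subjects):
        for c, coupling in enumerate(COUPLINGS):
            seed = stage_seed(config.seed, f"head/{i}/{coupling}")
            trace = generate_head_trace(
                h.frequency, h.half_amplitude, h.duration, h.sample_rate,
                h.freq_jitter, h.amp_jitter, h.crosstalk, seed)
            peaks, troughs = detect_turning_points(trace)
            s = summarize_kinematics(trace, peaks, troughs)
            amp[i, c] = s.mean_p2p_amplitude
            freq[i, c] = s.mean_frequency
            kin_summaries[f"S{i + 1:02d}/{coupling}"] = {
                "mean_p2p_amplitude_deg": s.mean_p2p_amplitude,
                "mean_frequency_hz": s.mean_frequency,
                "n_peaks": len(s.peak_times),
            }
    report["kinematics"] = {
        "per_trial": kin_summaries,
        "mean_p2p_amplitude_deg": float(amp.mean()),
        "sd_p2p_amplitude_deg": float(amp.std(ddof=1)),
        "mean_frequency_hz": float(freq.mean()),
        "sd_frequency_hz": float(freq.std(ddof=1)),
        "anova_amplitude": rm_anova_oneway(amp).to_dict(),
        "anova_frequency": rm_anova_oneway(freq).to_dict(),
    }

    # --- two-spot latency measurement ------------------------------------
    lat = config.latency
    lat_trace = generate_head_trace(
        h.frequency, h.half_amplitude, lat.duration, h.sample_rate,
        h.freq_jitter, h.amp_jitter, 0.0,
        stage_seed(config.seed, "latency/trace"))
    spots = simulate_two_spot_video(
        lat_trace, lat.lag_ms, lat.camera_fps, lat.gain, lat.noise_sd,
        stage_seed(config.seed, "latency/noise"))
    meas = estimate_lag(spots)
    report["latency"] = {
        "imposed_lag_ms": lat.lag_ms,
        "estimated_lag_ms": meas.lag_ms,
        "peak_correlation": meas.peak_correlation,
        "method": meas.method,
        "boundary_warning": meas.boundary_warning,
    }

    # --- rating generation and within-subject statistics ------------------
    table = playback_design(generate_ratings(
        config.effects, config.n_subjects,
        stage_seed(config.seed, "ratings")))
    strength = table.cell_matrix("strength")
    anova_strength = rm_anova_twoway(strength)
    followups = {}
    for c, coupling in enumerate(COUPLINGS):
        followups[coupling] = _ttest_dict(
            paired_t(strength[:, 1, c], strength[:, 0, c]))  # passive - active
    pooled = {v: _ttest_dict(pooled_oscillation_contrast(table, v))
              for v in VIEWINGS}

    onset = table.cell_matrix("onset_latency_s")
    missing_onsets = int(np.isnan(onset).sum())
    complete = ~np.isnan(onset).any(axis=(1, 2))
    onset_note = ("complete cases only; trials rated 0 carry no onset"
                  if missing_onsets else "all trials experienced vection")
    if complete.sum() >= 2:
        anova_onset = rm_anova_twoway(onset[complete]).to_dict()
    else:
        anova_onset = None

    report["ratings"] = {
        "n_subjects": config.n_subjects,
        "cell_means_strength": {
            v: {cp: float(strength[:, j, c].mean())
                for c, cp in enumerate(COUPLINGS)}
            for j, v in enumerate(VIEWINGS)},
        "anova_strength": anova_strength.to_dict(),
        "paired_t_passive_vs_active": followups,
        "pooled_oscillation_vs_radial": pooled,
        "anova_onset_latency": anova_onset,
        "onset_missing_trials": missing_onsets,
        "onset_handling": onset_note,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialisation of a study report."""
    return json.dumps(report, indent=2, sort_keys=True, default=float)
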