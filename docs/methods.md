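# Methods

This note documents the models behind `vectionsim`, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
generators do and do not emulate.

## Scene geometry and the coupling gain

The environment is a spherical shell of small squares around the observer.
Coordinates are right-handed with the observer at the origin, forward = −z,
up = +y; positive yaw is a leftward turn (counter-clockwise from above);
Euler composition is intrinsic yaw→pitch→roll; all angles are in degrees.

**Shell bounds and square size.** The squares' angular size follows the
exact subtense `2·atan(e/2d)`. Two constraints pin the free lengths: the
squares subtend 0.25° at the 3 m outer radius, giving the edge length
e ≈ 0.01309 m, and 2.5° at the inner radius, giving r_min ≈ 0.2999 m.
Dots are sampled volume-uniformly in the shell (radii by the r³ law), the
only depth distribution consistent with a continuous size range "with
proximity". Forward self-motion (default 1 m/s, a free parameter of the
simulation exposed in `SceneConfig`) displaces dots toward +z; dots leaving
the shell are recycled to the outer sphere at a fresh random direction,
preserving the count.

**Coupling rules.** All three display couplings are expressed through one
spatiotopic FOE gain k ∈ {0, 1, 2}: the scene (dots and heading together)
is rigidly yawed by k·ψ in world coordinates while the head sits at ψ, so
the head-relative rotation is (k−1)·ψ. k = 0 keeps the scene world-fixed
(display compensates the head), k = 1 ignores the head, k = 2 drives the
FOE with the head at twice its amplitude. The gain formulation is adopted
deliberately: describing the ipsilateral condition instead as "camera yaw
doubled" contradicts the requirement that contralateral and ipsilateral
playbacks of the same trace be mirror-equivalent, while k = 2 satisfies
both descriptions at the effect level.

**Binocular frustum.** Each eye is modelled as a symmetric rectangular
frustum in tangent space with a 110° diagonal and 4:5 width:height tangent
aspect (the per-eye panel aspect), and the two eye frusta are yawed outward
by ±8.5°; visibility is their union. The outward yaw is the one free
parameter of the device model — the headset's published geometry gives only
the diagonal — and 8.5° was fixed once by solving for the value at which
the default cloud's Monte-Carlo visible fraction equals the device's
published ~20 %. A single-cone approximation (half-angle 55°, solid-angle
fraction (1−cos 55°)/2 ≈ 0.213) is available via
`SceneConfig(frustum_model="cone")`. Near/far clipping is not modelled: at
shell distances every dot inside the angular frustum is counted visible.

## Head-oscillation generator and kinematics analysis

**Generator.** Yaw is built cycle by cycle: cycle i carries one full sine
with period 1/f_i and half-excursion A_i, drawn lognormally around the
nominal values with unit mean (`freq_jitter`, `amp_jitter` are the
fractional SDs). The trace is therefore continuous through zero at cycle
boundaries, with a small slope discontinuity there — a deliberate, simple
model of intentional rhythmic movement whose rate and extent drift from
cycle to cycle. Pitch and roll are slow sinusoids bounded by `crosstalk`
(default 2°), standing in for off-axis residuals.

Defaults: 0.53 Hz and ±21.8° (the measured behaviour of instructed
observers, who oscillate slightly faster and smaller than the ±30°/0.5 Hz
instruction), 30 s trials, 80 Hz sampling (the display-update rate; a 10 Hz
decimated log matches the logger's file format). The 5 % cycle jitters and
the 2° crosstalk are not measured quantities — within-trial variability is
unpublished (the reported SDs of 18° and 0.187 Hz are between-subject) — and
were chosen once as a realistic level of cycle-to-cycle drift for paced
voluntary movement.

**Analysis.** Yaw is smoothed by a 0.125 s moving average (raw derivative
sign tests are unstable under sensor noise; the window is short relative to
the ~1.9 s period, and amplitude is read from the *raw* trace at the
detected samples so the smoothing does not attenuate it). Turning points
are the sign changes of the finite-difference derivative of the smoothed
yaw, i.e. its strict local extrema; same-type detections closer than
`min_separation` (default 0.47 s ≈ a quarter of the nominal period) are
merged keeping the larger excursion, and peak/trough alternation is
enforced the same way. Peak-to-peak amplitude is the mean |Δyaw| between
consecutive alternating turning points; frequency is the reciprocal of the
mean of pooled consecutive-peak and consecutive-trough intervals — the
interval-based definition, not a spectral one.

**Round-trip accuracy.** On a noiseless sinusoid the analyzer is accurate
to ≤0.02° in amplitude and ≪0.005 Hz in frequency (the only error is the
±half-sample quantisation of extremum times). On jittered traces the
analyzer measures the trace it is given, so its per-trace output is
compared against the *realized* cycle parameters
(`draw_cycle_parameters`), which it matches within 3 % (amplitude) / 2 %
(frequency); the *nominal* generator inputs are recovered to the same
tolerance only on average across seeds, because a 60 s trace contains only
~32 cycles and the realized mean itself fluctuates around the nominal value
by ~1 % SD per trace.

## Latency rig and estimator

The simulated rig films two spots at 120 fps: the stationary spot's
horizontal position follows the physical yaw directly; the driven spot's
vertical position follows gain × yaw delayed by the imposed lag (linear
interpolation between 80 Hz sensor samples), both with optional Gaussian
digitisation noise. The estimator mean-centres both traces and searches
causal integer frame shifts 0 … min(2 s, n/4), maximising the per-shift
Pearson correlation (per-overlap normalisation makes the estimate invariant
to affine rescaling of either trace); the integer peak is refined by a
parabola through the peak and its two neighbours, giving sub-frame
(<8.3 ms) resolution. Only causal shifts are searched because the rig
measures a physical delay; a peak at the search boundary sets a warning
flag rather than failing. Bias over imposed lags 25–250 ms is within half a
frame noiseless and one frame at 5 %-of-amplitude noise.

## Rating generator

Strength for subject i in cell (j, c) is
`clamp[0,100]( μ + s_i + v_j + b_c + (vb)_jc + ε )` with
s_i ~ N(0, subject_sd = 8) and ε ~ N(0, noise_sd = 6.5); the clamp is the
only nonlinearity, so with the default moderate effects the cell means
equal the linear predictor to well under 0.1 unit. Onset latency is
`max(0.5 s, 20 − 0.1·strength + N(0, 4))` — onsets shorten as vection
strengthens — and is absent when the clamped strength is exactly 0 (the
observer never felt self-motion, so there is no onset to report); analyses
of onset latency run on complete cases and the report flags the dropped
count.

The default effect decomposition corresponds to cell means
(active: 60/54/49; passive: 64/57/66 for contralateral/pure/ipsilateral):
grand mean 58.33, viewing effect +8 (passive−active), coupling deviations
(+3.67, −2.83, −0.83), interaction (±2, ±2.5, ∓4.5). The magnitudes are
free parameters (no cell means are published); they were derived
analytically so that at n = 7 the *expected* statistics produce the
qualitative pattern the design is meant to exhibit — viewing main effect
significant (expected F₁,₆ ≈ 16), coupling marginal (F₂,₁₂ ≈ 3.7,
p ≈ 0.06), interaction significant (F₂,₁₂ ≈ 5), a large
ipsilateral passive-vs-active difference (t₆ ≈ 4.9) with the contralateral
and pure differences non-significant, and the pooled oscillating-vs-radial
advantage significant only under passive viewing (t₆ ≈ 2.7). Individual
seeds fluctuate around this modal pattern, as real 7-subject studies would.
The default n = 7 reflects the analyzed sample implied by df = 6
throughout the design's reporting convention.

## Statistics

Sums of squares are computed directly from marginal means (designs are
balanced by construction). In the two-way fully-within ANOVA each effect is
tested against its own interaction with subjects: A against A×S
(df 1, n−1), B against B×S (df 2, 2(n−1)), A×B against A×B×S (df 2,
2(n−1)); at n = 7 these are the (1,6)/(2,12) pairs. Degrees of freedom are
uncorrected by default (matching the reporting convention the package
mirrors); `gg=True` applies a Greenhouse–Geisser ε computed from the
covariance of the per-subject level scores (validated against pingouin).
Tail probabilities use scipy's F and t survival functions (regularized
incomplete beta; precision ~1e−10). Type-I error of all tests is calibrated
within [0.04, 0.06] at α = 0.05 under 10⁴ null simulations.

Degenerate inputs: an all-constant matrix (zero error variance) raises
`DegenerateDataError`; a paired t on identical samples returns the
degenerate t = 0, p = 1 (zero-variance differences around a *nonzero* mean
still raise, since t is then ±∞).

## Pipeline and reproducibility

`run_study` derives every stage's seed from the root seed by hashing the
stage name into a `SeedSequence`, so any stage can be re-run in isolation
and still match the full run; the report embeds a provenance block (seed,
config hash, version) and serialises byte-identically for a fixed config.
Problem sizes used by the test suite and acceptance script — 10⁵-dot
clouds × 20 scenes, 60 s traces × 500 seeds, 10⁴ null ANOVA simulations,
200 replicate power studies at n = 200 — were chosen as the package's
standard verification scale: large enough that Monte-Carlo error is small
against every tolerance checked.

## What the synthetic data do and do not show

The generators reproduce the *structure* of the paradigm — design balance,
rating-scale clamping, missing onsets, yaw-dominant oscillation with drift,
a causal sensor-to-display lag — but not the physiology behind it: no
adaptation or carry-over across trials, no observer-specific oscillation
style beyond an additive subject effect, no dependence of ratings on the
actual flow-field geometry module (the effect pattern is imposed, not
emergent), Gaussian noise throughout, and no motion-sickness or postural
covariates. Passing tests therefore validate the geometry, the estimators
and the statistical machinery, and show the generators are faithful to
their own stated distributions — they do not confirm the behavioural
effects in real observers.

## Known limitations

- The binocular frustum is a tangent-space rectangle union; real headset
  fields are lens-distorted and roughly oval, so per-dot visibility near
  the rim is approximate (the aggregate ~20 % fraction is calibrated).
- Dot recycling to the outer sphere makes the long-run radial occupancy
  only approximately volume-uniform (stationary, but with a mild outward
  bias); adequate for flow statistics, not for exact density claims.
- `estimate_lag` assumes a broadly oscillatory signal; for near-periodic
  traces with period shorter than the search range, correlation side-lobes
  one full period away can compete with the true peak under heavy noise.
- The ANOVA handles complete balanced designs only; unbalanced or missing
  data raise `DesignError` rather than falling back to a mixed model.
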