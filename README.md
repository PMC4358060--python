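# vectionsim

Vection — the illusion of self-motion in a stationary observer — can be
driven by optic flow in a head-mounted display whose virtual viewpoint is
coupled to the observer's tracked head rotation. `vectionsim` is a
synthetic, end-to-end testable model of that experimental paradigm, written
for vision scientists who want to prototype, power, and validate
head-coupled vection studies without hardware or human subjects. It
provides:

- **Flow-field geometry** (`vectionsim.scene`): a spherical cloud of
  163,840 squares (0.25°–2.5° optical size over a 0.30–3 m shell) viewed
  through a binocular 110°-diagonal frustum, with simulated forward
  self-motion and three visual-vestibular coupling rules unified by a
  focus-of-expansion gain *k*: for head yaw ψ the spatiotopic FOE azimuth is
  *k*ψ and the head-relative FOE azimuth is (*k*−1)ψ, with *k* = 0
  (contralateral / world-stable display), 1 (pure radial flow glued to the
  nose) and 2 (ipsilateral, FOE moving with the head at twice its
  amplitude).
- **Head-motion kinematics** (`vectionsim.head_motion`): a generator of
  yaw-dominant quasi-sinusoidal oscillation (nominal 0.53 Hz, ±21.8°, with
  cycle-to-cycle jitter and pitch/roll crosstalk) and the matching analysis:
  turning points from derivative sign changes, mean peak-to-peak amplitude,
  and frequency from pooled consecutive-peak/trough intervals.
- **Display-lag estimation** (`vectionsim.latency`): a simulated two-spot
  optical rig filmed at 120 fps, and a normalized cross-correlation lag
  estimator with sub-frame parabolic peak refinement.
- **Synthetic observers** (`vectionsim.observers`): a generative linear
  model of 0–100 vection strength ratings and onset latencies in the
  2 (active/passive viewing) × 3 (coupling) within-subject design, clamped
  to the rating-meter range.
- **Within-subject statistics** (`vectionsim.stats`): one- and two-way
  repeated-measures ANOVA computed from scratch (each effect tested against
  its own subject-by-effect error term; F = MS_effect/MS_error with df
  (a−1), (a−1)(n−1)), paired t-tests (t = d̄/(s_d/√n)), and the pooled
  oscillating-vs-radial contrast. An optional Greenhouse–Geisser correction
  sits behind a flag.
- **Pipeline + CLI** (`vectionsim.pipeline`, `vectionsim` command): a fully
  seeded study orchestrator and thin shell subcommands
  (`simulate-trace`, `analyze-kinematics`, `flow-summary`, `measure-lag`,
  `gen-ratings`, `analyze-ratings`, `run-study`).

## Worked example

`examples/04_rating_study.py` draws a 7-subject rating table from the
default effect pattern and runs the full statistical analysis:

```
cell mean vection strength (0-100):
            contralateral    pure_radial    ipsilateral
active               57.4           54.3           49.1
passive              65.3           51.9           66.1

effect                      df          SS          MS         F         p
viewing                 1,6        593.134     593.134    22.793    0.0031
coupling                2,12       479.898     239.949     7.485    0.0078
viewing x coupling      2,12       650.811     325.405     6.299    0.0135

passive vs active, per coupling condition:
  contralateral   t(6) =  1.84, p = 0.1148, mean diff = +7.9
  pure_radial     t(6) = -0.79, p = 0.4585, mean diff = -2.3
  ipsilateral     t(6) =  5.39, p = 0.0017, mean diff = +16.9

pooled (contralateral+ipsilateral)/2 vs pure radial:
  active   t(6) = -0.51, p = 0.6286, mean diff = -1.0
  passive  t(6) =  3.85, p = 0.0084, mean diff = +13.8
```

The df pairs (1,6) and (2,12) are those of a 7-subject fully-within 2×3
design. In this draw passive viewing yields stronger vection overall, and
the passive advantage concentrates in the ipsilateral condition — the
interaction the generator's default effect pattern encodes. The pooled
contrast shows head-coupled (oscillating) flow beating pure radial flow
only under passive viewing.

Other examples: `01_flow_field_geometry.py` (optical sizes, ~20% frustum
visibility, FOE gain law), `02_head_kinematics.py` (ASCII head-log
round-trip and amplitude/frequency recovery), `03_display_lag.py`
(196.7 ms and 37.9 ms imposed lags recovered to sub-frame accuracy),
`05_full_study.py` (the seeded end-to-end report).

## Layout

```
src/vectionsim/    scene, head_motion, latency, observers, stats, pipeline,
                   io, cli
examples/          one narrative script per capability
tests/             unit + property tests, plus end-to-end suite
docs/methods.md    model assumptions, defaults, numerical choices
```
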