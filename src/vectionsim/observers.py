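"""Generative model of per-subject vection ratings and onset latencies.

The study design is fully within-subject: every observer rates vection
strength (0-100 meter setting) and reports an onset latency in each cell of
a 2 (viewing: active head oscillation vs passive playback) x 3 (display
coupling: contralateral / pure radial / ipsilateral) design.  No raw human
data are available, so this module provides a linear-model generator whose
default effect pattern encodes the study's qualitative findings: passive
viewing yields stronger vection overall, the coupling main effect is only
marginal, and the passive advantage is concentrated in the ipsilateral
condition (the interaction).  Onset latency is inversely related to rated
strength, with trials rated 0 (no vection ever experienced) carrying no
onset at all.

Strength for subject *i* in cell (*j*, *c*) is

    clamp_[0,100]( mu + s_i + v_j + b_c + (vb)_jc + eps_ijc )

with s_i ~ N(0, subject_sd) and eps ~ N(0, noise_sd); the clamp to the
rating meter's range is the model's only nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError

__all__ = ["EffectConfig", "RatingTable", "generate_ratings",
           "playback_design", "VIEWINGS", "COUPLINGS"]

VIEWINGS = ("active", "passive")
COUPLINGS = ("contralateral", "pure_radial", "ipsilateral")

# Default cell means (active: 60/54/49, passive: 64/57/66) decomposed into
# grand mean + main effects + interaction; magnitudes are free parameters of
# the generator, chosen so that at n = 7 the expected statistics reproduce
# the qualitative significance pattern of the study (see docs/methods.md).
_GRAND_MEAN = 175.0 / 3.0
_VIEWING_EFFECT = 8.0                       # passive minus active
_COUPLING = (11.0 / 3.0, -17.0 / 6.0, -5.0 / 6.0)
_INTERACTION = ((2.0, 2.5, -4.5),           # active row
                (-2.0, -2.5, 4.5))          # passive row


@dataclass(frozen=True)
class EffectConfig:
    """Population parameters of the rating generator.

    ``viewing_effect`` is the passive-minus-active difference in rating
    units; ``coupling_effects`` are the three coupling deviations (summing
    to zero, ordered contralateral / pure_radial / ipsilateral);
    ``interaction_effects`` is the 2x3 viewing-by-coupling table with zero
    row and column sums.  ``latency_base`` and ``latency_slope`` map rated
    strength to onset latency (seconds), floored at 0.5 s.
    """

    grand_mean: float = _GRAND_MEAN
    viewing_effect: float = _VIEWING_EFFECT
    coupling_effects: tuple[float, float, float] = _COUPLING
    interaction_effects: tuple[tuple[float, float, float],
                               tuple[float, float, float]] = _INTERACTION
    subject_sd: float = 8.0
    noise_sd: float = 6.5
    latency_base: float = 20.0
    latency_slope: float = 0.1
    latency_noise_sd: float = 4.0

    def __post_init__(self):
        for name in ("subject_sd", "noise_sd", "latency_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(sum(self.coupling_effects)) > 1e-9:
            raise ConfigurationError("coupling_effects must sum to zero")
        inter = np.asarray(self.interaction_effects, dtype=float)
        if inter.shape != (2, 3):
            raise ConfigurationError("interaction_effects must be 2x3")
        if np.max(np.abs(inter.sum(axis=0))) > 1e-9 \
                or np.max(np.abs(inter.sum(axis=1))) > 1e-9:
            raise ConfigurationError(
                "interaction_effects must have zero row and column sums"
            )

    def cell_mean(self, viewing: str, coupling: str) -> float:
        """Population mean strength of one design cell (before clamping)."""
        j = VIEWINGS.index(viewing)
        c = COUPLINGS.index(coupling)
        v = (-0.5 if j == 0 else 0.5) * self.viewing_effect
        return (self.grand_mean + v + self.coupling_effects[c]
                + self.interaction_effects[j][c])


@dataclass
class RatingTable:
    """Vection ratings in long format.

    ``data`` columns: subject, viewing, coupling, strength,
    onset_latency_s (NaN when vection never arose), trial_id, and after
    :func:`playback_design` also source_trial_id / playback_equivalent.
    """

    data: pd.DataFrame

    REQUIRED = ("subject", "viewing", "coupling", "strength", "onset_latency_s")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DesignError(f"rating table missing columns {missing}")

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.data["subject"])

    @property
    def is_complete(self) -> bool:
        counts = self.data.groupby(
            ["subject", "viewing", "coupling"], observed=True).size()
        n_sub = len(self.subjects)
        return len(counts) == n_sub * 6 and bool((counts == 1).all())

    def cell_matrix(self, measure: str = "strength") -> np.ndarray:
        """Return an (n_subjects, 2, 3) array of the requested measure.

        Ordering follows :data:`VIEWINGS` and :data:`COUPLINGS`.  Raises
        :class:`DesignError` if the design is incomplete.
        """
        if not self.is_complete:
            raise DesignError("design is incomplete: one record per "
                              "subject x viewing x coupling cell required")
        wide = self.data.pivot_table(index="subject", columns=["viewing", "coupling"],
                                     values=measure, observed=True)
        out = np.empty((len(wide), 2, 3))
        for j, v in enumerate(VIEWINGS):
            for c, cp in enumerate(COUPLINGS):
                out[:, j, c] = wide[(v, cp)].to_numpy()
        return out


def generate_ratings(effects: EffectConfig, n_subjects: int = 7,
                     seed: int = 0) -> RatingTable:
    """Draw a complete 2x3 within-subject rating table.

    One record per subject x viewing x coupling cell; strengths are clamped
    to the [0, 100] meter range; onset latency is
    ``max(0.5, latency_base - latency_slope * strength + noise)`` seconds
    and absent (NaN) when the clamped strength is exactly 0.  Deterministic
    given ``seed``.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    subj_dev = effects.subject_sd * rng.standard_normal(n_subjects)
    rows = []
    trial = 0
    for i in range(n_subjects):
        for j, viewing in enumerate(VIEWINGS):
            for coupling in COUPLINGS:
                mu = effects.cell_mean(viewing, coupling) + subj_dev[i]
                strength = float(np.clip(
                    mu + effects.noise_sd * rng.standard_normal(), 0.0, 100.0))
                if strength == 0.0:
                    onset = np.nan
                else:
                    onset = max(0.5, effects.latency_base
                                - effects.latency_slope * strength
                                + effects.latency_noise_sd
                                * rng.standard_normal())
                rows.append({"subject": f"S{i + 1:02d}", "viewing": viewing,
                             "coupling": coupling, "strength": strength,
                             "onset_latency_s": onset, "trial_id": trial})
                trial += 1
    return RatingTable(pd.DataFrame(rows))


def playback_design(table: RatingTable) -> RatingTable:
    """Link each passive trial to the active trial whose head trace it replays.

    Passive playback re-presents the display recorded during the matching
    active trial of the same subject and coupling; contralateral and
    ipsilateral playbacks of the same head trace deliver identical visual
    stimulation and are flagged ``playback_equivalent``.  Returns a new
    table with ``source_trial_id`` (NaN for active rows) and
    ``playback_equivalent`` columns.
    """
    df = table.data
    if len(df) == 0:
        raise DesignError("empty rating table")
    active = df[df["viewing"] == "active"]
    passive = df[df["viewing"] == "passive"]
    key = active.set_index(["subject", "coupling"])["trial_id"]
    if key.index.has_duplicates:
        raise DesignError("duplicate active trials for a subject x coupling cell")
    needed = set(zip(passive["subject"], passive["coupling"]))
    missing = [k for k in needed if k not in key.index]
    if missing:
        raise DesignError(f"incomplete active block: missing cells {missing}")
    out = df.copy()
    src = pd.Series(np.nan, index=df.index)
    mask = df["viewing"] == "passive"
    src[mask] = [key[(s, c)] for s, c in
                 zip(df.loc[mask, "subject"], df.loc[mask, "coupling"])]
    out["source_trial_id"] = src
    out["playback_equivalent"] = mask & df["coupling"].isin(
        ["contralateral", "ipsilateral"])
    return RatingTable(out)
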