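"""Repeated-measures ANOVA, paired t-tests and the pooled-oscillation contrast.

All sums-of-squares partitions are computed directly from cell and marginal
means (every observer contributes one observation to every level, so the
designs are balanced and the classical closed forms apply).  Each
within-subject effect is tested against its own subject-by-effect
interaction error term, and degrees of freedom are uncorrected by default —
a Greenhouse-Geisser sphericity correction is available behind a flag.
Tail probabilities come from the F and t distributions (regularized
incomplete beta function, precise to ~1e-10 over the relevant range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, DesignError
from .observers import COUPLINGS, VIEWINGS, RatingTable

__all__ = ["EffectTest", "AnovaResult", "TTestResult",
           "rm_anova_oneway", "rm_anova_twoway", "paired_t",
           "pooled_oscillation_contrast"]


@dataclass
class EffectTest:
    """One tested effect of a repeated-measures ANOVA."""

    name: str
    df_effect: int
    df_error: int
    ss_effect: float
    ss_error: float
    F: float
    p: float
    gg_epsilon: float | None = None

    @property
    def ms_effect(self) -> float:
        return self.ss_effect / self.df_effect

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error


@dataclass
class AnovaResult:
    """Collection of effect tests from one ANOVA."""

    effects: list[EffectTest]
    n_subjects: int

    def __getitem__(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {e.name: {"df": [e.df_effect, e.df_error],
                         "SS": e.ss_effect, "SS_error": e.ss_error,
                         "F": e.F, "p": e.p} for e in self.effects}

    def to_text(self) -> str:
        lines = [f"{'effect':<22}{'df':>8}{'SS':>12}{'MS':>12}"
                 f"{'F':>10}{'p':>10}"]
        for e in self.effects:
            lines.append(f"{e.name:<22}{e.df_effect:>3},{e.df_error:<4}"
                         f"{e.ss_effect:>12.3f}{e.ms_effect:>12.3f}"
                         f"{e.F:>10.3f}{e.p:>10.4f}")
        return "\n".join(lines)


@dataclass
class TTestResult:
    """Two-sided repeated-measures (paired) t-test result."""

    t: float
    df: int
    p: float
    mean_difference: float


def _check_matrix(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise DesignError(f"{name} contains missing cells")
    return x


def _f_p(F: float, df1: int, df2: int) -> float:
    return float(sps.f.sf(F, df1, df2))


def rm_anova_oneway(table: np.ndarray, gg: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x levels matrix.

    Partitions total SS into subjects, treatment and subject-by-treatment
    error; F = MS_treatment / MS_error with df (a-1, (a-1)(n-1)).
    """
    x = _check_matrix(table, "table")
    if x.ndim != 2:
        raise DesignError("expected a 2-D subjects x levels matrix")
    n, a = x.shape
    if n < 2 or a < 2:
        raise DesignError("need >= 2 subjects and >= 2 levels")
    gm = x.mean()
    ss_sub = a * np.sum((x.mean(axis=1) - gm) ** 2)
    ss_trt = n * np.sum((x.mean(axis=0) - gm) ** 2)
    ss_tot = np.sum((x - gm) ** 2)
    ss_err = ss_tot - ss_sub - ss_trt
    df_e, df_r = a - 1, (a - 1) * (n - 1)
    if ss_err <= 1e-12 * max(ss_tot, 1.0):
        raise DegenerateDataError("zero within-subject error variance")
    F = (ss_trt / df_e) / (ss_err / df_r)
    eps = _gg_epsilon(x) if gg else None
    p = _f_p(F, df_e, df_r) if eps is None else _f_p(F, df_e * eps, df_r * eps)
    eff = EffectTest("treatment", df_e, df_r, float(ss_trt), float(ss_err),
                     float(F), p, gg_epsilon=eps)
    return AnovaResult([eff], n_subjects=n)


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x levels score matrix."""
    k = scores.shape[1]
    if k < 3:
        return 1.0
    S = np.cov(scores, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k**2 * mean_all**2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_twoway(table: np.ndarray, factor_names: tuple[str, str] =
                    ("viewing", "coupling"), gg: bool = False) -> AnovaResult:
    """Two-way fully-within ANOVA on a subjects x a x b array.

    Each effect (A, B, A x B) is tested against its own interaction with
    subjects.  For the study design (n = 7, a = 2, b = 3) the df pairs are
    (1, 6) for A and (2, 12) for both B and the interaction.
    """
    x = _check_matrix(table, "table")
    if x.ndim != 3:
        raise DesignError("expected a 3-D subjects x A x B array")
    n, a, b = x.shape
    if n < 2 or a < 2 or b < 2:
        raise DesignError("need >= 2 subjects and >= 2 levels per factor")
    gm = x.mean()
    m_s = x.mean(axis=(1, 2))            # per subject
    m_a = x.mean(axis=(0, 2))            # per A level
    m_b = x.mean(axis=(0, 1))            # per B level
    m_sa = x.mean(axis=2)                # n x a
    m_sb = x.mean(axis=1)                # n x b
    m_ab = x.mean(axis=0)                # a x b

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    resid = (x - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - gm)
    ss_abs = np.sum(resid**2)

    ss_tot = np.sum((x - gm) ** 2)
    specs = [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1),
         m_sa),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
         m_sb),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab, (a - 1) * (b - 1),
         ss_abs, (a - 1) * (b - 1) * (n - 1), None),
    ]
    effects = []
    for name, ss_e, df_e, ss_r, df_r, scores in specs:
        if ss_r <= 1e-12 * max(ss_tot, 1.0):
            raise DegenerateDataError(f"zero error variance for effect {name!r}")
        F = (ss_e / df_e) / (ss_r / df_r)
        eps = None
        if gg:
            if scores is None:
                # interaction contrasts: subjects x (a-1)(b-1) score matrix
                contr = (x - m_sa[:, :, None] - m_sb[:, None, :]
                         + m_s[:, None, None])
                eps = _gg_epsilon(contr.reshape(n, a * b))
            else:
                eps = _gg_epsilon(scores)
        p = _f_p(F, df_e, df_r) if eps is None \
            else _f_p(F, df_e * eps, df_r * eps)
        effects.append(EffectTest(name, df_e, df_r, float(ss_e), float(ss_r),
                                  float(F), p, gg_epsilon=eps))
    return AnovaResult(effects, n_subjects=n)


def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-sided repeated-measures t-test on paired per-subject values.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = x - y`` and df = n - 1.
    Identical samples (zero-variance, zero-mean differences) return the
    degenerate t = 0, p = 1; zero variance around a nonzero mean is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise DesignError("need two equal-length 1-D samples with n >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DesignError("paired samples contain missing values")
    d = x - y
    n = len(d)
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(0.0, n - 1, 1.0, 0.0)
        raise DegenerateDataError("zero-variance differences with nonzero mean")
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(float(t), n - 1, p, md)


def pooled_oscillation_contrast(table: RatingTable, viewing: str,
                                measure: str = "strength") -> TTestResult:
    """Oscillating-vs-radial contrast within one viewing block.

    For each subject, the contralateral and ipsilateral cells are averaged
    and compared against the pure-radial cell with a paired t-test.  A
    positive mean difference means head-coupled (oscillating) flow produced
    stronger vection than pure radial flow.
    """
    if viewing not in VIEWINGS:
        raise DesignError(f"viewing must be one of {VIEWINGS}")
    cells = table.cell_matrix(measure)          # raises DesignError if incomplete
    j = VIEWINGS.index(viewing)
    contra = cells[:, j, COUPLINGS.index("contralateral")]
    ipsi = cells[:, j, COUPLINGS.index("ipsilateral")]
    pure = cells[:, j, COUPLINGS.index("pure_radial")]
    return paired_t((contra + ipsi) / 2.0, pure)
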