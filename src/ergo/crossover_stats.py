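"""Inferential statistics for the two-condition crossover trial.

Paired t-tests compare the per-subject energy components between the LIE
and LIE-BFR sessions; a two-way (condition × time) repeated-measures
ANOVA with Bonferroni-adjusted per-time paired comparisons handles the
lactate, HR and V̇E time courses; typical error and coefficient of
variation summarise test–retest reliability.

The repeated-measures decomposition is the classical fully-within-subject
one: every effect (condition, time, condition × time) is tested against
its own subject-interaction error stratum. Sphericity is assumed and no
Greenhouse–Geisser correction is applied; this assumption is surfaced in
the result object.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "PairedTResult",
    "Effect",
    "AnovaResult",
    "RMAnova",
    "paired_t",
    "rm_anova",
    "bonferroni",
    "typical_error_cv",
    "posthoc_by_time",
]

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass(frozen=True)
class PairedSample:
    """One subject's outcome in both conditions of the crossover
    (``value_a`` = LIE, ``value_b`` = LIE-BFR)."""

    subject_id: str
    value_a: float
    value_b: float


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float  # mean(value_b − value_a)
    degenerate: bool = False


def paired_t(samples_or_a, b=None) -> PairedTResult:
    """Two-sided paired t-test on within-subject differences (df = n − 1).

    Accepts either a list of :class:`PairedSample` or two equal-length
    arrays ``(a, b)``; the tested difference is ``b − a``. Zero variance
    of the differences with a nonzero mean is reported as a degenerate
    result (|t| = ∞, p = 0) rather than an error.
    """
    if b is None:
        a = np.array([s.value_a for s in samples_or_a], dtype=float)
        b_arr = np.array([s.value_b for s in samples_or_a], dtype=float)
    else:
        a = np.asarray(samples_or_a, dtype=float)
        b_arr = np.asarray(b, dtype=float)
    if a.size != b_arr.size:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = b_arr - a
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0)
        return PairedTResult(math.copysign(math.inf, mean_d), n - 1, 0.0, mean_d, degenerate=True)
    res = stats.ttest_rel(b_arr, a)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue), mean_d)


class Effect(str, enum.Enum):
    CONDITION = "condition"
    TIME = "time"
    INTERACTION = "interaction"


@dataclass(frozen=True)
class AnovaResult:
    effect: Effect
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float
    ss_error: float


@dataclass(frozen=True)
class RMAnova:
    """Two-way fully-within-subject ANOVA table.

    ``ss_components`` holds every stratum of the decomposition; their sum
    equals ``ss_total`` exactly (conservation of sums of squares).
    """

    effects: tuple[AnovaResult, ...]
    ss_components: dict = field(default_factory=dict)
    ss_total: float = 0.0
    sphericity_assumed: bool = True

    def __getitem__(self, effect: Effect | str) -> AnovaResult:
        effect = Effect(effect)
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)


def rm_anova(data: np.ndarray) -> RMAnova:
    """Two-way repeated-measures ANOVA on a balanced (subject × condition
    × time) array.

    ``data`` has shape ``(n_subjects, n_conditions, n_times)`` with one
    observation per cell and no missing values. Each effect's F uses its
    own subject-interaction error stratum:

    * condition:        df = (a−1), (a−1)(n−1)
    * time:             df = (b−1), (b−1)(n−1)
    * condition × time: df = (a−1)(b−1), (a−1)(b−1)(n−1)
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, conditions, times)")
    if np.any(np.isnan(data)):
        raise ValueError("missing cells are not allowed (no imputation)")
    n, a, b = data.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects, >= 2 conditions, >= 2 times")

    grand = data.mean()
    m_s = data.mean(axis=(1, 2))  # per subject
    m_a = data.mean(axis=(0, 2))  # per condition
    m_b = data.mean(axis=(0, 1))  # per time
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_s = a * b * float(np.sum((m_s - grand) ** 2))
    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    ss_as = b * float(np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2))
    ss_bs = a * float(np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_as + ss_bs + ss_ab)

    def f_test(effect: Effect, ss_eff: float, df_num: int, ss_err: float, df_den: int) -> AnovaResult:
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        if ms_err == 0.0:
            F = 0.0 if ms_eff == 0.0 else math.inf
            p = 1.0 if ms_eff == 0.0 else 0.0
        else:
            F = ms_eff / ms_err
            p = float(stats.f.sf(F, df_num, df_den))
        return AnovaResult(effect, F, df_num, df_den, p, ss_eff, ss_err)

    effects = (
        f_test(Effect.CONDITION, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        f_test(Effect.TIME, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        f_test(Effect.INTERACTION, ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    )
    components = {
        "subject": ss_s,
        "condition": ss_a,
        "time": ss_b,
        "condition_x_subject": ss_as,
        "time_x_subject": ss_bs,
        "condition_x_time": ss_ab,
        "condition_x_time_x_subject": ss_abs,
    }
    return RMAnova(effects, components, ss_total)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, p × m)`` (m defaults to the
    number of comparisons)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def typical_error_cv(test, retest) -> dict:
    """Test–retest typical error and coefficient of variation.

    te = SD(differences)/√2; cv = 100 × te / grand mean of all
    measurements. A zero grand mean makes the CV undefined → error.
    """
    t1 = np.asarray(test, dtype=float)
    t2 = np.asarray(retest, dtype=float)
    if t1.size != t2.size:
        raise ValueError("test and retest must have equal length")
    if t1.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = t2 - t1
    te = float(d.std(ddof=1)) / math.sqrt(2.0)
    grand = float(np.concatenate([t1, t2]).mean())
    if grand == 0.0:
        raise ZeroDivisionError("coefficient of variation undefined: grand mean is 0")
    return {"te": te, "cv_percent": 100.0 * te / grand}


def posthoc_by_time(data: np.ndarray) -> list[dict]:
    """Per-time between-condition paired comparisons, Bonferroni-adjusted
    over the number of time points (the post-hoc family used after a
    significant condition or interaction F)."""
    data = np.asarray(data, dtype=float)
    n, a, b = data.shape
    if a != 2:
        raise ValueError("post hoc implemented for exactly 2 conditions")
    raw = []
    for j in range(b):
        raw.append(paired_t(data[:, 0, j], data[:, 1, j]))
    adj = bonferroni([r.p for r in raw], m=b)
    return [
        {"time_index": j, "t": r.t, "df": r.df, "p_raw": r.p, "p_adj": float(adj[j]),
         "mean_diff": r.mean_diff}
        for j, r in enumerate(raw)
    ]
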