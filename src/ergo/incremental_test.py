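"""Incremental cycling test utilities.

Protocol construction (50 W start, +15 W·min⁻¹ to 200 W, +10 W·min⁻¹
after), maximal-effort criteria, segmented-regression detection of the
ventilatory threshold (VT, non-linear rise of V̇E/V̇O2) and respiratory
compensation point (RCP, non-linear rise of V̇E/V̇CO2), %V̇O2max
arithmetic, and blood-flow-restriction cuff-pressure prescription as a
fraction of the arterial occlusion pressure.

The breakpoint detector is an automated surrogate for by-eye threshold
placement by independent raters: a continuous two-segment piecewise-linear
least-squares fit over a grid of candidate breakpoints, gated by an F-test
against the single-line fit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ProtocolStage",
    "MaximalityReport",
    "ThresholdKind",
    "ThresholdEstimate",
    "CuffPrescription",
    "build_protocol",
    "maximality_criteria",
    "detect_breakpoint",
    "fraction_of_vo2max",
    "occlusion_target",
    "power_at_vo2",
]


@dataclass(frozen=True)
class ProtocolStage:
    minute_index: int  # 1-based
    power: float  # W


def build_protocol(max_minutes: int) -> list[ProtocolStage]:
    """Stage powers for the graded test: minute 1 at 50 W, +15 W per
    minute until 200 W is reached, +10 W per minute thereafter."""
    if max_minutes < 1:
        raise ValueError("max_minutes must be >= 1")
    stages: list[ProtocolStage] = []
    power = 50.0
    for minute in range(1, max_minutes + 1):
        stages.append(ProtocolStage(minute, power))
        power += 15.0 if power < 200.0 else 10.0
    return stages


@dataclass(frozen=True)
class MaximalityReport:
    """Which of the four maximal-effort criteria were met.

    A test is maximal when two or more hold: a V̇O2 plateau, RER > 1.1,
    HR above 90% of the age-predicted maximum (220 − age), and a rating
    of perceived exertion above 17 on the 6–20 scale.
    """

    plateau: bool
    rer_gt_1_1: bool
    hr_gt_90pct_pred: bool
    rpe_gt_17: bool

    @property
    def n_met(self) -> int:
        return sum((self.plateau, self.rer_gt_1_1, self.hr_gt_90pct_pred, self.rpe_gt_17))

    @property
    def is_maximal(self) -> bool:
        return self.n_met >= 2


def maximality_criteria(
    *,
    plateau: bool | None = None,
    rer_max: float | None = None,
    hr_max: float | None = None,
    age: float | None = None,
    rpe_max: float | None = None,
) -> MaximalityReport:
    """Evaluate the four maximal-effort criteria; absent inputs count as
    not met. ``age`` (years, 10–90) is required when ``hr_max`` is given."""
    if all(v is None for v in (plateau, rer_max, hr_max, rpe_max)):
        raise ValueError("at least one criterion input must be provided")
    hr_ok = False
    if hr_max is not None:
        if age is None or not (10 <= age <= 90):
            raise ValueError("age in [10, 90] required to evaluate the HR criterion")
        hr_ok = hr_max > 0.9 * (220.0 - age)
    return MaximalityReport(
        plateau=bool(plateau),
        rer_gt_1_1=rer_max is not None and rer_max > 1.1,
        hr_gt_90pct_pred=hr_ok,
        rpe_gt_17=rpe_max is not None and rpe_max > 17.0,
    )


class ThresholdKind(str, enum.Enum):
    VT = "VT"
    RCP = "RCP"


@dataclass(frozen=True)
class ThresholdEstimate:
    kind: ThresholdKind
    breakpoint_vo2: float | None  # in units of x (mL·kg⁻¹·min⁻¹ when x is V̇O2)
    breakpoint_power: float | None
    found: bool
    f_stat: float = float("nan")
    p_value: float = float("nan")


def _two_segment_rss(x: np.ndarray, y: np.ndarray, c: float) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), beta


def detect_breakpoint(
    x: np.ndarray,
    y: np.ndarray,
    kind: ThresholdKind | str = ThresholdKind.VT,
    *,
    power: np.ndarray | None = None,
    alpha: float = 0.05,
    n_grid: int = 101,
    min_edge_points: int = 3,
) -> ThresholdEstimate:
    """Locate a slope breakpoint in a ventilatory-equivalent curve.

    Fits ``y = b0 + b1·x + b2·(x − c)₊`` by least squares for each
    candidate breakpoint ``c`` on a uniform interior grid and keeps the
    RSS-minimising one. ``found`` is False when the two-segment model does
    not beat the single straight line at the ``alpha`` level of the
    F-test (2 extra parameters).

    ``x`` must be strictly increasing with at least 8 points (typically
    V̇O2 in mL·kg⁻¹·min⁻¹); ``y`` is the ventilatory equivalent
    (V̇E/V̇O2 for VT, V̇E/V̇CO2 for RCP). When ``power`` is supplied the
    breakpoint is also mapped to watts by interpolation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kind = ThresholdKind(kind)
    if x.size < 8 or y.size != x.size:
        raise ValueError("need >= 8 (x, y) points with matching lengths")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")

    n = x.size
    # single-line fit
    X1 = np.column_stack([np.ones_like(x), x])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ beta1) ** 2))
    y_scale = float(np.sum((y - y.mean()) ** 2))
    if rss1 <= 1e-12 * max(y_scale, 1e-12):
        # the single line already fits to numerical precision: no breakpoint
        return ThresholdEstimate(kind, None, None, False)

    lo, hi = x[min_edge_points - 1], x[n - min_edge_points]
    candidates = np.linspace(lo, hi, n_grid)
    rss_best, c_best = np.inf, None
    for c in candidates:
        rss, _ = _two_segment_rss(x, y, c)
        if rss < rss_best:
            rss_best, c_best = rss, float(c)

    scale = max(rss1, 1e-300)
    if rss_best >= rss1 or (rss1 - rss_best) / scale < 1e-12:
        return ThresholdEstimate(kind, None, None, False)
    df_den = n - 4
    if rss_best <= 1e-12 * max(1.0, float(y @ y)):
        f, p = float("inf"), 0.0  # noiseless piecewise data
    else:
        f = ((rss1 - rss_best) / 2.0) / (rss_best / df_den)
        p = float(stats.f.sf(f, 2, df_den))
    found = p <= alpha
    bp_power = None
    if power is not None and found:
        bp_power = float(np.interp(c_best, x, np.asarray(power, dtype=float)))
    return ThresholdEstimate(
        kind,
        c_best if found else None,
        bp_power,
        found,
        f_stat=f,
        p_value=p,
    )


def fraction_of_vo2max(value: float, vo2max: float) -> float:
    """Express a V̇O2 (mL·kg⁻¹·min⁻¹) as a percentage of V̇O2max,
    rounded to one decimal."""
    if vo2max <= 0:
        raise ValueError("vo2max must be positive")
    return round(100.0 * value / vo2max, 1)


@dataclass(frozen=True)
class CuffPrescription:
    """Session cuff pressure as a fraction of the maximal arterial
    occlusion pressure (AOP), rounded to integer mmHg."""

    aop: float
    fraction: float
    target: int


def occlusion_target(aop: float, fraction: float = 0.8) -> CuffPrescription:
    """Cuff pressure prescription: ``round(fraction × aop)`` mmHg."""
    if aop <= 0:
        raise ValueError("arterial occlusion pressure must be positive")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return CuffPrescription(aop, fraction, int(round(fraction * aop)))


def power_at_vo2(
    vo2: np.ndarray, power: np.ndarray, target_vo2: float
) -> float:
    """Power (W) at a target V̇O2 from a least-squares V̇O2–power line.

    Used to prescribe the constant-load intensity (e.g. 40% of V̇O2max)
    from a subject's incremental test; unanchored to any published
    per-subject mapping.
    """
    vo2 = np.asarray(vo2, dtype=float)
    power = np.asarray(power, dtype=float)
    if vo2.size < 2:
        raise ValueError("need >= 2 points")
    slope, intercept = np.polyfit(power, vo2, 1)
    if slope == 0:
        raise ValueError("degenerate V̇O2–power relationship")
    return float((target_vo2 - intercept) / slope)
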