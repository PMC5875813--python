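"""Mono-exponential V̇O2 off-kinetics and the anaerobic alactic O2 equivalent.

After constant-load exercise, oxygen uptake decays from an end-exercise
plateau back toward rest. The fast component of this excess post-exercise
oxygen consumption (EPOC) is modelled as

    V̇O2(t) = baseline + A1                          for t < td
    V̇O2(t) = baseline + A1 · exp(−(t − td)/τ1)      for t ≥ td

with amplitude ``A1`` (L·min⁻¹), time constant ``τ1`` (min) and time delay
``td`` (min). The O2 volume stored in the fast component, A1·τ1 (L), is
the classical estimate of the anaerobic alactic (phosphocreatine)
contribution to the preceding exercise.

Fitting is nonlinear least squares over the first ``fit_window`` minutes
of recovery (default 10 min), multistarted over a fixed grid of initial
values so the reported solution is the best of all converged starts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .gasex_io import BreathSeries, Phase, ValidationError

__all__ = ["RecoveryFit", "FitError", "predict_vo2", "fit_off_kinetics", "alactic_volume"]

# bounds: baseline [0, 2] L·min⁻¹, A1 [0, 10] L·min⁻¹, τ1 (0.05, 10] min, td [0, 2] min
_LOWER = np.array([0.0, 0.0, 0.05, 0.0])
_UPPER = np.array([2.0, 10.0, 10.0, 2.0])


class FitError(RuntimeError):
    """No multistart converged; carries the best attempt, if any."""

    def __init__(self, message: str, best: "RecoveryFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class RecoveryFit:
    """Fitted off-kinetics parameters with goodness of fit.

    Units: ``baseline``, ``a1`` in L·min⁻¹; ``tau1``, ``td`` in min;
    ``rss`` in (L·min⁻¹)².
    """

    baseline: float
    a1: float
    tau1: float
    td: float
    rss: float = 0.0
    n_breaths: int = 0

    def __post_init__(self) -> None:
        if self.a1 < 0:
            raise ValueError("a1 must be >= 0")
        if self.tau1 <= 0:
            raise ValueError("tau1 must be > 0")
        if self.td < 0:
            raise ValueError("td must be >= 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def _model(t: np.ndarray, baseline: float, a1: float, tau1: float, td: float,
           form: str = "decay") -> np.ndarray:
    s = np.maximum(t - td, 0.0)
    if form == "decay":
        return baseline + a1 * np.exp(-s / tau1)
    if form == "printed":
        # literal reading of the published exponent, for sensitivity only
        return baseline + a1 * np.exp(1.0 - s / tau1)
    raise ValueError(f"unknown model form {form!r}")


def predict_vo2(fit: RecoveryFit, t: float | np.ndarray, form: str = "decay") -> float | np.ndarray:
    """Model V̇O2 (L·min⁻¹) at ``t`` minutes after exercise end.

    Before the time delay the curve sits on the end-exercise plateau
    ``baseline + a1``; from ``td`` it decays exponentially to ``baseline``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (minutes since exercise end)")
    out = _model(t_arr, fit.baseline, fit.a1, fit.tau1, fit.td, form=form)
    return float(out) if np.isscalar(t) else out


def _recovery_minutes(recovery: BreathSeries) -> tuple[np.ndarray, np.ndarray]:
    if Phase.RECOVERY in recovery.phases_present:
        rec = recovery.phase_slice(Phase.RECOVERY)
    else:
        raise ValidationError("series contains no recovery phase")
    t0 = rec.t[0]
    return (rec.t - t0) / 60.0, rec.vo2


def fit_off_kinetics(
    recovery: BreathSeries,
    fit_window: float = 10.0,
    seed: int | None = None,
    *,
    form: str = "decay",
    coverage_tol: float = 0.25,
) -> RecoveryFit:
    """Fit the mono-exponential off-kinetics model to recovery breaths.

    Parameters
    ----------
    recovery
        Series containing a recovery phase; only breaths within
        ``fit_window`` minutes of its first breath are used.
    fit_window
        Minutes of recovery data entering the fit (default 10).
    seed
        Seeds the jittered fallback restarts used only if every start of
        the deterministic grid fails.
    form
        ``"decay"`` for the standard exponential decay; ``"printed"``
        selects the alternative exponent ``exp(1 − (t−td)/τ1)``.

    Returns the lowest-RSS converged solution. Raw breaths are fitted
    without smoothing; residuals are unweighted.
    """
    t, y = _recovery_minutes(recovery)
    if t[-1] < fit_window - coverage_tol:
        raise ValidationError(
            f"recovery ({t[-1]:.2f} min) shorter than fit window ({fit_window:g} min)"
        )
    m = t <= fit_window
    t, y = t[m], y[m]
    if t.size < 20:
        raise ValidationError(f"need >= 20 recovery breaths, got {t.size}")

    # data-driven grid of starts
    base0 = float(np.mean(y[t >= max(t[-1] - 2.0, 0.0)]))
    a1_ref = float(np.mean(y[t <= 0.5]) - base0)
    a1_ref = max(a1_ref, 0.05)
    base0 = float(np.clip(base0, _LOWER[0], _UPPER[0]))
    starts = [
        np.array([base0, np.clip(f * a1_ref, 1e-3, 10.0), tau, td])
        for f, tau, td in itertools.product((0.25, 1.0, 2.0), (0.3, 0.75, 1.5), (0.0, 0.25, 0.5))
    ]

    def resid(p: np.ndarray) -> np.ndarray:
        return _model(t, *p, form=form) - y

    def jac(p: np.ndarray) -> np.ndarray:
        baseline, a1, tau1, td = p
        s = np.maximum(t - td, 0.0)
        if form == "decay":
            e = np.exp(-s / tau1)
        else:
            e = np.exp(1.0 - s / tau1)
        J = np.empty((t.size, 4))
        J[:, 0] = 1.0
        J[:, 1] = e
        J[:, 2] = a1 * e * s / tau1**2
        J[:, 3] = np.where(t > td, a1 * e / tau1, 0.0)
        return J

    best: RecoveryFit | None = None

    def try_start(x0: np.ndarray) -> None:
        nonlocal best
        x0 = np.clip(x0, _LOWER + 1e-12, _UPPER - 1e-12)
        try:
            sol = least_squares(
                resid, x0, jac=jac, bounds=(_LOWER, _UPPER), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:
            return
        if not sol.success:
            return
        rss = float(np.sum(sol.fun**2))
        baseline, a1, tau1, td = (float(v) for v in sol.x)
        cand = RecoveryFit(baseline, a1, max(tau1, 1e-9), td, rss, int(t.size))
        # tie-break equal-RSS solutions toward the smaller amplitude
        if best is None or cand.rss < best.rss - 1e-14 or (
            abs(cand.rss - best.rss) <= 1e-14 and cand.a1 < best.a1
        ):
            best = cand

    for x0 in starts:
        try_start(x0)

    if best is None:
        rng = np.random.default_rng(0 if seed is None else seed)
        for _ in range(20):
            jittered = starts[len(starts) // 2] * rng.uniform(0.5, 1.5, size=4)
            try_start(jittered)

    if best is None:
        raise FitError("off-kinetics fit failed to converge from every start", best=None)
    return best


def alactic_volume(fit: RecoveryFit) -> float:
    """Anaerobic alactic O2 equivalent (L): amplitude × time constant.

    Equals the area between the fitted recovery curve and its baseline
    from ``td`` to infinity.
    """
    return fit.a1 * fit.tau1
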