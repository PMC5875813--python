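"""Energy-system partition of a constant-load cycling session.

Three contributions are estimated from a session's gas exchange and
blood-lactate samples:

* **aerobic** — area under exercise V̇O2 above the resting baseline over
  the declared exercise duration (default 30 min);
* **anaerobic alactic** — fast-component EPOC volume A1·τ1 from the
  mono-exponential off-kinetics fit (:mod:`ergo.kinetics`);
* **anaerobic lactic** — net blood-lactate accumulation (peak
  post-exercise minus pre-exercise) converted at 3 mL O2·kg⁻¹ body mass
  per mmol·L⁻¹.

Total energy expenditure is the sum of the three O2 volumes, convertible
to kJ with a caloric equivalent (default 20.92 kJ·L⁻¹ O2 ≈ 5 kcal·L⁻¹).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics
from .gasex_io import BreathSeries, Condition, Phase, ValidationError, baseline_vo2

__all__ = [
    "LactateLabel",
    "LactateSample",
    "LactateProfile",
    "EnergyPartition",
    "EnergeticsWarning",
    "StageError",
    "read_lactate_csv",
    "write_lactate_csv",
    "aerobic_volume",
    "net_lactate",
    "lactic_volume",
    "o2_volume_to_energy",
    "partition_session",
    "DEFAULT_CALORIC_EQUIV_KJ_PER_L",
    "ML_O2_PER_KG_PER_MMOL",
]

#: kJ released per litre of O2 consumed (≈5 kcal·L⁻¹); configurable everywhere.
DEFAULT_CALORIC_EQUIV_KJ_PER_L = 20.92

#: O2 equivalent of net lactate accumulation: 3 mL O2 per kg body mass per mmol·L⁻¹.
ML_O2_PER_KG_PER_MMOL = 3.0


class EnergeticsWarning(UserWarning):
    """A physically questionable but recoverable situation (negative net
    values clamped or flagged)."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage} stage failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


class LactateLabel(str, enum.Enum):
    """Sampling schedule: pre-exercise, 15 min into exercise, immediately
    and 3/5/7 min post-exercise, and 15 min into recovery."""

    PRE = "pre"
    EX15 = "ex15"
    POST0 = "post0"
    POST3 = "post3"
    POST5 = "post5"
    POST7 = "post7"
    REC15 = "rec15"


POST_LABELS: tuple[LactateLabel, ...] = (
    LactateLabel.POST0,
    LactateLabel.POST3,
    LactateLabel.POST5,
    LactateLabel.POST7,
)


@dataclass(frozen=True)
class LactateSample:
    """One earlobe capillary sample: ``t`` in minutes relative to exercise
    start, concentration in mmol·L⁻¹."""

    label: LactateLabel
    t: float
    conc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", LactateLabel(self.label))
        if self.conc < 0:
            raise ValueError("lactate concentration must be >= 0")


@dataclass
class LactateProfile:
    samples: list[LactateSample]
    subject_id: str = ""
    condition: Condition = Condition.LIE

    def __post_init__(self) -> None:
        if isinstance(self.condition, str):
            self.condition = Condition(self.condition)
        labels = [s.label for s in self.samples]
        if labels.count(LactateLabel.PRE) != 1:
            raise ValidationError("profile must contain exactly one 'pre' sample")
        if not any(l in POST_LABELS for l in labels):
            raise ValidationError("profile must contain at least one post-exercise sample")

    def __getitem__(self, label: LactateLabel | str) -> LactateSample:
        label = LactateLabel(label)
        for s in self.samples:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def pre(self) -> float:
        return self[LactateLabel.PRE].conc

    @property
    def peak_post(self) -> float:
        return max(s.conc for s in self.samples if s.label in POST_LABELS)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label.value for s in self.samples],
                "time_min": [s.t for s in self.samples],
                "lactate_mmol_l": [s.conc for s in self.samples],
            }
        )


def read_lactate_csv(
    path: str | Path,
    *,
    subject_id: str = "",
    condition: Condition | str = Condition.LIE,
) -> LactateProfile:
    """Read ``label, time_min, lactate_mmol_l`` rows into a profile."""
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for c in ("label", "time_min", "lactate_mmol_l"):
        if c not in df.columns:
            raise ValidationError(f"lactate CSV missing column {c!r}")
    samples = [
        LactateSample(LactateLabel(str(r.label).strip()), float(r.time_min), float(r.lactate_mmol_l))
        for r in df.itertuples()
    ]
    return LactateProfile(samples, subject_id=subject_id, condition=Condition(condition))


def write_lactate_csv(profile: LactateProfile, path: str | Path) -> None:
    profile.to_dataframe().to_csv(path, index=False, float_format="%.4f")


@dataclass(frozen=True)
class EnergyPartition:
    """O2 volumes (L) per energy system, their exact sum, and the energy
    conversion. ``flags`` records clamped or negative intermediate values."""

    aerobic_l: float
    alactic_l: float
    lactic_l: float
    total_l: float
    total_kj: float
    body_mass: float
    caloric_equiv: float = DEFAULT_CALORIC_EQUIV_KJ_PER_L
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "aerobic_l": round(self.aerobic_l, 3),
            "alactic_l": round(self.alactic_l, 3),
            "lactic_l": round(self.lactic_l, 3),
            "total_l": round(self.total_l, 3),
            "total_kj": round(self.total_kj, 1),
            "body_mass_kg": self.body_mass,
            "caloric_equiv_kj_per_l": self.caloric_equiv,
            "flags": list(self.flags),
        }


def aerobic_volume(
    series: BreathSeries,
    baseline: float,
    duration: float = 30.0,
    *,
    coverage_tol: float = 15.0,
) -> float:
    """Aerobic O2 volume (L): exercise V̇O2 area minus baseline × duration.

    Exercise V̇O2 is linearly interpolated to a 1 s grid anchored at the
    first exercise breath and integrated by the trapezoidal rule over
    ``duration`` minutes; the resting baseline (L·min⁻¹) times the
    duration is subtracted. A negative result (V̇O2 below baseline) is
    returned as-is with an :class:`EnergeticsWarning`.
    """
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    ex = series.phase_slice(Phase.EXERCISE)
    span = ex.t[-1] - ex.t[0]
    dur_s = duration * 60.0
    if span < dur_s - coverage_tol:
        raise ValidationError(
            f"exercise phase ({span:.0f} s) shorter than duration ({dur_s:.0f} s)"
        )
    grid = np.arange(0.0, dur_s + 0.5, 1.0)
    vo2 = np.interp(grid, ex.t - ex.t[0], ex.vo2)  # edge-clamped
    gross_l = float(np.trapezoid(vo2, grid)) / 60.0
    net = gross_l - baseline * duration
    if net < 0:
        warnings.warn(
            f"exercise V̇O2 below baseline: net aerobic volume {net:.3f} L",
            EnergeticsWarning,
            stacklevel=2,
        )
    return net


def net_lactate(profile: LactateProfile) -> float:
    """Net lactate accumulation [La⁻]_net (mmol·L⁻¹): peak of the
    post-exercise samples minus the pre-exercise concentration."""
    return profile.peak_post - profile.pre


def lactic_volume(
    delta_la: float,
    body_mass: float,
    *,
    ml_per_kg_per_mmol: float = ML_O2_PER_KG_PER_MMOL,
    clamp_negative: bool = True,
) -> float:
    """Anaerobic lactic O2 equivalent (L) of a net lactate accumulation.

    1 mmol·L⁻¹ of net accumulation is equivalent to 3 mL O2 per kg body
    mass. Negative ``delta_la`` is clamped to 0 with a warning (set
    ``clamp_negative=False`` to propagate the negative volume).
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    if delta_la < 0 and clamp_negative:
        warnings.warn(
            f"negative net lactate ({delta_la:.3f} mmol/L) clamped to 0",
            EnergeticsWarning,
            stacklevel=2,
        )
        return 0.0
    return delta_la * ml_per_kg_per_mmol * body_mass / 1000.0


def o2_volume_to_energy(volume: float, caloric_equiv: float = DEFAULT_CALORIC_EQUIV_KJ_PER_L) -> float:
    """Convert an O2 volume (L) to energy (kJ)."""
    if caloric_equiv <= 0:
        raise ValueError("caloric equivalent must be positive")
    return volume * caloric_equiv


@dataclass(frozen=True)
class SessionReport:
    """Full partition of one session with fitted kinetics and the
    intermediate quantities each stage produced."""

    partition: EnergyPartition
    fit: kinetics.RecoveryFit
    baseline_l_min: float
    net_lactate_mmol: float
    intermediates: dict = field(default_factory=dict)


def partition_session(
    series: BreathSeries,
    profile: LactateProfile,
    body_mass: float,
    *,
    duration: float = 30.0,
    baseline_window: float = 120.0,
    fit_window: float = 10.0,
    caloric_equiv: float = DEFAULT_CALORIC_EQUIV_KJ_PER_L,
    seed: int | None = None,
    clamp_negative_lactate: bool = True,
) -> SessionReport:
    """Run the whole partition for one session.

    Orchestrates baseline estimation → aerobic integration → off-kinetics
    fit → alactic volume → net lactate → lactic volume, then assembles an
    :class:`EnergyPartition` whose total is the exact component sum. Stage
    failures are re-raised as :class:`StageError` naming the stage.
    """
    if body_mass <= 0:
        raise StageError("input", ValueError("body mass must be positive"))
    if profile is None:
        raise StageError("lactate", ValueError("lactate profile missing"))
    flags: list[str] = []

    try:
        base = baseline_vo2(series, window=baseline_window)
    except Exception as e:  # noqa: BLE001 - stage identification
        raise StageError("baseline", e) from e

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", EnergeticsWarning)
            aerobic = aerobic_volume(series, base, duration=duration)
        if caught:
            flags.append("negative_aerobic")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("aerobic", e) from e

    try:
        fit = kinetics.fit_off_kinetics(series, fit_window=fit_window, seed=seed)
        alactic = kinetics.alactic_volume(fit)
    except Exception as e:  # noqa: BLE001
        raise StageError("kinetics", e) from e

    try:
        d_la = net_lactate(profile)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", EnergeticsWarning)
            lactic = lactic_volume(d_la, body_mass, clamp_negative=clamp_negative_lactate)
        if caught:
            flags.append("negative_net_lactate_clamped")
    except Exception as e:  # noqa: BLE001
        raise StageError("lactate", e) from e

    total = aerobic + alactic + lactic
    partition = EnergyPartition(
        aerobic_l=aerobic,
        alactic_l=alactic,
        lactic_l=lactic,
        total_l=total,
        total_kj=o2_volume_to_energy(total, caloric_equiv),
        body_mass=body_mass,
        caloric_equiv=caloric_equiv,
        flags=tuple(flags),
    )
    intermediates = {
        "baseline_l_min": base,
        "net_lactate_mmol_l": d_la,
        "recovery_fit": {
            "baseline": fit.baseline,
            "a1": fit.a1,
            "tau1": fit.tau1,
            "td": fit.td,
            "rss": fit.rss,
            "n_breaths": fit.n_breaths,
        },
        "duration_min": duration,
        "fit_window_min": fit_window,
    }
    return SessionReport(partition, fit, base, d_la, intermediates)
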