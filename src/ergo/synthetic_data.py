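"""Synthetic crossover-trial generator.

Forward model of one experimental session — ~5 min seated rest, 30 min
constant-load cycling at 40% V̇O2max, 15 min recovery — producing
breath-by-breath gas exchange with mono-exponential on/off V̇O2 kinetics
and Gaussian breath noise, plus the seven-point capillary lactate
schedule. A crossover trial pairs each simulated subject's LIE session
with an LIE-BFR session in which blood-flow restriction shifts steady-
state V̇O2, peak lactate, HR and V̇E by configurable amounts while the
alactic (phosphocreatine) stores are left untouched.

Population defaults reproduce the studied group (sedentary young men:
body mass 82.8 ± 12.6 kg, V̇O2max 33.4 ± 4.6 mL·kg⁻¹·min⁻¹, cycling at
70 ± 9.8 W); condition-effect defaults are calibrated so that group mean
pre and peak lactate land on the observed values in both arms. Every
draw is reproducible from a single integer seed: the trial seed expands
into per-subject, per-condition session seeds by a fixed arithmetic rule
recorded in the manifest, so any single session can be regenerated in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .energetics import LactateLabel, LactateProfile, LactateSample, write_lactate_csv
from .gasex_io import BreathSeries, Condition, Phase, write_breath_csv

__all__ = [
    "SubjectParams",
    "PopulationConfig",
    "ConditionEffects",
    "Durations",
    "SessionTruth",
    "TrialDataset",
    "make_population",
    "simulate_breath_series",
    "simulate_lactate_profile",
    "simulate_crossover_trial",
    "write_trial",
    "load_trial",
]

#: cycling economy used to map power to steady-state ΔV̇O2 (mL·min⁻¹·W⁻¹)
O2_COST_ML_PER_MIN_PER_W = 10.8


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiological parameters driving the forward model."""

    subject_id: str
    body_mass: float  # kg
    vo2max: float  # mL·kg⁻¹·min⁻¹
    age: float  # years
    rest_vo2: float  # L·min⁻¹
    power_w: float  # constant-load power at ~40% V̇O2max
    tau_on: float  # min, on-kinetics time constant
    a1: float  # L·min⁻¹, off-kinetics fast-component amplitude
    tau1: float  # min, off-kinetics time constant
    td: float  # min, off-kinetics time delay
    la_pre: float  # mmol·L⁻¹ resting lactate
    la_rise: float  # mmol·L⁻¹ net accumulation without BFR
    hr_rest: float  # bpm
    hr_amp: float  # bpm exercise rise
    ve_rest: float  # L·min⁻¹
    ve_amp: float  # L·min⁻¹ exercise rise

    def __post_init__(self) -> None:
        for name in ("body_mass", "vo2max", "rest_vo2", "power_w", "tau_on",
                     "a1", "tau1", "la_pre", "hr_rest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 20.0 <= self.vo2max <= 60.0:
            raise ValueError("vo2max outside the plausible [20, 60] range")

    @property
    def delta_vo2_ss(self) -> float:
        """Steady-state exercise ΔV̇O2 above rest (L·min⁻¹) from the
        cycling-economy constant."""
        return O2_COST_ML_PER_MIN_PER_W * self.power_w / 1000.0


@dataclass(frozen=True)
class PopulationConfig:
    """Truncated-normal moments for subject sampling (mean, SD, lo, hi)."""

    body_mass: tuple = (82.8, 12.6, 50.0, 130.0)
    vo2max: tuple = (33.4, 4.6, 20.0, 60.0)
    age: tuple = (24.5, 4.0, 18.0, 30.0)
    rest_vo2_ml_kg: tuple = (3.5, 0.3, 2.5, 4.8)  # scaled by mass on draw
    power_w: tuple = (70.0, 9.8, 40.0, 110.0)
    tau_on: tuple = (0.55, 0.08, 0.30, 1.20)
    a1_frac: tuple = (0.95, 0.08, 0.60, 1.30)  # fraction of ΔV̇O2_ss
    tau1: tuple = (0.75, 0.10, 0.30, 1.50)
    td: tuple = (0.10, 0.03, 0.0, 0.50)
    la_pre: tuple = (1.25, 0.35, 0.40, 3.0)
    la_rise: tuple = (0.65, 0.25, 0.10, 2.0)
    hr_rest: tuple = (68.0, 7.0, 45.0, 95.0)
    hr_amp: tuple = (40.0, 8.0, 20.0, 70.0)
    ve_rest: tuple = (10.0, 1.5, 6.0, 16.0)
    ve_amp: tuple = (18.0, 4.0, 8.0, 35.0)


@dataclass(frozen=True)
class ConditionEffects:
    """Additive blood-flow-restriction shifts and measurement noise.

    ``d_*`` fields apply only to LIE-BFR sessions; ``noise_*`` are
    per-breath / per-sample Gaussian SDs; ``session_sd_*`` are day-to-day
    random offsets drawn once per session (both arms), giving the
    within-subject between-session variability a crossover needs.
    """

    d_la_peak: float = 1.0  # mmol·L⁻¹ extra net lactate under BFR
    d_vo2_ss: float = 0.05  # L·min⁻¹ extra steady-state V̇O2 under BFR
    d_hr: float = 8.0  # bpm extra exercise HR rise under BFR
    d_ve: float = 5.0  # L·min⁻¹ extra exercise V̇E rise under BFR
    noise_vo2: float = 0.03  # L·min⁻¹ breath SD
    noise_la: float = 0.12  # mmol·L⁻¹ sample SD
    noise_hr: float = 2.0
    noise_ve: float = 1.0
    session_sd_vo2: float = 0.02  # L·min⁻¹ SD of steady-state offset
    session_sd_a1: float = 0.02  # L·min⁻¹ SD of recovery amplitude
    session_sd_tau1: float = 0.03  # min SD of recovery time constant
    session_sd_hr: float = 2.0
    session_sd_ve: float = 1.5
    session_sd_la: float = 0.15  # mmol·L⁻¹ SD of session lactate-rise offset

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name.startswith(("noise_", "session_sd_")) and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def null(self) -> "ConditionEffects":
        """Copy with all BFR shifts zeroed (noise retained)."""
        return replace(self, d_la_peak=0.0, d_vo2_ss=0.0, d_hr=0.0, d_ve=0.0)


@dataclass(frozen=True)
class Durations:
    """Phase durations in seconds (rest, exercise, recovery)."""

    rest_s: float = 300.0
    exercise_s: float = 1800.0
    recovery_s: float = 900.0

    def __post_init__(self) -> None:
        if min(self.rest_s, self.exercise_s, self.recovery_s) <= 0:
            raise ValueError("durations must be positive")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int | None = None) -> np.ndarray | float:
    """Truncation by resampling (moments are configured well inside the
    bounds, so acceptance is high)."""
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    return float(out[0]) if size is None else out


def make_population(
    n: int, seed: int, config: PopulationConfig | None = None
) -> list[SubjectParams]:
    """Draw ``n`` subjects from the configured population moments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        mass = _trunc_normal(rng, *cfg.body_mass)
        vo2max = _trunc_normal(rng, *cfg.vo2max)
        power = _trunc_normal(rng, *cfg.power_w)
        delta_ss = O2_COST_ML_PER_MIN_PER_W * power / 1000.0
        subjects.append(
            SubjectParams(
                subject_id=f"S{i + 1:02d}",
                body_mass=mass,
                vo2max=vo2max,
                age=_trunc_normal(rng, *cfg.age),
                rest_vo2=_trunc_normal(rng, *cfg.rest_vo2_ml_kg) * mass / 1000.0,
                power_w=power,
                tau_on=_trunc_normal(rng, *cfg.tau_on),
                a1=delta_ss * _trunc_normal(rng, *cfg.a1_frac),
                tau1=_trunc_normal(rng, *cfg.tau1),
                td=_trunc_normal(rng, *cfg.td),
                la_pre=_trunc_normal(rng, *cfg.la_pre),
                la_rise=_trunc_normal(rng, *cfg.la_rise),
                hr_rest=_trunc_normal(rng, *cfg.hr_rest),
                hr_amp=_trunc_normal(rng, *cfg.hr_amp),
                ve_rest=_trunc_normal(rng, *cfg.ve_rest),
                ve_amp=_trunc_normal(rng, *cfg.ve_amp),
            )
        )
    return subjects


@dataclass(frozen=True)
class SessionTruth:
    """Ground-truth quantities behind one simulated session."""

    baseline_l_min: float
    delta_ss_l_min: float  # session steady-state ΔV̇O2 incl. BFR and session offset
    a1: float
    tau1: float
    td: float
    net_lactate_mmol: float
    aerobic_l: float
    alactic_l: float
    lactic_l: float

    @property
    def total_l(self) -> float:
        return self.aerobic_l + self.alactic_l + self.lactic_l


def _breath_times(rng: np.random.Generator, start: float, end: float,
                  interval: float = 3.0, jitter: float = 0.5) -> np.ndarray:
    """Breath timestamps: first breath at phase start, then ~3 s apart
    with uniform jitter."""
    times = [start]
    t = start
    while True:
        t += interval + rng.uniform(-jitter, jitter)
        if t >= end:
            break
        times.append(t)
    return np.array(times)


def _session_draws(subject: SubjectParams, effects: ConditionEffects,
                   condition: Condition, rng: np.random.Generator) -> dict:
    bfr = condition == Condition.LIE_BFR
    return {
        "delta_ss": subject.delta_vo2_ss
        + (effects.d_vo2_ss if bfr else 0.0)
        + rng.normal(0.0, effects.session_sd_vo2),
        "a1": max(subject.a1 + rng.normal(0.0, effects.session_sd_a1), 0.05),
        "tau1": max(subject.tau1 + rng.normal(0.0, effects.session_sd_tau1), 0.15),
        "hr_amp": subject.hr_amp + (effects.d_hr if bfr else 0.0)
        + rng.normal(0.0, effects.session_sd_hr),
        "ve_amp": subject.ve_amp + (effects.d_ve if bfr else 0.0)
        + rng.normal(0.0, effects.session_sd_ve),
        "la_rise": max(
            subject.la_rise + (effects.d_la_peak if bfr else 0.0)
            + rng.normal(0.0, effects.session_sd_la),
            0.0,
        ),
    }


def simulate_breath_series(
    subject: SubjectParams,
    effects: ConditionEffects | None = None,
    condition: Condition | str = Condition.LIE,
    durations: Durations | None = None,
    seed: int = 0,
    *,
    return_truth: bool = False,
):
    """Forward-simulate one session's breath-by-breath series.

    Rest sits at the subject's resting V̇O2; exercise rises
    mono-exponentially (τ_on) to a steady state set by the cycling
    economy (plus the BFR shift and a session offset); recovery follows
    the plateau-then-decay off-kinetics model with the subject's
    (A1, τ1, td) — deliberately unaffected by BFR, mirroring unchanged
    phosphocreatine stores. HR and V̇E are generated analogously. All
    channels share breath timestamps (~3 s ± 0.5 s apart) and carry
    Gaussian noise.
    """
    effects = effects or ConditionEffects()
    durations = durations or Durations()
    condition = Condition(condition)
    rng = np.random.default_rng(seed)
    s = _session_draws(subject, effects, condition, rng)

    t_ex = durations.rest_s
    t_rec = durations.rest_s + durations.exercise_s
    t_end = t_rec + durations.recovery_s
    t_rest = _breath_times(rng, 0.0, t_ex)
    t_exer = _breath_times(rng, t_ex, t_rec)
    t_reco = _breath_times(rng, t_rec, t_end)
    t = np.concatenate([t_rest, t_exer, t_reco])
    phase = np.array(
        [Phase.REST.value] * t_rest.size
        + [Phase.EXERCISE.value] * t_exer.size
        + [Phase.RECOVERY.value] * t_reco.size
    )

    def profile(amp_rest: float, amp: float, tau_on_min: float,
                tau_off_min: float, td_min: float = 0.0) -> np.ndarray:
        out = np.full(t.shape, amp_rest, dtype=float)
        m_ex = phase == Phase.EXERCISE.value
        te = (t[m_ex] - t_ex) / 60.0
        out[m_ex] = amp_rest + amp * (1.0 - np.exp(-te / tau_on_min))
        m_rec = phase == Phase.RECOVERY.value
        tr = (t[m_rec] - t_rec) / 60.0
        sdec = np.maximum(tr - td_min, 0.0)
        out[m_rec] = amp_rest + amp * np.where(tr < td_min, 1.0, np.exp(-sdec / tau_off_min))
        return out

    vo2 = profile(subject.rest_vo2, s["delta_ss"], subject.tau_on, s["tau1"], 0.0)
    # recovery uses the subject's off-kinetics parameters, not the exercise amplitude
    m_rec = phase == Phase.RECOVERY.value
    tr = (t[m_rec] - t_rec) / 60.0
    sdec = np.maximum(tr - subject.td, 0.0)
    vo2[m_rec] = subject.rest_vo2 + s["a1"] * np.where(
        tr < subject.td, 1.0, np.exp(-sdec / s["tau1"])
    )
    vo2 = np.clip(vo2 + rng.normal(0.0, effects.noise_vo2, size=t.shape), 0.0, None)

    vco2 = np.clip(0.9 * vo2 + rng.normal(0.0, effects.noise_vo2, size=t.shape), 0.0, None)
    hr = profile(subject.hr_rest, s["hr_amp"], subject.tau_on * 1.3, 1.5)
    hr = np.clip(hr + rng.normal(0.0, effects.noise_hr, size=t.shape), 30.0, 240.0)
    ve = profile(subject.ve_rest, s["ve_amp"], subject.tau_on * 1.1, 1.0)
    ve = np.clip(ve + rng.normal(0.0, effects.noise_ve, size=t.shape), 0.0, None)

    series = BreathSeries(
        t=t, vo2=vo2, vco2=vco2, ve=ve, hr=hr, phase=phase,
        subject_id=subject.subject_id, condition=condition,
    )
    if not return_truth:
        return series

    d_min = durations.exercise_s / 60.0
    aerobic_true = s["delta_ss"] * (
        d_min - subject.tau_on * (1.0 - np.exp(-d_min / subject.tau_on))
    )
    truth = SessionTruth(
        baseline_l_min=subject.rest_vo2,
        delta_ss_l_min=s["delta_ss"],
        a1=s["a1"],
        tau1=s["tau1"],
        td=subject.td,
        net_lactate_mmol=s["la_rise"],
        aerobic_l=aerobic_true,
        alactic_l=s["a1"] * s["tau1"],
        lactic_l=s["la_rise"] * 3.0 * subject.body_mass / 1000.0,
    )
    return series, truth


# fraction of the session lactate rise present at each sampling point;
# immediate-post is the peak and recovery decays back toward rest
_LA_SCHEDULE: tuple[tuple[LactateLabel, float, float], ...] = (
    (LactateLabel.PRE, -5.0, 0.0),
    (LactateLabel.EX15, 15.0, 1.0),
    (LactateLabel.POST0, 30.0, 1.0),
    (LactateLabel.POST3, 33.0, 0.85),
    (LactateLabel.POST5, 35.0, 0.72),
    (LactateLabel.POST7, 37.0, 0.62),
    (LactateLabel.REC15, 45.0, 0.20),
)


def simulate_lactate_profile(
    subject: SubjectParams,
    effects: ConditionEffects | None = None,
    condition: Condition | str = Condition.LIE,
    seed: int = 0,
    *,
    session_la_rise: float | None = None,
) -> LactateProfile:
    """Simulate the seven-sample lactate schedule.

    Concentrations rise from the subject's resting level toward a
    session-specific peak (resting + rise, where BFR adds ``d_la_peak``
    to the rise) reached immediately post-exercise, then decay by 15 min
    of recovery back toward rest. Sample noise is Gaussian; values are
    clamped at 0.
    """
    effects = effects or ConditionEffects()
    condition = Condition(condition)
    rng = np.random.default_rng(seed)
    if session_la_rise is None:
        session_la_rise = _session_draws(subject, effects, condition, rng)["la_rise"]
    samples = []
    for label, t_min, frac in _LA_SCHEDULE:
        conc = subject.la_pre + frac * session_la_rise + rng.normal(0.0, effects.noise_la)
        samples.append(LactateSample(label, t_min, max(conc, 0.0)))
    return LactateProfile(samples, subject_id=subject.subject_id, condition=condition)


def _session_seed(trial_seed: int, subject_index: int, condition: Condition) -> int:
    cond_index = 0 if condition == Condition.LIE else 1
    return (trial_seed * 100_003 + subject_index * 211 + cond_index * 7 + 1) % (2**31)


@dataclass
class TrialDataset:
    """All sessions of one simulated crossover trial plus provenance."""

    subjects: list[SubjectParams]
    series: dict  # (subject_id, Condition) -> BreathSeries
    profiles: dict  # (subject_id, Condition) -> LactateProfile
    truths: dict = field(default_factory=dict)  # (subject_id, Condition) -> SessionTruth
    effects: ConditionEffects = field(default_factory=ConditionEffects)
    durations: Durations = field(default_factory=Durations)
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.subjects)

    def session(self, subject_id: str, condition: Condition | str):
        key = (subject_id, Condition(condition))
        return self.series[key], self.profiles[key]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n,
            "conditions": [c.value for c in Condition],
            "effects": asdict(self.effects),
            "durations": asdict(self.durations),
            "subjects": [asdict(s) for s in self.subjects],
            "session_seeds": {
                f"{s.subject_id}:{c.value}": _session_seed(self.seed or 0, i, c)
                for i, s in enumerate(self.subjects)
                for c in Condition
            },
        }


def simulate_crossover_trial(
    n: int = 12,
    effects: ConditionEffects | None = None,
    seed: int = 0,
    *,
    durations: Durations | None = None,
    population: PopulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> TrialDataset:
    """Simulate a full counter-balanced crossover: ``n`` subjects, each
    with one LIE and one LIE-BFR session (breath series + lactate
    profile). The same session seed drives both the breath and lactate
    streams so their shared session lactate rise stays consistent.

    When ``out_dir`` is given the dataset is also written to disk
    (CSV per session plus ``manifest.json``).
    """
    if n < 2:
        raise ValueError("a crossover needs at least 2 subjects")
    effects = effects or ConditionEffects()
    durations = durations or Durations()
    subjects = make_population(n, seed, population)
    series: dict = {}
    profiles: dict = {}
    truths: dict = {}
    for i, subj in enumerate(subjects):
        for cond in Condition:
            s_seed = _session_seed(seed, i, cond)
            ser, truth = simulate_breath_series(
                subj, effects, cond, durations, seed=s_seed, return_truth=True
            )
            prof = simulate_lactate_profile(
                subj, effects, cond, seed=s_seed + 1,
                session_la_rise=truth.net_lactate_mmol,
            )
            key = (subj.subject_id, cond)
            series[key], profiles[key], truths[key] = ser, prof, truth
    ds = TrialDataset(subjects, series, profiles, truths, effects, durations, seed)
    if out_dir is not None:
        write_trial(ds, out_dir)
    return ds


def write_trial(dataset: TrialDataset, out_dir: str | Path) -> Path:
    """Write one breath CSV and one lactate CSV per subject × condition,
    plus a manifest recording every generator parameter and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sid, cond), ser in dataset.series.items():
        write_breath_csv(ser, out / f"breath_{sid}_{cond.value}.csv")
    for (sid, cond), prof in dataset.profiles.items():
        write_lactate_csv(prof, out / f"lactate_{sid}_{cond.value}.csv")
    (out / "manifest.json").write_text(json.dumps(dataset.manifest(), indent=2))
    return out


def load_trial(trial_dir: str | Path) -> TrialDataset:
    """Load a written trial directory back into a :class:`TrialDataset`
    (ground truths are not persisted beyond the manifest parameters)."""
    from .gasex_io import read_breath_csv
    from .energetics import read_lactate_csv

    trial_dir = Path(trial_dir)
    manifest = json.loads((trial_dir / "manifest.json").read_text())
    subjects = [SubjectParams(**s) for s in manifest["subjects"]]
    effects = ConditionEffects(**manifest["effects"])
    durations = Durations(**manifest["durations"])
    series, profiles = {}, {}
    for s in subjects:
        for cond in Condition:
            key = (s.subject_id, cond)
            series[key] = read_breath_csv(
                trial_dir / f"breath_{s.subject_id}_{cond.value}.csv",
                subject_id=s.subject_id, condition=cond,
            )
            profiles[key] = read_lactate_csv(
                trial_dir / f"lactate_{s.subject_id}_{cond.value}.csv",
                subject_id=s.subject_id, condition=cond,
            )
    return TrialDataset(subjects, series, profiles, {}, effects, durations, manifest["seed"])
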