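"""End-to-end crossover-trial analysis.

Runs the energy-system partition on every session of a trial, then the
inferential stage: paired t-tests between conditions for the aerobic,
anaerobic alactic, anaerobic lactic and total energy expenditure, and
condition × time repeated-measures ANOVAs (with per-time Bonferroni post
hocs) for the lactate, HR and V̇E time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crossover_stats as cs
from .energetics import LactateLabel, SessionReport, partition_session
from .gasex_io import Condition, bin_phase_averages
from .synthetic_data import TrialDataset

__all__ = ["TrialAnalysis", "analyze_trial", "COMPONENTS"]

COMPONENTS = ("aerobic_l", "alactic_l", "lactic_l", "total_l", "total_kj")

# Table-style lactate time course: rest, mid-exercise, post-exercise peak,
# late recovery
_LACTATE_TIMEPOINTS = ("pre", "ex15", "peak_post", "rec15")


@dataclass
class TrialAnalysis:
    """Per-session partitions plus the trial-level statistics."""

    reports: dict  # (subject_id, Condition) -> SessionReport
    component_tests: dict  # component name -> PairedTResult
    component_means: dict  # component name -> {"LIE": m, "LIE_BFR": m}
    lactate_anova: cs.RMAnova | None = None
    lactate_posthoc: list = field(default_factory=list)
    hr_anova: cs.RMAnova | None = None
    hr_posthoc: list = field(default_factory=list)
    ve_anova: cs.RMAnova | None = None
    ve_posthoc: list = field(default_factory=list)

    def component_matrix(self, component: str) -> np.ndarray:
        """(n_subjects, 2) array of a component, columns (LIE, LIE_BFR)."""
        sids = sorted({sid for sid, _ in self.reports})
        out = np.empty((len(sids), 2))
        for i, sid in enumerate(sids):
            for j, cond in enumerate((Condition.LIE, Condition.LIE_BFR)):
                p = self.reports[(sid, cond)].partition
                out[i, j] = getattr(p, component) if component != "total_kj" else p.total_kj
        return out


def _lactate_array(trial: TrialDataset) -> np.ndarray:
    """(n, 2, 4) lactate at pre / 15 min exercise / post peak / 15 min
    recovery for both conditions."""
    sids = [s.subject_id for s in trial.subjects]
    out = np.empty((len(sids), 2, len(_LACTATE_TIMEPOINTS)))
    for i, sid in enumerate(sids):
        for j, cond in enumerate((Condition.LIE, Condition.LIE_BFR)):
            prof = trial.profiles[(sid, cond)]
            for k, tp in enumerate(_LACTATE_TIMEPOINTS):
                if tp == "peak_post":
                    out[i, j, k] = prof.peak_post
                else:
                    out[i, j, k] = prof[LactateLabel(tp)].conc
    return out


def _binned_array(trial: TrialDataset, channel: str, window: float = 300.0) -> np.ndarray:
    """(n, 2, n_bins) five-minute means of a channel across all phases."""
    sids = [s.subject_id for s in trial.subjects]
    rows = {}
    n_bins = None
    for sid in sids:
        for cond in (Condition.LIE, Condition.LIE_BFR):
            bins = bin_phase_averages(trial.series[(sid, cond)], channel, window)
            vals = [b.mean_value for b in bins]
            n_bins = len(vals) if n_bins is None else min(n_bins, len(vals))
            rows[(sid, cond)] = vals
    out = np.empty((len(sids), 2, n_bins))
    for i, sid in enumerate(sids):
        for j, cond in enumerate((Condition.LIE, Condition.LIE_BFR)):
            out[i, j, :] = rows[(sid, cond)][:n_bins]
    return out


def analyze_trial(
    trial: TrialDataset,
    *,
    duration: float | None = None,
    fit_window: float = 10.0,
    seed: int | None = None,
    timecourse_stats: bool = True,
) -> TrialAnalysis:
    """Partition every session and run the crossover statistics.

    ``duration`` (min) defaults to the trial's exercise duration;
    ``timecourse_stats=False`` skips the ANOVA stage (partitions and
    component tests only).
    """
    if duration is None:
        duration = trial.durations.exercise_s / 60.0
    fit_window = min(fit_window, trial.durations.recovery_s / 60.0)
    reports: dict = {}
    for s in trial.subjects:
        for cond in (Condition.LIE, Condition.LIE_BFR):
            ser, prof = trial.session(s.subject_id, cond)
            reports[(s.subject_id, cond)] = partition_session(
                ser, prof, s.body_mass,
                duration=duration, fit_window=fit_window, seed=seed,
                baseline_window=min(120.0, trial.durations.rest_s),
            )

    analysis = TrialAnalysis(reports, {}, {})
    for comp in COMPONENTS:
        mat = analysis.component_matrix(comp)
        analysis.component_tests[comp] = cs.paired_t(mat[:, 0], mat[:, 1])
        analysis.component_means[comp] = {
            "LIE": float(mat[:, 0].mean()),
            "LIE_BFR": float(mat[:, 1].mean()),
        }

    if timecourse_stats:
        la = _lactate_array(trial)
        analysis.lactate_anova = cs.rm_anova(la)
        analysis.lactate_posthoc = cs.posthoc_by_time(la)
        for channel, name in (("hr", "hr"), ("ve", "ve")):
            arr = _binned_array(trial, channel)
            setattr(analysis, f"{name}_anova", cs.rm_anova(arr))
            setattr(analysis, f"{name}_posthoc", cs.posthoc_by_time(arr))
    return analysis
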