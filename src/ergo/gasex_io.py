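"""Breath-by-breath gas-exchange containers, CSV I/O and phase summaries.

A session is an ordered sequence of breaths, each time-stamped in seconds
from session start and labelled with one of three contiguous phases:
seated ``rest``, constant-load ``exercise`` and post-exercise ``recovery``.
V̇O2 (and V̇CO2, V̇E) are held in L·min⁻¹ STPD; heart rate in beats·min⁻¹.

The canonical CSV dialect is comma-separated with a header row::

    time_s, vo2_l_min, vco2_l_min, ve_l_min, hr_bpm, phase

where ``phase`` is one of ``rest``, ``exercise``, ``recovery``. Readers
can remap column names and convert from mL·min⁻¹ or mL·kg⁻¹·min⁻¹ on
ingest. HR and V̇E are optional channels and are never imputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Condition",
    "BreathSeries",
    "PhaseAverages",
    "FormatError",
    "ValidationError",
    "EmptyWindowError",
    "read_breath_csv",
    "write_breath_csv",
    "bin_phase_averages",
    "baseline_vo2",
    "DEFAULT_COLUMNS",
]


class Phase(str, enum.Enum):
    REST = "rest"
    EXERCISE = "exercise"
    RECOVERY = "recovery"


PHASE_ORDER: tuple[Phase, ...] = (Phase.REST, Phase.EXERCISE, Phase.RECOVERY)


class Condition(str, enum.Enum):
    """Trial arm: low-intensity endurance exercise without (LIE) or with
    blood-flow restriction (LIE_BFR)."""

    LIE = "LIE"
    LIE_BFR = "LIE_BFR"


class FormatError(ValueError):
    """A file does not follow the expected CSV dialect."""


class ValidationError(ValueError):
    """Data violate a physiological or structural invariant."""


class EmptyWindowError(ValidationError):
    """An averaging window contains no breaths."""


# canonical name -> CSV header
DEFAULT_COLUMNS: dict[str, str] = {
    "t": "time_s",
    "vo2": "vo2_l_min",
    "vco2": "vco2_l_min",
    "ve": "ve_l_min",
    "hr": "hr_bpm",
    "phase": "phase",
}

_CHANNELS = ("vo2", "vco2", "ve", "hr")


@dataclass(frozen=True)
class PhaseAverages:
    """Mean of one channel over one complete window within a phase.

    ``window_start``/``window_end`` are seconds from session start; the
    window is half-open ``[start, end)``.
    """

    phase: Phase
    window_start: float
    window_end: float
    mean_value: float
    channel: str


@dataclass
class BreathSeries:
    """Validated breath-by-breath series for one subject and condition.

    Arrays are aligned per breath. ``vco2``, ``ve`` and ``hr`` may be
    ``None`` (absent channel) or contain NaN for individual breaths.
    """

    t: np.ndarray
    vo2: np.ndarray
    phase: np.ndarray  # array of Phase values (str dtype ok)
    vco2: np.ndarray | None = None
    ve: np.ndarray | None = None
    hr: np.ndarray | None = None
    subject_id: str = ""
    condition: Condition = Condition.LIE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.phase = np.asarray([Phase(p) for p in np.asarray(self.phase)], dtype=object)
        for name in ("vco2", "ve", "hr"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if isinstance(self.condition, str):
            self.condition = Condition(self.condition)
        self._validate()

    def _validate(self) -> None:
        n = self.t.size
        if n == 0:
            raise ValidationError("empty breath series")
        for name in ("vo2", "vco2", "ve", "hr", "phase"):
            v = getattr(self, name)
            if v is not None and v.shape != (n,):
                raise ValidationError(f"channel {name!r} length mismatch")
        if np.any(self.t < 0):
            raise ValidationError("negative timestamps")
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"time not strictly increasing at row {int(bad[0]) + 1} "
                f"(t={self.t[bad[0] + 1]:g} follows t={self.t[bad[0]]:g})"
            )
        for name in ("vo2", "vco2", "ve"):
            v = getattr(self, name)
            if v is not None and np.any(v[~np.isnan(v)] < 0):
                raise ValidationError(f"negative {name} values")
        if self.hr is not None:
            h = self.hr[~np.isnan(self.hr)]
            if h.size and (np.any(h < 20) or np.any(h > 250)):
                raise ValidationError("hr outside [20, 250] bpm")
        # phases: each present phase one contiguous block, rest→exercise→recovery
        order = {p: i for i, p in enumerate(PHASE_ORDER)}
        idx = np.array([order[p] for p in self.phase])
        if np.any(np.diff(idx) < 0):
            raise ValidationError("phases out of rest→exercise→recovery order")
        # contiguity follows from monotone phase index

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def phases_present(self) -> list[Phase]:
        seen: list[Phase] = []
        for p in self.phase:
            if p not in seen:
                seen.append(p)
        return seen

    def phase_mask(self, phase: Phase | str) -> np.ndarray:
        phase = Phase(phase)
        return np.array([p == phase for p in self.phase])

    def phase_slice(self, phase: Phase | str) -> "BreathSeries":
        """Sub-series containing only the given phase."""
        m = self.phase_mask(phase)
        if not m.any():
            raise ValidationError(f"phase {Phase(phase).value!r} absent from series")
        return replace(
            self,
            t=self.t[m],
            vo2=self.vo2[m],
            phase=self.phase[m],
            vco2=None if self.vco2 is None else self.vco2[m],
            ve=None if self.ve is None else self.ve[m],
            hr=None if self.hr is None else self.hr[m],
        )

    def phase_start(self, phase: Phase | str) -> float:
        """Timestamp (s) of the first breath in the phase."""
        m = self.phase_mask(phase)
        if not m.any():
            raise ValidationError(f"phase {Phase(phase).value!r} absent from series")
        return float(self.t[m][0])

    def phase_end(self, phase: Phase | str) -> float:
        """End of the phase: start of the next present phase, or for the
        final phase the last breath time plus the median breath interval."""
        phase = Phase(phase)
        present = self.phases_present
        i = present.index(phase)
        if i + 1 < len(present):
            return self.phase_start(present[i + 1])
        t_last = float(self.t[self.phase_mask(phase)][-1])
        dt = float(np.median(np.diff(self.t))) if len(self) > 1 else 0.0
        return t_last + dt

    def phase_duration(self, phase: Phase | str) -> float:
        return self.phase_end(phase) - self.phase_start(phase)

    def channel(self, name: str) -> np.ndarray:
        if name not in _CHANNELS:
            raise ValueError(f"unknown channel {name!r}; expected one of {_CHANNELS}")
        v = getattr(self, name)
        if v is None:
            raise ValidationError(f"channel {name!r} absent from series")
        return v

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"time_s": self.t, "vo2_l_min": self.vo2}
        for name, col in (("vco2", "vco2_l_min"), ("ve", "ve_l_min"), ("hr", "hr_bpm")):
            v = getattr(self, name)
            if v is not None:
                cols[col] = v
        cols["phase"] = [p.value for p in self.phase]
        return pd.DataFrame(cols)


def _resolve(columns: Sequence[str], column_map: dict[str, str] | None, key: str) -> str | None:
    name = (column_map or {}).get(key, DEFAULT_COLUMNS[key])
    return name if name in columns else None


def read_breath_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    *,
    vo2_units: str = "l_min",
    body_mass: float | None = None,
    subject_id: str = "",
    condition: Condition | str = Condition.LIE,
) -> BreathSeries:
    """Read a breath-by-breath CSV into a validated :class:`BreathSeries`.

    Parameters
    ----------
    column_map
        Optional mapping from canonical names (``t``, ``vo2``, ``vco2``,
        ``ve``, ``hr``, ``phase``) to the file's column headers.
    vo2_units
        ``"l_min"`` (default), ``"ml_min"`` or ``"ml_kg_min"``; the latter
        requires ``body_mass`` (kg). V̇O2/V̇CO2 are converted to L·min⁻¹.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    for key in ("t", "vo2", "phase"):
        if _resolve(df.columns, column_map, key) is None:
            name = (column_map or {}).get(key, DEFAULT_COLUMNS[key])
            raise FormatError(f"required column {name!r} ({key}) missing from {path.name}")

    if vo2_units == "l_min":
        scale = 1.0
    elif vo2_units == "ml_min":
        scale = 1e-3
    elif vo2_units == "ml_kg_min":
        if body_mass is None or body_mass <= 0:
            raise ValueError("vo2_units='ml_kg_min' requires positive body_mass")
        scale = body_mass * 1e-3
    else:
        raise ValueError(f"unknown vo2_units {vo2_units!r}")

    def col(key: str) -> np.ndarray | None:
        name = _resolve(df.columns, column_map, key)
        if name is None:
            return None
        return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)

    phase_raw = df[_resolve(df.columns, column_map, "phase")].astype(str).str.strip().str.lower()
    valid = {p.value for p in Phase}
    bad = ~phase_raw.isin(valid)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValidationError(
            f"unknown phase label {phase_raw.iloc[row]!r} at row {row} of {path.name}"
        )
    vco2 = col("vco2")
    return BreathSeries(
        t=col("t"),
        vo2=col("vo2") * scale,
        vco2=None if vco2 is None else vco2 * scale,
        ve=col("ve"),
        hr=col("hr"),
        phase=phase_raw.to_numpy(),
        subject_id=subject_id,
        condition=Condition(condition),
    )


def write_breath_csv(series: BreathSeries, path: str | Path) -> None:
    """Write a series in the canonical dialect (round-trips numerically)."""
    series.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def bin_phase_averages(
    series: BreathSeries, channel: str, window: float = 300.0
) -> list[PhaseAverages]:
    """Average one channel over consecutive windows within each phase.

    Windows are half-open ``[start, start + window)`` seconds, anchored at
    each phase's first breath; only windows fully contained in the phase
    are produced (the 5-min averaging of HR and V̇E across rest, exercise
    and recovery). The mean is the arithmetic mean of the breaths whose
    timestamps fall inside the window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    values = series.channel(channel)
    out: list[PhaseAverages] = []
    for phase in series.phases_present:
        start = series.phase_start(phase)
        end = series.phase_end(phase)
        n_bins = int(np.floor((end - start) / window + 1e-9))
        for i in range(n_bins):
            w0, w1 = start + i * window, start + (i + 1) * window
            m = series.phase_mask(phase) & (series.t >= w0) & (series.t < w1)
            v = values[m]
            v = v[~np.isnan(v)]
            if v.size == 0:
                raise EmptyWindowError(
                    f"no breaths in window [{w0:g}, {w1:g}) s of phase {phase.value}"
                )
            out.append(PhaseAverages(phase, w0, w1, float(v.mean()), channel))
    if not out:
        raise EmptyWindowError(
            f"no complete {window:g} s window fits in any phase of the series"
        )
    return out


def baseline_vo2(series: BreathSeries, window: float = 120.0) -> float:
    """Resting baseline V̇O2 (L·min⁻¹): mean over the final ``window``
    seconds of the rest phase.

    The early part of seated rest is discarded as un-steady; by default
    the last 120 s are averaged (arithmetic mean of covered breaths).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rest = series.phase_slice(Phase.REST)
    end = series.phase_end(Phase.REST)
    start = series.phase_start(Phase.REST)
    if end - start < window:
        raise ValidationError(
            f"rest phase ({end - start:g} s) shorter than baseline window ({window:g} s)"
        )
    m = rest.t >= end - window
    v = rest.vo2[m]
    if v.size == 0:
        raise EmptyWindowError("no breaths in baseline window")
    return float(v.mean())
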