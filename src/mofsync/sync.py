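"""Severity-based temporal synchronization and five-phase binning.

Each patient's expression time series is aligned on the day(s) of maximal
Marshall MOF score (without the neurological component) within days 0-28.
The maximal-score window is the "acute phase"; when the maximum recurs on
several days the stretch from the first to the last maximal day — possibly
containing lower-score days in between — is the "unstable phase" and is
treated as a single acute window provided it spans at most 3 days.

Days around the window are binned into five phases covering a 7-day
interval: early pre-acute (offsets -3, -2), pre-acute (-1), acute (0,
i.e. inside the window), post-acute (+1) and late post-acute (+2, +3).
Offsets before the window are measured from its first day, offsets after
it from its last day, so multi-day windows keep the 7-day interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import pandas as pd

MIN_DAY = 0
MAX_DAY = 28

#: Inclusive span limit of the unstable phase for inclusion.
MAX_UNSTABLE_SPAN = 3

#: Age eligibility bounds (inclusive); the upper bound restricts the
#: female group to the pre-menopausal range.
AGE_BOUNDS = (16, 50)

#: Patients must reach a maximum MOF strictly above this value.
MIN_MAX_MOF = 1


class PhaseLabel(str, Enum):
    """Temporal phase of a sample relative to the acute window."""

    EARLY_PRE_ACUTE = "early_pre_acute"
    PRE_ACUTE = "pre_acute"
    ACUTE = "acute"
    POST_ACUTE = "post_acute"
    LATE_POST_ACUTE = "late_post_acute"
    UNMAPPED = "unmapped"


#: The five analyzable phases in temporal order.
PHASE_ORDER = (
    PhaseLabel.EARLY_PRE_ACUTE,
    PhaseLabel.PRE_ACUTE,
    PhaseLabel.ACUTE,
    PhaseLabel.POST_ACUTE,
    PhaseLabel.LATE_POST_ACUTE,
)

_OFFSET_TO_PHASE = {
    -3: PhaseLabel.EARLY_PRE_ACUTE,
    -2: PhaseLabel.EARLY_PRE_ACUTE,
    -1: PhaseLabel.PRE_ACUTE,
    0: PhaseLabel.ACUTE,
    1: PhaseLabel.POST_ACUTE,
    2: PhaseLabel.LATE_POST_ACUTE,
    3: PhaseLabel.LATE_POST_ACUTE,
}


@dataclass(frozen=True)
class MOFTrajectory:
    """Daily MOF scores of one patient over hospital days 0-28."""

    patient_id: str
    observations: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"empty trajectory for patient {self.patient_id!r}")
        for day, score in self.observations.items():
            if not MIN_DAY <= day <= MAX_DAY:
                raise ValueError(
                    f"patient {self.patient_id!r}: day {day} outside {MIN_DAY}..{MAX_DAY}"
                )
            if score < 0:
                raise ValueError(
                    f"patient {self.patient_id!r}: negative MOF score on day {day}"
                )


@dataclass(frozen=True)
class AcuteWindow:
    """First/last day attaining the maximal MOF score, spanning the unstable phase."""

    patient_id: str
    first_day: int
    last_day: int
    max_score: int
    span: int = field(init=False)

    def __post_init__(self) -> None:
        if self.first_day > self.last_day:
            raise ValueError("first_day must not exceed last_day")
        object.__setattr__(self, "span", self.last_day - self.first_day + 1)


@dataclass(frozen=True)
class PhaseAssignment:
    sample_id: str
    patient_id: str
    day: int
    offset: int
    phase: PhaseLabel


def find_acute_window(trajectory: MOFTrajectory) -> AcuteWindow:
    """Locate the window of maximal MOF score.

    The window runs from the earliest to the latest observed day attaining
    the maximum; intervening days of lower score are absorbed into it.
    """
    obs = trajectory.observations
    max_score = max(obs.values())
    max_days = [d for d, s in obs.items() if s == max_score]
    return AcuteWindow(
        patient_id=trajectory.patient_id,
        first_day=min(max_days),
        last_day=max(max_days),
        max_score=max_score,
    )


def assign_phase(day: int, window: AcuteWindow) -> tuple[int, PhaseLabel]:
    """Map a sampling day to its offset from the acute window and phase bin.

    Days inside the window have offset 0 (acute). Days before it are
    offset from the window's first day, days after it from its last day;
    offsets beyond +-3 fall outside the 7-day analysis interval and are
    unmapped.
    """
    if day < window.first_day:
        offset = day - window.first_day
    elif day > window.last_day:
        offset = day - window.last_day
    else:
        offset = 0
    return offset, _OFFSET_TO_PHASE.get(offset, PhaseLabel.UNMAPPED)


def assign_phases(
    sample_meta: pd.DataFrame, windows: Mapping[str, AcuteWindow]
) -> pd.DataFrame:
    """Assign every sample to its phase.

    Parameters
    ----------
    sample_meta
        Columns ``sample_id``, ``patient_id``, ``day``.
    windows
        Acute window per patient; samples of patients without a window
        are dropped.

    Returns
    -------
    DataFrame with columns ``sample_id, patient_id, day, offset, phase``.
    """
    rows = []
    for rec in sample_meta.itertuples(index=False):
        window = windows.get(str(rec.patient_id))
        if window is None:
            continue
        offset, phase = assign_phase(int(rec.day), window)
        rows.append(
            (str(rec.sample_id), str(rec.patient_id), int(rec.day), offset, phase.value)
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "day", "offset", "phase"]
    )


def filter_patients(
    clinical: pd.DataFrame,
    trajectories: Mapping[str, MOFTrajectory],
    sample_meta: Optional[pd.DataFrame] = None,
    *,
    age_bounds: tuple[int, int] = AGE_BOUNDS,
    min_max_mof: int = MIN_MAX_MOF,
    max_span: int = MAX_UNSTABLE_SPAN,
) -> pd.DataFrame:
    """Apply the cohort inclusion filters, recording one reason per patient.

    Inclusion requires, checked in this order: age within 16-50, maximum
    MOF score > 1, unstable-phase span <= 3 days, and — when sample
    metadata is supplied — at least one expression sample mapping to a
    non-unmapped phase. The first failing criterion becomes the recorded
    exclusion reason.

    Returns
    -------
    DataFrame with columns ``patient_id, included, exclusion_reason,
    age, max_mof, span``.
    """
    clinical = clinical.copy()
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    for pid in clinical["patient_id"]:
        if pid not in trajectories:
            raise KeyError(f"no MOF trajectory for clinical patient {pid!r}")

    per_patient_samples: Optional[Mapping[str, pd.DataFrame]] = None
    if sample_meta is not None:
        meta = sample_meta.copy()
        meta["patient_id"] = meta["patient_id"].astype(str)
        per_patient_samples = dict(tuple(meta.groupby("patient_id")))

    rows = []
    lo, hi = age_bounds
    for rec in clinical.itertuples(index=False):
        pid = str(rec.patient_id)
        window = find_acute_window(trajectories[pid])
        reason = "none"
        if not lo <= int(rec.age) <= hi:
            reason = "age"
        elif window.max_score <= min_max_mof:
            reason = "max_mof"
        elif window.span > max_span:
            reason = "unstable_span"
        elif per_patient_samples is not None:
            mapped = False
            patient_samples = per_patient_samples.get(pid)
            if patient_samples is not None:
                for day in patient_samples["day"]:
                    _, phase = assign_phase(int(day), window)
                    if phase is not PhaseLabel.UNMAPPED:
                        mapped = True
                        break
            if not mapped:
                reason = "no_profile_in_window"
        rows.append(
            (
                pid,
                reason == "none",
                reason,
                int(rec.age),
                window.max_score,
                window.span,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "included", "exclusion_reason", "age", "max_mof", "span"],
    )


def trajectories_from_table(table: pd.DataFrame) -> dict[str, MOFTrajectory]:
    """Build per-patient trajectories from a long table (patient_id, day, mof_score)."""
    out: dict[str, MOFTrajectory] = {}
    for pid, group in table.groupby("patient_id"):
        days = group["day"].astype(int).tolist()
        if len(days) != len(set(days)):
            raise ValueError(f"duplicate days in trajectory of patient {pid!r}")
        out[str(pid)] = MOFTrajectory(
            patient_id=str(pid),
            observations=dict(zip(days, group["mof_score"].astype(int).tolist())),
        )
    return out
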