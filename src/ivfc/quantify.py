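"""Per-record summaries and longitudinal time courses.

``summarize_record`` composes the closed-form estimators: count the events,
average their velocities, plug the vessel diameter and scanning time into
the sampled-volume formula, and divide.  The truncation policy matters:
events clipped by the record boundary have a censored traverse time, so by
default they are *counted* in ``n`` (their existence is evidence of a
traversing cell) but *excluded* from ``ave(v)`` (their velocity is biased
high).  Both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CellEvent,
    RecordSummary,
    ScanMetadata,
    TimeCoursePoint,
    VesselMeasurement,
    concentration,
    sampled_blood_volume,
)
from .exceptions import DataError, InvalidMeasurementError


def summarize_record(
    events: list[CellEvent],
    vessel: VesselMeasurement,
    metadata: ScanMetadata,
    *,
    count_truncated: bool = True,
    velocity_from_truncated: bool = False,
) -> RecordSummary:
    """Aggregate detected events into (n, ave(v), D, T, V, concentration).

    An empty record reports concentration 0 with ``low_confidence=True`` and
    NaN volume (ave(v) is not computable).  If only truncated events exist,
    their censored velocities are used as a fallback and the summary is
    flagged low-confidence.
    """
    if vessel is None:
        raise InvalidMeasurementError("vessel measurement is required")
    T_s = metadata.duration_s
    if not (T_s > 0):
        raise InvalidMeasurementError("record duration must be positive")

    n = len(events) if count_truncated else sum(not e.truncated for e in events)
    velocities = [e.v_um_s for e in events
                  if velocity_from_truncated or not e.truncated]
    low_confidence = False
    if n == 0:
        return RecordSummary(
            n_cells=0, ave_v_um_s=float("nan"), D_um=vessel.D_um, T_s=T_s,
            V_ml=float("nan"), concentration_per_ml=0.0, low_confidence=True,
        )
    if not velocities:  # only truncated events; fall back to censored values
        velocities = [e.v_um_s for e in events]
        low_confidence = True
    ave_v = float(np.mean(velocities))
    V_ml = sampled_blood_volume(vessel.D_um, ave_v, T_s)
    return RecordSummary(
        n_cells=n,
        ave_v_um_s=ave_v,
        D_um=vessel.D_um,
        T_s=T_s,
        V_ml=V_ml,
        concentration_per_ml=concentration(n, V_ml),
        low_confidence=low_confidence,
    )


@dataclass
class TimeCourse:
    """Grouped, time-ordered record summaries for a longitudinal experiment."""

    points: list[TimeCoursePoint]
    schedule_min: tuple[float, ...]

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pt in self.points:
            seen.setdefault(pt.group, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = {"subject_id": pt.subject_id, "group": pt.group,
                   "time_min": pt.time_min}
            row.update(pt.summary.to_dict())
            rows.append(row)
        frame = pd.DataFrame(rows)
        return frame.sort_values(["group", "subject_id", "time_min"]).reset_index(
            drop=True
        )

    def group_stats(self) -> pd.DataFrame:
        """Per (group, time) mean and standard error of the concentration.

        SEM (not SD) is the display aggregation for time-course curves;
        per-record tables keep the raw values.
        """
        frame = self.to_frame()
        g = frame.groupby(["group", "time_min"])["concentration_per_ml"]
        out = g.agg(mean="mean", sem="sem", n="count").reset_index()
        return out

    def fold_change(self, treated: str, control: str) -> pd.DataFrame:
        """Per-timepoint treated-mean / control-mean concentration ratio."""
        stats = self.group_stats().pivot(index="time_min", columns="group",
                                         values="mean")
        for name in (treated, control):
            if name not in stats.columns:
                raise DataError(f"group {name!r} not present in time course")
        out = pd.DataFrame({
            "time_min": stats.index,
            "fold_change": (stats[treated] / stats[control]).to_numpy(),
        }).reset_index(drop=True)
        return out


def build_timecourse(
    points: list[TimeCoursePoint],
    schedule_min: tuple[float, ...] | None = None,
) -> TimeCourse:
    """Assemble per-record summaries into a :class:`TimeCourse`.

    Every point's time must belong to the declared schedule (inferred from
    the data when not given) and each (subject, time) may appear once.
    """
    if schedule_min is None:
        schedule_min = tuple(sorted({pt.time_min for pt in points}))
    schedule = set(schedule_min)
    seen: set[tuple[str, float]] = set()
    for pt in points:
        if pt.time_min not in schedule:
            raise DataError(
                f"time {pt.time_min} of subject {pt.subject_id!r} is not in the "
                f"declared schedule {sorted(schedule)}"
            )
        key = (pt.subject_id, pt.time_min)
        if key in seen:
            raise DataError(f"duplicate measurement for subject/time {key}")
        seen.add(key)
        if pt.summary.concentration_per_ml < 0:
            raise DataError("negative concentration in time course")
    return TimeCourse(points=list(points), schedule_min=tuple(schedule_min))
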