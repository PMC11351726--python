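"""Model/Results interface over the IVFC pipeline.

`RecordModel` wraps one kymograph; its :meth:`~RecordModel.fit` runs vessel
measurement, threshold fitting (or adaptation of a session-level threshold
state), streak detection and summarization, returning a
:class:`RecordResults` that carries the detected events, the vessel
measurement, the record summary, Poisson uncertainty on the concentration,
and a ``summary()`` table.

A longitudinal run keeps the threshold fitted on the first record of a
session and re-scales it per record (`analyze_run`, `run_timecourse`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from . import io as scan_io
from .core import (
    CellEvent,
    Kymograph,
    RecordSummary,
    ScanMetadata,
    TimeCoursePoint,
    VesselMeasurement,
)
from .exceptions import ConfigError
from .quantify import TimeCourse, build_timecourse, summarize_record
from .segmentation import (
    ThresholdState,
    adapt_threshold,
    detect_cells,
    fit_threshold,
    measure_vessel_diameter,
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the record pipeline; defaults match the methods note."""

    reporter_channel: str = "reporter"
    vessel_channel: str = "vessel"
    min_area_px: int = 4
    connectivity: int = 2  # skimage convention; 2 = 8-connected
    scale_bounds: tuple[float, float] = (0.5, 2.0)
    max_cell_fraction: float = 0.02
    k_sigma: float = 3.5
    count_truncated: bool = True
    velocity_from_truncated: bool = False
    vessel_line_stride: int = 1

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ConfigError("min_area_px must be >= 1")
        if self.connectivity not in (1, 2):
            raise ConfigError("connectivity must be 1 (4-conn) or 2 (8-conn)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class RecordModel:
    """One line-scan record to be analyzed.

    Parameters
    ----------
    kymograph : Kymograph
        The record (see :func:`RecordModel.from_files` to load from disk).
    config : AnalysisConfig, optional
    threshold_state : ThresholdState, optional
        A session-level threshold fitted on a previous record; when given it
        is brightness-adapted instead of refitting.
    """

    def __init__(
        self,
        kymograph: Kymograph,
        config: AnalysisConfig | None = None,
        threshold_state: ThresholdState | None = None,
    ) -> None:
        self.kymograph = kymograph
        self.config = config or AnalysisConfig()
        self.threshold_state = threshold_state

    @classmethod
    def from_files(
        cls,
        image_path: str | Path,
        metadata_path: str | Path,
        config: AnalysisConfig | None = None,
        threshold_state: ThresholdState | None = None,
    ) -> "RecordModel":
        kymo = scan_io.read_kymograph(image_path, metadata_path)
        return cls(kymo, config=config, threshold_state=threshold_state)

    def fit(self) -> "RecordResults":
        cfg = self.config
        kymo = self.kymograph
        vessel = measure_vessel_diameter(
            kymo, cfg.vessel_channel, line_stride=cfg.vessel_line_stride
        )
        reporter = kymo.channel(cfg.reporter_channel)
        state = self.threshold_state
        if state is None:
            state = fit_threshold(
                reporter,
                scale_bounds=cfg.scale_bounds,
                max_cell_fraction=cfg.max_cell_fraction,
                k_sigma=cfg.k_sigma,
            )
        threshold = adapt_threshold(state, reporter)
        events = detect_cells(
            kymo, cfg.reporter_channel, threshold,
            min_area_px=cfg.min_area_px, connectivity=cfg.connectivity,
        )
        summary = summarize_record(
            events, vessel, kymo.metadata,
            count_truncated=cfg.count_truncated,
            velocity_from_truncated=cfg.velocity_from_truncated,
        )
        return RecordResults(
            model=self, events=events, vessel=vessel, summary_=summary,
            threshold_state=state, threshold_used=threshold,
        )


@dataclass
class RecordResults:
    """Fitted per-record results: events, vessel, summary, uncertainties."""

    model: RecordModel
    events: list[CellEvent]
    vessel: VesselMeasurement
    summary_: RecordSummary
    threshold_state: ThresholdState
    threshold_used: float

    # -- point estimates ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.summary_.n_cells

    @property
    def concentration_per_ml(self) -> float:
        return self.summary_.concentration_per_ml

    @property
    def ave_v_um_s(self) -> float:
        return self.summary_.ave_v_um_s

    @property
    def metadata(self) -> ScanMetadata:
        return self.model.kymograph.metadata

    # -- uncertainties ------------------------------------------------------
    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Exact Poisson (garwood) confidence interval on the concentration.

        Treats the event count as Poisson at fixed sampled volume; the
        dominant uncertainty for sparse records.
        """
        n = self.summary_.n_cells
        V = self.summary_.V_ml
        if not (V > 0):
            return (0.0, float("nan"))
        lo = sps.chi2.ppf(alpha / 2, 2 * n) / 2 if n > 0 else 0.0
        hi = sps.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2
        return (float(lo) / V, float(hi) / V)

    def velocity_sem(self) -> float:
        v = [e.v_um_s for e in self.events if not e.truncated]
        if len(v) < 2:
            return float("nan")
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        s = self.summary_
        lo, hi = self.conf_int()
        md = self.metadata
        lines = [
            "IVFC record summary",
            "=" * 55,
            f"record: {md.n_lines} lines x {md.n_pixels} px @ "
            f"{md.scan_rate_hz:.1f} Hz, {md.pixel_size_um:.3g} um/px",
            f"scanning time T:        {s.T_s:10.2f} s",
            f"vessel diameter D:      {s.D_um:10.2f} um",
            f"cells counted n:        {s.n_cells:10d}"
            + ("   (low confidence)" if s.low_confidence else ""),
            f"mean velocity ave(v):   {s.ave_v_um_s:10.1f} um/s"
            + (f"  (SEM {self.velocity_sem():.1f})"
               if np.isfinite(self.velocity_sem()) else ""),
            f"sampled volume V:       {s.V_ml:10.3e} mL",
            f"concentration n/V:      {s.concentration_per_ml:10.3e} cells/mL",
            f"  95% Poisson CI:       [{lo:.3e}, {hi:.3e}]",
            f"threshold used:         {self.threshold_used:10.2f} "
            f"({self.threshold_state.method})",
        ]
        return "\n".join(lines)

    def events_frame(self, record_id: str = "record"):
        return scan_io.events_to_frame(self.events, self.metadata.channel_names,
                                       record_id)

    def save(self, out_dir: str | Path, stem: str = "record",
             extra: dict | None = None) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"events": out / f"{stem}_events.csv",
                 "summary": out / f"{stem}_summary.json"}
        scan_io.write_events_csv(self.events, paths["events"],
                                 self.metadata.channel_names, record_id=stem)
        scan_io.write_summary_json(self.summary_, paths["summary"], extra=extra)
        return paths

    def plot(self, ax=None, max_lines: int = 4000):
        from .plot import plot_record  # lazy; matplotlib import is slow
        return plot_record(self, ax=ax, max_lines=max_lines)


# ---------------------------------------------------------------------------
# Session-level helpers
# ---------------------------------------------------------------------------


def analyze_run(
    kymographs: Iterable[Kymograph],
    config: AnalysisConfig | None = None,
) -> list[RecordResults]:
    """Analyze a sequence of records sharing one threshold fit.

    The threshold is fitted on the first record and brightness-adapted to
    each subsequent one, mirroring how a session's records are processed.
    """
    results: list[RecordResults] = []
    state: ThresholdState | None = None
    for kymo in kymographs:
        res = RecordModel(kymo, config=config, threshold_state=state).fit()
        state = res.threshold_state
        results.append(res)
    return results


def run_timecourse(
    records: Iterable[tuple[str, str, float, Kymograph]],
    config: AnalysisConfig | None = None,
    schedule_min: Sequence[float] | None = None,
) -> TimeCourse:
    """Analyze labelled records into a :class:`~ivfc.quantify.TimeCourse`.

    ``records`` yields ``(subject_id, group, time_min, kymograph)``; a
    threshold state is maintained per subject (one imaging session each).
    """
    states: dict[str, ThresholdState] = {}
    points: list[TimeCoursePoint] = []
    for subject, group, time_min, kymo in records:
        res = RecordModel(kymo, config=config,
                          threshold_state=states.get(subject)).fit()
        states[subject] = res.threshold_state
        points.append(TimeCoursePoint(subject_id=subject, group=group,
                                      time_min=time_min, summary=res.summary_))
    return build_timecourse(
        points, tuple(schedule_min) if schedule_min is not None else None
    )
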