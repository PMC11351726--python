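"""Two-color IVFC: antibody gating, percent-positive, and MFI.

A second fluorescence channel (an injected fluorophore-conjugated antibody,
e.g. PE-anti-CD64) is read out at the positions of the cells detected in
the reporter channel.  Events are classified positive/negative against an
intensity gate; the reference instrument gates on single-stained beads,
which have no software equivalent, so the default gate here is the standard
background-statistics rule: positive iff the event's mean intensity on the
gated channel exceeds ``background mean + k * background SD`` (k = 3 by
default), with a fixed-threshold override.

MFI (mean fluorescence intensity) is the background-subtracted mean event
intensity on the gated channel, floored at zero.

Cells carrying the antibody but not the reporter (e.g. CD64+ non-myeloid
leukocytes) leave streaks only in the antibody channel; a secondary
detection pass on that channel, confined to the lumen and matched against
the primary events, recovers them flagged ``reporter-negative``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellEvent, Kymograph, VesselMeasurement
from .exceptions import ConfigError, DataError
from .segmentation import detect_cells, robust_background


@dataclass(frozen=True)
class GateConfig:
    """Positive/negative gate on one channel.

    ``mode="background-kSD"`` thresholds at background mean + ``k`` SD;
    ``mode="fixed"`` uses ``fixed_threshold`` directly.
    """

    channel_name: str = "antibody"
    mode: str = "background-kSD"
    k: float = 3.0
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("background-kSD", "fixed"):
            raise ConfigError(f"unknown gate mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed gate mode requires fixed_threshold")
        if self.mode == "background-kSD" and not (self.k > 0):
            raise ConfigError("k must be positive")


@dataclass(frozen=True)
class GateResult:
    n_total: int
    n_positive: int
    fraction_positive: float
    mfi: float
    threshold_used: float

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_positive": self.n_positive,
            "fraction_positive": self.fraction_positive,
            "mfi": self.mfi,
            "threshold_used": self.threshold_used,
        }


def estimate_background(
    kymo: Kymograph,
    channel_name: str,
    cell_mask: np.ndarray,
    *,
    px_bounds: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """(mean, sd) of the non-cell background on one channel.

    ``cell_mask`` must cover all detected events (dilate generously);
    ``px_bounds`` restricts the statistics to the lumen columns so the
    gate background reflects intravascular plasma, not tissue.
    """
    channel = kymo.channel(channel_name)
    select = ~np.asarray(cell_mask, dtype=bool)
    if select.shape != channel.shape:
        raise DataError(
            f"cell mask shape {select.shape} does not match channel {channel.shape}"
        )
    if px_bounds is not None:
        keep = np.zeros_like(select)
        keep[:, px_bounds[0]:px_bounds[1]] = True
        select &= keep
    values = channel[select]
    if values.size == 0:
        raise DataError("cell mask leaves no background pixels")
    return float(values.mean()), float(values.std())


def gate_threshold(gate: GateConfig, background: tuple[float, float]) -> float:
    if gate.mode == "fixed":
        return float(gate.fixed_threshold)
    mean, sd = background
    return mean + gate.k * sd


def gate_events(
    events: list[CellEvent],
    gate: GateConfig,
    background: tuple[float, float],
) -> GateResult:
    """Classify events against the gate and compute percent-positive and MFI."""
    threshold = gate_threshold(gate, background)
    bg_mean = background[0]
    intensities = []
    for ev in events:
        if gate.channel_name not in ev.mean_intensity:
            raise DataError(
                f"event lacks intensity for channel {gate.channel_name!r}"
            )
        intensities.append(ev.mean_intensity[gate.channel_name])
    intensities = np.asarray(intensities, dtype=float)
    n_total = len(events)
    n_positive = int(np.sum(intensities > threshold))
    mfi = float(max(np.mean(intensities - bg_mean), 0.0)) if n_total else 0.0
    return GateResult(
        n_total=n_total,
        n_positive=n_positive,
        fraction_positive=(n_positive / n_total) if n_total else 0.0,
        mfi=mfi,
        threshold_used=threshold,
    )


def detect_reporter_negative(
    kymo: Kymograph,
    primary_events: list[CellEvent],
    *,
    antibody_channel: str = "antibody",
    vessel: VesselMeasurement | None = None,
    k_sigma: float = 3.5,
    min_area_px: int = 4,
) -> list[CellEvent]:
    """Secondary pass: antibody-only streaks missed by the reporter channel.

    Detects on the antibody channel (thresholded at a robust in-lumen
    background floor), restricted to the lumen columns, and discards any
    component overlapping a primary event's bounding box.
    """
    channel = kymo.channel(antibody_channel)
    bounds = vessel.px_bounds if vessel is not None else (0, channel.shape[1])
    lumen = channel[:, bounds[0]:bounds[1]]
    med, sigma = robust_background(lumen)
    threshold = med + k_sigma * sigma
    candidates = detect_cells(
        kymo, antibody_channel, threshold,
        min_area_px=min_area_px, restrict_cols=bounds,
    )
    primary_boxes = [ev.bbox for ev in primary_events]

    def overlaps(b1, b2) -> bool:
        return b1[0] < b2[1] and b2[0] < b1[1] and b1[2] < b2[3] and b2[2] < b1[3]

    return [ev for ev in candidates
            if not any(overlaps(ev.bbox, pb) for pb in primary_boxes)]


def dotplot_table(
    events: list[CellEvent],
    reporter_channel: str = "reporter",
    antibody_channel: str = "antibody",
) -> pd.DataFrame:
    """Per-event (reporter, antibody) mean-intensity pairs for quadrant plots."""
    rows = []
    for i, ev in enumerate(events):
        for ch in (reporter_channel, antibody_channel):
            if ch not in ev.mean_intensity:
                raise DataError(f"event lacks intensity for channel {ch!r}")
        rows.append({
            "event_id": i,
            "reporter_intensity": ev.mean_intensity[reporter_channel],
            "antibody_intensity": ev.mean_intensity[antibody_channel],
            "source_channel": ev.source_channel,
        })
    return pd.DataFrame(
        rows, columns=["event_id", "reporter_intensity", "antibody_intensity",
                       "source_channel"]
    )


def quadrant_counts(
    table: pd.DataFrame,
    reporter_threshold: float,
    antibody_threshold: float,
) -> dict[str, int]:
    """Quadrant occupancy of a dot plot; counts always sum to the table length."""
    rpos = table["reporter_intensity"] > reporter_threshold
    apos = table["antibody_intensity"] > antibody_threshold
    return {
        "reporter+/antibody-": int((rpos & ~apos).sum()),
        "reporter+/antibody+": int((rpos & apos).sum()),
        "reporter-/antibody+": int((~rpos & apos).sum()),
        "reporter-/antibody-": int((~rpos & ~apos).sum()),
    }
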