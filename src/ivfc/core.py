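"""Domain types, unit conventions, and closed-form IVFC estimators.

The measurement geometry: a scanning microscope repeatedly images a single
line placed across a blood vessel (650-850 lines/s in typical recordings).
Stacking successive lines gives a *kymograph* with one spatial axis (position
along the scan line, in pixels) and one temporal axis (scan-line index).
A fluorescent cell crossing the line leaves a streak whose spatial extent is
the cell diameter ``d`` (a flowing leukocyte is approximately round, so the
traversing distance equals the diameter) and whose temporal extent is the
traverse time ``t``; its velocity is ``v = d / t``.

Counting ``n`` cells over a record of duration ``T`` in a vessel of lumen
diameter ``D`` samples the blood volume

    V = pi * (D/2)**2 * ave(v) * T

and the circulating-cell concentration is ``n / V``.

Unit conventions, used consistently across the package: lengths in
micrometres, times in seconds except the per-event traverse time (reported
in milliseconds, matching how the quantity is usually quoted), velocities in
um/s, volumes internally in um^3 and reported in mL with the fixed factor
1 mL = 1e12 um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, FormatError, InvalidMeasurementError, MetadataError

#: Conversion factor between the internal volume unit (um^3) and millilitres.
UM3_PER_ML = 1.0e12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanMetadata:
    """Acquisition parameters converting pixels to um and scan lines to seconds.

    Parameters
    ----------
    scan_rate_hz : float
        Line-scan rate in lines per second (strictly positive).
    pixel_size_um : float
        Pixel pitch along the scan line, in micrometres per pixel.
    n_lines : int
        Number of scan lines in the record (temporal axis length).
    n_pixels : int
        Pixels per scan line (spatial axis length).
    channel_names : tuple of str
        Ordered channel labels, e.g. ``("vessel", "reporter")``.
    duration_s : float, optional
        Record duration T in seconds.  Defaults to ``n_lines / scan_rate_hz``
        and must agree with it to within one line period.
    """

    scan_rate_hz: float
    pixel_size_um: float
    n_lines: int
    n_pixels: int
    channel_names: tuple[str, ...] = ("vessel", "reporter")
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.scan_rate_hz > 0):
            raise MetadataError("scan_rate_hz must be positive")
        if not (self.pixel_size_um > 0):
            raise MetadataError("pixel_size_um must be positive")
        if self.n_lines < 1 or self.n_pixels < 1:
            raise MetadataError("n_lines and n_pixels must be >= 1")
        if len(self.channel_names) != len(set(self.channel_names)):
            raise MetadataError("channel_names must be unique")
        nominal = self.n_lines / self.scan_rate_hz
        if self.duration_s is None:
            object.__setattr__(self, "duration_s", nominal)
        elif abs(self.duration_s - nominal) > 1.0 / self.scan_rate_hz:
            raise MetadataError(
                f"duration_s={self.duration_s} inconsistent with "
                f"n_lines/scan_rate_hz={nominal} (tolerance one line period)"
            )
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    # -- unit conversions ---------------------------------------------------
    @property
    def line_period_s(self) -> float:
        return 1.0 / self.scan_rate_hz

    def px_to_um(self, px: float) -> float:
        """Physical length of a ``px``-pixel extent (count convention)."""
        return px * self.pixel_size_um

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def um_to_px_index(self, um: float) -> int:
        """Inverse of :meth:`px_to_um` for integral pixel counts."""
        return round(um / self.pixel_size_um)

    def lines_to_ms(self, lines: float) -> float:
        return lines / self.scan_rate_hz * 1000.0

    def ms_to_lines(self, ms: float) -> float:
        return ms * self.scan_rate_hz / 1000.0

    def ms_to_line_index(self, ms: float) -> int:
        return round(ms * self.scan_rate_hz / 1000.0)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MetadataError(
                f"unknown channel {name!r}; channels are {self.channel_names}"
            ) from None


@dataclass
class Kymograph:
    """A multi-channel line-scan record, time-major.

    ``pixels`` has shape ``(n_lines, n_pixels, n_channels)``: axis 0 is the
    scan-line index (time), axis 1 the position along the scan line, axis 2
    the channel.  Intensities are non-negative and finite.
    """

    pixels: np.ndarray
    metadata: ScanMetadata

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise FormatError(f"kymograph pixels must be 2-D or 3-D, got {arr.ndim}-D")
        md = self.metadata
        if arr.shape != (md.n_lines, md.n_pixels, md.n_channels):
            raise FormatError(
                f"pixel grid {arr.shape} does not match metadata "
                f"({md.n_lines}, {md.n_pixels}, {md.n_channels})"
            )
        if not np.all(np.isfinite(arr)):
            raise DataError("kymograph contains non-finite pixels")
        if arr.min() < 0:
            raise DataError("kymograph contains negative pixels")
        self.pixels = arr

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D ``(n_lines, n_pixels)`` plane of a named channel."""
        return self.pixels[:, :, self.metadata.channel_index(name)]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CellEvent:
    """One detected cell traversing the scan line.

    ``bbox`` is half-open pixel ranges ``(line_start, line_end, px_start,
    px_end)``.  ``truncated`` is set when the bounding box touches the first
    or last scan line, i.e. the traverse time is censored by the record
    boundary.
    """

    bbox: tuple[int, int, int, int]
    d_um: float
    t_ms: float
    v_um_s: float
    centroid: tuple[float, float]
    mean_intensity: dict[str, float]
    max_intensity: dict[str, float]
    truncated: bool = False
    source_channel: str = "reporter"

    def __post_init__(self) -> None:
        l0, l1, p0, p1 = self.bbox
        if not (l1 > l0 >= 0 and p1 > p0 >= 0):
            raise InvalidMeasurementError(f"degenerate bbox {self.bbox}")
        if not (self.d_um > 0 and self.t_ms > 0):
            raise InvalidMeasurementError("cell extent must be positive")

    @property
    def line_start(self) -> int:
        return self.bbox[0]


@dataclass(frozen=True)
class VesselMeasurement:
    """Vessel lumen diameter measured from the intravascular dye channel."""

    D_um: float
    px_bounds: tuple[int, int]
    lines_used: int

    def __post_init__(self) -> None:
        if not self.D_um > 0:
            raise InvalidMeasurementError("vessel diameter must be positive")


@dataclass(frozen=True)
class RecordSummary:
    """Per-record aggregate: n, ave(v), D, T, V, and concentration.

    When no events are usable the record reports concentration 0 with
    ``low_confidence=True`` and undefined (NaN) volume, since ave(v) cannot
    be computed.
    """

    n_cells: int
    ave_v_um_s: float
    D_um: float
    T_s: float
    V_ml: float
    concentration_per_ml: float
    low_confidence: bool = False

    def to_dict(self) -> dict:
        return {
            "n_cells": int(self.n_cells),
            "ave_v_um_s": float(self.ave_v_um_s),
            "D_um": float(self.D_um),
            "T_s": float(self.T_s),
            "V_ml": float(self.V_ml),
            "concentration_per_ml": float(self.concentration_per_ml),
            "low_confidence": bool(self.low_confidence),
        }


@dataclass(frozen=True)
class TimeCoursePoint:
    """One (subject, group, time) measurement in a longitudinal experiment."""

    subject_id: str
    group: str
    time_min: float
    summary: RecordSummary


# ---------------------------------------------------------------------------
# Closed-form estimators
# ---------------------------------------------------------------------------


def cell_velocity(d_um: float, t_ms: float) -> float:
    """Cell velocity ``v = d / t`` in um/s from diameter (um) and traverse time (ms)."""
    if not (d_um > 0):
        raise InvalidMeasurementError(f"cell diameter must be positive, got {d_um}")
    if not (t_ms > 0):
        raise InvalidMeasurementError(f"traverse time must be positive, got {t_ms}")
    return d_um / (t_ms / 1000.0)


def sampled_blood_volume(D_um: float, ave_v_um_s: float, T_s: float) -> float:
    """Blood volume (mL) sampled by the scan line: ``pi (D/2)^2 ave(v) T``.

    The cylinder of blood that crossed the line during the record: lumen
    cross-section ``pi (D/2)^2`` (um^2) times the mean cell velocity (um/s)
    times the scanning time (s), converted from um^3 to mL.
    """
    if not (D_um > 0):
        raise InvalidMeasurementError(f"vessel diameter must be positive, got {D_um}")
    if not (ave_v_um_s > 0):
        raise InvalidMeasurementError(
            f"average velocity must be positive, got {ave_v_um_s}"
        )
    if not (T_s > 0):
        raise InvalidMeasurementError(f"scanning time must be positive, got {T_s}")
    return math.pi * (D_um / 2.0) ** 2 * ave_v_um_s * T_s / UM3_PER_ML


def concentration(n: int, V_ml: float) -> float:
    """Circulating-cell concentration ``n / V`` in cells/mL."""
    if n < 0:
        raise InvalidMeasurementError(f"cell count must be non-negative, got {n}")
    if not (V_ml > 0):
        raise InvalidMeasurementError(f"sampled volume must be positive, got {V_ml}")
    return n / V_ml
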