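"""Cell-streak and vessel-lumen segmentation of line-scan kymographs.

The detection procedure mirrors the classic threshold -> binarize -> label ->
measure chain: a global intensity threshold fitted on the first record of a
session separates cells (brighter) from background (darker), is re-scaled to
each subsequent record's brightness, and connected-component labeling of the
binary image yields one component per traversing cell, from which diameter,
traverse time and velocity are measured.

Thresholding.  Otsu's criterion (maximize between-class variance over the
histogram) is the fitted threshold whenever its split is plausible for a
kymograph.  Kymographs are, however, extremely foreground-sparse: cells
typically occupy well under a percent of the pixels, and with such class
imbalance the between-class variance is maximized by splitting the
*background noise* distribution near its mean rather than separating cells
from background.  ``fit_threshold`` therefore sanity-checks the Otsu split:
if it marks more than ``max_cell_fraction`` of pixels as foreground
(default 2%, far above any physically possible streak coverage) the
threshold falls back to a robust background floor,
``median + k_sigma * sigma`` with sigma estimated by sigma-clipped MAD
(default ``k_sigma = 3.5``, i.e. a ~3.5-sigma detection floor).  On a
noise-free image the sparse Otsu split is valid and is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

from .core import CellEvent, Kymograph, VesselMeasurement, cell_velocity
from .exceptions import (
    ConfigError,
    DataError,
    DegenerateImageError,
    VesselNotFoundError,
)

# ---------------------------------------------------------------------------
# Threshold fitting and adaptation
# ---------------------------------------------------------------------------


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: the histogram split maximizing between-class variance."""
    arr = np.asarray(channel)
    if arr.max() == arr.min():
        raise DegenerateImageError("constant image has no Otsu threshold")
    return float(threshold_otsu(arr, nbins=nbins))


def _median(channel: np.ndarray, max_sample: int = 500_000) -> float:
    """Median brightness, estimated on a deterministic stride for large channels."""
    arr = np.asarray(channel).ravel()
    if arr.size > max_sample:
        arr = arr[:: arr.size // max_sample + 1]
    return float(np.median(arr))


def robust_background(
    channel: np.ndarray, *, clip_sigma: float = 3.0, n_iter: int = 5,
    max_sample: int = 200_000,
) -> tuple[float, float]:
    """Sigma-clipped (median, sigma) of the background intensity distribution.

    MAD-based sigma (scaled by 1.4826) with iterative clipping rejects the
    sparse bright streaks; large channels are strided down to ``max_sample``
    pixels (deterministically) before estimation.
    """
    arr = np.asarray(channel, dtype=np.float64).ravel()
    if arr.size > max_sample:
        arr = arr[:: arr.size // max_sample + 1]
    for _ in range(n_iter):
        med = np.median(arr)
        sigma = 1.4826 * np.median(np.abs(arr - med))
        if sigma == 0:
            break
        keep = np.abs(arr - med) <= clip_sigma * sigma
        if keep.all():
            break
        arr = arr[keep]
    return float(np.median(arr)), float(sigma)


@dataclass(frozen=True)
class ThresholdState:
    """Threshold fitted on a session's first record, re-usable across records."""

    base_threshold: float
    base_brightness: float
    scale_bounds: tuple[float, float] = (0.5, 2.0)
    method: str = "otsu"  # "otsu" | "background-floor"

    def __post_init__(self) -> None:
        lo, hi = self.scale_bounds
        if not (lo <= 1.0 <= hi):
            raise ConfigError(f"scale_bounds must bracket 1.0, got {self.scale_bounds}")


def fit_threshold(
    channel: np.ndarray,
    *,
    scale_bounds: tuple[float, float] = (0.5, 2.0),
    max_cell_fraction: float = 0.02,
    k_sigma: float = 3.5,
) -> ThresholdState:
    """Fit the cell/background threshold on (the reporter channel of) a record.

    Otsu's criterion when its split is kymograph-plausible; a robust
    background floor (``median + k_sigma * sigma``) otherwise.  See the
    module docstring for why both are needed.
    """
    arr = np.asarray(channel)
    t = otsu_threshold(arr)
    method = "otsu"
    if float(np.mean(arr > t)) > max_cell_fraction:
        med, sigma = robust_background(arr)
        t = med + k_sigma * sigma
        method = "background-floor"
    brightness = _median(arr)
    return ThresholdState(
        base_threshold=float(t),
        base_brightness=brightness,
        scale_bounds=scale_bounds,
        method=method,
    )


def adapt_threshold(state: ThresholdState, channel: np.ndarray) -> float:
    """Re-scale the fitted threshold to a record's brightness.

    Returns ``base_threshold * clip(median(channel)/base_brightness,
    scale_bounds)`` — the brightness-adjustment applied to every record
    after the first; deterministic.
    """
    if state.base_brightness == 0:
        raise DataError("threshold state has zero base brightness")
    ratio = _median(channel) / state.base_brightness
    lo, hi = state.scale_bounds
    return state.base_threshold * float(np.clip(ratio, lo, hi))


# ---------------------------------------------------------------------------
# Cell detection
# ---------------------------------------------------------------------------


def _component_events(
    binary: np.ndarray,
    kymo: Kymograph,
    *,
    min_area_px: int,
    connectivity: int,
    source_channel: str,
    restrict_cols: tuple[int, int] | None = None,
) -> list[CellEvent]:
    md = kymo.metadata
    labels = _sk_label(binary, connectivity=connectivity)
    events: list[CellEvent] = []
    for region in regionprops(labels, intensity_image=kymo.pixels):
        if region.area < min_area_px:
            continue
        l0, p0, l1, p1 = region.bbox  # 2-D label image: (min_row, min_col, max_row, max_col)
        if restrict_cols is not None and (p1 <= restrict_cols[0] or p0 >= restrict_cols[1]):
            continue
        d_um = md.px_to_um(p1 - p0)
        t_ms = md.lines_to_ms(l1 - l0)
        mean_int = np.atleast_1d(region.intensity_mean)
        max_int = np.atleast_1d(region.intensity_max)
        events.append(
            CellEvent(
                bbox=(l0, l1, p0, p1),
                d_um=d_um,
                t_ms=t_ms,
                v_um_s=cell_velocity(d_um, t_ms),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                mean_intensity={
                    ch: float(mean_int[i]) for i, ch in enumerate(md.channel_names)
                },
                max_intensity={
                    ch: float(max_int[i]) for i, ch in enumerate(md.channel_names)
                },
                truncated=(l0 == 0 or l1 == md.n_lines),
                source_channel=source_channel,
            )
        )
    events.sort(key=lambda ev: (ev.bbox[0], ev.bbox[2]))
    return events


def detect_cells(
    kymo: Kymograph,
    channel_name: str,
    threshold: float,
    *,
    min_area_px: int = 4,
    connectivity: int = 2,
    restrict_cols: tuple[int, int] | None = None,
) -> list[CellEvent]:
    """Detect cell streaks in one channel of a kymograph.

    Pixels strictly above ``threshold`` are binarized and labeled
    (``connectivity=2`` means 8-connected, the default: fast streaks run
    diagonally); components smaller than ``min_area_px`` pixels are
    discarded as shot noise.  Each surviving component becomes a
    :class:`CellEvent` with the spatial bbox extent as diameter, the
    temporal bbox extent as traverse time, ``v = d/t``, per-channel
    mean/max intensities, and a ``truncated`` flag when the component
    touches the record's first or last line.  Events are sorted by onset.

    ``restrict_cols`` optionally drops components entirely outside a pixel
    column range (used to confine a secondary detection pass to the lumen).
    """
    channel = kymo.channel(channel_name)  # raises on unknown channel
    binary = channel > threshold
    return _component_events(
        binary,
        kymo,
        min_area_px=min_area_px,
        connectivity=connectivity,
        source_channel=channel_name,
        restrict_cols=restrict_cols,
    )


def events_to_mask(
    events: list[CellEvent], shape: tuple[int, int], dilate_px: int = 0
) -> np.ndarray:
    """Binary mask of event bounding boxes (optionally dilated), for background stats."""
    mask = np.zeros(shape, dtype=bool)
    for ev in events:
        l0, l1, p0, p1 = ev.bbox
        mask[
            max(0, l0 - dilate_px): l1 + dilate_px,
            max(0, p0 - dilate_px): p1 + dilate_px,
        ] = True
    return mask


# ---------------------------------------------------------------------------
# Vessel diameter
# ---------------------------------------------------------------------------


def _longest_runs(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-line longest above-threshold run: (length, start, end), vectorized."""
    n_lines, n_px = binary.shape
    idx = np.arange(n_px)
    # index of the most recent zero at or before each position (-1 if none)
    last_zero = np.where(~binary, idx, -1)
    last_zero = np.maximum.accumulate(last_zero, axis=1)
    run_len = np.where(binary, idx - last_zero, 0)
    lengths = run_len.max(axis=1)
    ends = run_len.argmax(axis=1) + 1  # exclusive; valid where lengths > 0
    starts = ends - lengths
    return lengths, starts, ends


def measure_vessel_diameter(
    kymo: Kymograph,
    dye_channel_name: str = "vessel",
    *,
    line_stride: int = 1,
    min_valid_fraction: float = 0.5,
) -> VesselMeasurement:
    """Vessel lumen diameter from the intravascular dye channel.

    The dye channel is thresholded with Otsu's criterion (the lumen/outside
    split is well balanced, Otsu's home turf); on each scan line the longest
    contiguous above-threshold run is taken as the lumen cross-section, and
    the diameter is the median run length across lines times the pixel size.
    ``px_bounds`` is the half-open median lumen extent.  ``line_stride``
    subsamples lines for speed (the median over tens of thousands of lines
    is insensitive to striding).
    """
    channel = np.asarray(kymo.channel(dye_channel_name))[::line_stride]
    if channel.max() == channel.min():
        raise VesselNotFoundError("dye channel is constant; no lumen detectable")
    t = otsu_threshold(channel)
    binary = channel > t
    lengths, starts, ends = _longest_runs(binary)
    valid = lengths > 0
    if valid.mean() <= min_valid_fraction:
        raise VesselNotFoundError(
            f"above-threshold lumen found on only {valid.mean():.0%} of scan lines"
        )
    width_px = int(round(float(np.median(lengths[valid]))))
    start_px = int(round(float(np.median(starts[valid]))))
    if width_px < 1:
        raise VesselNotFoundError("median lumen width is below one pixel")
    return VesselMeasurement(
        D_um=kymo.metadata.px_to_um(width_px),
        px_bounds=(start_px, start_px + width_px),
        lines_used=int(valid.sum()),
    )
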