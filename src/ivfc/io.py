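"""Readers and writers for kymograph images, scan metadata, and tables.

Supported image layouts (all TIFF, via :mod:`tifffile`):

* multi-page grayscale, one page per channel (``(C, L, P)``);
* single-page grayscale (one channel, ``(L, P)``);
* single-page multi-channel (``(L, P, C)`` with C <= 4, samples-per-pixel);
* single-page RGBA composite, split by color convention (below).

RGBA convention: scanning-microscope exports often render the myeloid
reporter (EGFP) in the green plane and the intravascular dye /
PE-conjugated antibody in magenta (red+blue).  The default split is
``reporter = G`` and ``vessel = max(R, B)``; the alpha plane is ignored.
Both assignments are overridable.

Metadata dialects:

* ``native-json`` — ``{"scan_rate_hz": ..., "pixel_size_um": ...,
  "n_lines": ..., "n_pixels": ..., "channels": [...]}``;
* ``prairie-xml`` — PrairieView-style ``<PVStateValue key=... value=...>``
  entries with ``scanLinePeriod`` (seconds per line) and
  ``micronsPerPixel`` (flat or with ``<IndexedValue index="XAxis">``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd
import tifffile

from .core import CellEvent, Kymograph, RecordSummary, ScanMetadata
from .exceptions import DataError, FormatError, MetadataError

logger = logging.getLogger(__name__)

_XML_KEYS_USED = {
    "scanLinePeriod",
    "micronsPerPixel",
    "linesPerFrame",
    "pixelsPerLine",
}


@dataclass(frozen=True)
class MetadataDocument:
    """A parsed metadata file: raw key-value pairs plus the resolved ScanMetadata."""

    source_path: str
    dialect: str  # "native-json" | "prairie-xml"
    raw: dict
    resolved: ScanMetadata


# ---------------------------------------------------------------------------
# Metadata parsing
# ---------------------------------------------------------------------------


def _resolve(raw: dict, dialect: str, source: str) -> MetadataDocument:
    for key in ("scan_rate_hz", "pixel_size_um", "n_lines", "n_pixels"):
        if key not in raw:
            raise MetadataError(f"{source}: required metadata key {key!r} not found")
        if key in ("scan_rate_hz", "pixel_size_um") and not (float(raw[key]) > 0):
            raise MetadataError(f"{source}: {key} must be positive, got {raw[key]}")
    md = ScanMetadata(
        scan_rate_hz=float(raw["scan_rate_hz"]),
        pixel_size_um=float(raw["pixel_size_um"]),
        n_lines=int(raw["n_lines"]),
        n_pixels=int(raw["n_pixels"]),
        channel_names=tuple(raw.get("channels", ("vessel", "reporter"))),
        duration_s=float(raw["duration_s"]) if "duration_s" in raw else None,
    )
    return MetadataDocument(source_path=source, dialect=dialect, raw=raw, resolved=md)


def _parse_prairie_xml(path: Path) -> MetadataDocument:
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise MetadataError(f"{path}: malformed XML ({exc})") from exc
    values: dict[str, object] = {}
    for node in tree.iter("PVStateValue"):
        key = node.get("key")
        if key is None:
            continue
        if node.get("value") is not None:
            values[key] = node.get("value")
        else:
            indexed = {
                child.get("index"): child.get("value")
                for child in node.iter("IndexedValue")
            }
            if indexed:
                values[key] = indexed
    unknown = sorted(set(values) - _XML_KEYS_USED)
    if unknown:
        logger.warning("%s: ignoring unrecognized XML keys %s", path, unknown)

    if "scanLinePeriod" not in values:
        raise MetadataError(f"{path}: scan rate not found (no scanLinePeriod key)")
    period = float(values["scanLinePeriod"])  # seconds per line
    if period <= 0:
        raise MetadataError(f"{path}: scanLinePeriod must be positive, got {period}")

    mpp = values.get("micronsPerPixel")
    if mpp is None:
        raise MetadataError(f"{path}: pixel size not found (no micronsPerPixel key)")
    if isinstance(mpp, dict):
        if "XAxis" not in mpp:
            raise MetadataError(f"{path}: pixel size not found (no XAxis entry)")
        pixel_size = float(mpp["XAxis"])
    else:
        pixel_size = float(mpp)

    raw = {
        "scan_rate_hz": 1.0 / period,
        "pixel_size_um": pixel_size,
    }
    for src, dst in (("linesPerFrame", "n_lines"), ("pixelsPerLine", "n_pixels")):
        if src in values:
            raw[dst] = int(float(values[src]))
        else:
            raise MetadataError(f"{path}: required metadata key {src!r} not found")
    return _resolve(raw, "prairie-xml", str(path))


def parse_scan_metadata(metadata_path: str | Path) -> MetadataDocument:
    """Parse a native-JSON or PrairieView-style XML metadata sidecar."""
    path = Path(metadata_path)
    if not path.exists():
        raise MetadataError(f"metadata file not found: {path}")
    if path.suffix.lower() == ".xml":
        return _parse_prairie_xml(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise MetadataError(f"{path}: metadata JSON must be an object")
    return _resolve(raw, "native-json", str(path))


def write_scan_metadata_json(metadata: ScanMetadata, path: str | Path) -> None:
    doc = {
        "scan_rate_hz": metadata.scan_rate_hz,
        "pixel_size_um": metadata.pixel_size_um,
        "n_lines": metadata.n_lines,
        "n_pixels": metadata.n_pixels,
        "channels": list(metadata.channel_names),
        "duration_s": metadata.duration_s,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Kymograph images
# ---------------------------------------------------------------------------


def split_rgba(
    plane: np.ndarray,
    reporter_plane: str = "G",
    vessel_planes: str = "RB",
) -> np.ndarray:
    """Split an ``(L, P, 4)`` RGBA composite into (vessel, reporter) channels.

    ``vessel_planes`` are combined by per-pixel maximum (magenta = R+B
    rendering of the dye).  Returns an ``(L, P, 2)`` array ordered
    (vessel, reporter).
    """
    if plane.ndim != 3 or plane.shape[2] != 4:
        raise FormatError(f"expected an RGBA plane, got shape {plane.shape}")
    idx = {"R": 0, "G": 1, "B": 2, "A": 3}
    rep = plane[:, :, idx[reporter_plane]]
    ves = np.max(plane[:, :, [idx[c] for c in vessel_planes]], axis=2)
    return np.stack([ves, rep], axis=2)


def read_kymograph(
    image_path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    metadata: ScanMetadata | None = None,
    transpose: bool = False,
) -> Kymograph:
    """Read a TIFF kymograph and validate it against its scan metadata.

    Exactly one of ``metadata_path`` / ``metadata`` must be given.  Set
    ``transpose=True`` if the file is stored space-major (rows = pixels).
    """
    if (metadata is None) == (metadata_path is None):
        raise MetadataError("provide exactly one of metadata_path or metadata")
    if metadata is None:
        metadata = parse_scan_metadata(metadata_path).resolved

    path = Path(image_path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()

    arr = np.asarray(arr)
    if transpose:
        arr = arr.swapaxes(-2, -1) if arr.ndim == 2 else arr.swapaxes(0, 1)

    md = metadata
    if arr.ndim == 2:
        pixels = arr[:, :, None]
    elif arr.ndim == 3:
        if arr.shape[2] == 4 and md.n_channels != 4:
            # RGBA composite
            pixels = split_rgba(arr)
        elif arr.shape[0] == md.n_channels and arr.shape[1:] == (md.n_lines, md.n_pixels):
            # multi-page: pages are channels
            pixels = np.moveaxis(arr, 0, 2)
        else:
            pixels = arr
    else:
        raise FormatError(f"unsupported TIFF dimensionality {arr.ndim}")

    if pixels.shape[:2] != (md.n_lines, md.n_pixels):
        raise FormatError(
            f"image is {pixels.shape[0]} lines x {pixels.shape[1]} px but metadata "
            f"declares {md.n_lines} x {md.n_pixels}"
        )
    if pixels.shape[2] != md.n_channels:
        raise FormatError(
            f"image has {pixels.shape[2]} channels but metadata declares "
            f"{md.n_channels} ({md.channel_names})"
        )
    pixels = np.ascontiguousarray(pixels, dtype=np.float32)
    if not np.all(np.isfinite(pixels)):
        raise DataError(f"{path}: image contains NaN or infinite pixels")
    if pixels.min() < 0:
        raise DataError(f"{path}: image contains negative pixels")
    return Kymograph(pixels=pixels, metadata=md)


def write_kymograph(kymo: Kymograph, image_path: str | Path) -> None:
    """Write a kymograph as a multi-page grayscale float32 TIFF (page = channel)."""
    arr = np.moveaxis(kymo.pixels.astype(np.float32), 2, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tifffile.imwrite(image_path, arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------


def events_to_frame(
    events: list[CellEvent],
    channel_names: tuple[str, ...],
    record_id: str = "record",
) -> pd.DataFrame:
    """Flatten detected events into the canonical per-event table."""
    rows = []
    for i, ev in enumerate(events):
        row = {
            "record_id": record_id,
            "event_id": i,
            "line_start": ev.bbox[0],
            "line_end": ev.bbox[1],
            "px_start": ev.bbox[2],
            "px_end": ev.bbox[3],
            "d_um": ev.d_um,
            "t_ms": ev.t_ms,
            "v_um_s": ev.v_um_s,
        }
        for ch in channel_names:
            row[f"mean_intensity_{ch}"] = ev.mean_intensity.get(ch, np.nan)
            row[f"max_intensity_{ch}"] = ev.max_intensity.get(ch, np.nan)
        row["truncated"] = ev.truncated
        row["source_channel"] = ev.source_channel
        rows.append(row)
    columns = (
        ["record_id", "event_id", "line_start", "line_end", "px_start", "px_end",
         "d_um", "t_ms", "v_um_s"]
        + [f"mean_intensity_{ch}" for ch in channel_names]
        + [f"max_intensity_{ch}" for ch in channel_names]
        + ["truncated", "source_channel"]
    )
    return pd.DataFrame(rows, columns=columns)


def write_events_csv(
    events: list[CellEvent],
    path: str | Path,
    channel_names: tuple[str, ...],
    record_id: str = "record",
) -> None:
    events_to_frame(events, channel_names, record_id).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def frame_to_events(frame: pd.DataFrame) -> list[CellEvent]:
    """Rehydrate :class:`CellEvent` objects from the canonical table."""
    mean_cols = [c for c in frame.columns if c.startswith("mean_intensity_")]
    max_cols = [c for c in frame.columns if c.startswith("max_intensity_")]
    events = []
    for _, row in frame.iterrows():
        bbox = (int(row.line_start), int(row.line_end),
                int(row.px_start), int(row.px_end))
        events.append(
            CellEvent(
                bbox=bbox,
                d_um=float(row.d_um),
                t_ms=float(row.t_ms),
                v_um_s=float(row.v_um_s),
                centroid=((bbox[0] + bbox[1]) / 2.0, (bbox[2] + bbox[3]) / 2.0),
                mean_intensity={
                    c.removeprefix("mean_intensity_"): float(row[c]) for c in mean_cols
                },
                max_intensity={
                    c.removeprefix("max_intensity_"): float(row[c]) for c in max_cols
                },
                truncated=bool(row.truncated),
                source_channel=str(row.get("source_channel", "reporter")),
            )
        )
    return events


def write_summary_json(
    summary: RecordSummary, path: str | Path, extra: dict | None = None
) -> None:
    doc = summary.to_dict()
    # NaN (undefined volume on empty records) is not valid JSON; use null.
    doc = {k: (None if isinstance(v, float) and np.isnan(v) else v)
           for k, v in doc.items()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_summary_json(path: str | Path) -> RecordSummary:
    doc = json.loads(Path(path).read_text())
    doc = {k: (np.nan if v is None else v) for k, v in doc.items()}
    return RecordSummary(
        n_cells=doc["n_cells"],
        ave_v_um_s=doc["ave_v_um_s"],
        D_um=doc["D_um"],
        T_s=doc["T_s"],
        V_ml=doc["V_ml"],
        concentration_per_ml=doc["concentration_per_ml"],
        low_confidence=doc["low_confidence"],
    )
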