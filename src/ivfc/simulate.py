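"""Ground-truth synthetic kymograph generator.

Operationalizes the concentration model in reverse: cells at blood
concentration ``C`` flowing through a lumen of diameter ``D`` at mean
velocity ``mean(v)`` cross the scan line as a Poisson process with rate

    lambda = C * pi * (D/2)**2 * mean(v) * 1e-12   [events / s]

(volumetric flux times concentration).  Each arrival draws a diameter and a
velocity from truncated-normal distributions (positivity is physical) and is
rendered as a filled ellipse in (pixel, line) space with spatial axis
``d / pixel_size`` pixels and temporal axis ``(d / v) * scan_rate`` lines,
centred at a uniform lane within the lumen.  Plug flow is assumed (one
velocity per cell, no radial profile), matching the single ``ave(v)`` the
volume formula uses; an optional parabolic profile exists for sensitivity
analysis only.  The vessel-dye channel is the dye level inside the lumen and
background outside; additive Gaussian read noise (clipped at zero) is the
default noise model.

Default parameters are the conditions of typical mouse-ear recordings:
d ~ 6.6 +/- 1.4 um, v ~ 1063 +/- 357 um/s, D = 40 um, 650-850 Hz line rate,
T = 120 s, and a resting myeloid-reporter concentration of ~1.31e5 cells/mL.

Arrivals are drawn in a margin of +/- max-traverse-time around ``[0, T]`` so
boundary truncation occurs naturally; the truth table marks truncated
events.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import Kymograph, ScanMetadata, UM3_PER_ML
from .exceptions import ConfigError, GeometryError
from . import io as scan_io


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for one synthetic record.

    Intensity levels are absolute (arbitrary units); ``noise_sd`` is the
    Gaussian read-noise standard deviation, so the reporter SNR is
    ``(reporter_level - background_level) / noise_sd`` (default 5).
    ``positive_fraction`` / ``reporter_fraction`` control the two-color
    mixture; cells carrying neither marker are invisible to the instrument
    and are not generated.
    """

    seed: int = 0
    D_um: float = 40.0
    T_s: float = 120.0
    scan_rate_hz: float = 750.0
    pixel_size_um: float = 0.6
    n_pixels: int = 128
    concentration_per_ml: float = 1.31e5
    v_mean_um_s: float = 1063.0
    v_sd_um_s: float = 357.0
    d_mean_um: float = 6.6
    d_sd_um: float = 1.4
    background_level: float = 100.0
    vessel_dye_level: float = 200.0
    reporter_level: float = 200.0
    antibody_level: float = 250.0
    antibody_plasma_level: float = 150.0
    noise_sd: float = 20.0
    two_color: bool = False
    positive_fraction: float = 0.208
    reporter_fraction: float = 1.0
    cells_in_dye_level: float = 0.0
    avoid_overlap: bool = False
    overlap_margin_px: int = 2
    parabolic_profile: bool = False

    def __post_init__(self) -> None:
        if min(self.D_um, self.T_s, self.scan_rate_hz, self.pixel_size_um,
               self.v_mean_um_s, self.d_mean_um) <= 0:
            raise ConfigError("all physical scales must be positive")
        if self.noise_sd < 0 or self.concentration_per_ml < 0:
            raise ConfigError("noise_sd and concentration must be non-negative")
        if not (0.0 <= self.positive_fraction <= 1.0
                and 0.0 <= self.reporter_fraction <= 1.0):
            raise ConfigError("mixture fractions must lie in [0, 1]")
        if self.D_um / self.pixel_size_um > self.n_pixels:
            raise GeometryError(
                f"lumen of {self.D_um} um does not fit in {self.n_pixels} px "
                f"at {self.pixel_size_um} um/px"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return int(round(self.T_s * self.scan_rate_hz))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return (("vessel", "reporter", "antibody") if self.two_color
                else ("vessel", "reporter"))

    @property
    def truncated_v_mean(self) -> float:
        """Mean of the velocity distribution after truncation at zero."""
        a = -self.v_mean_um_s / self.v_sd_um_s if self.v_sd_um_s > 0 else -np.inf
        if self.v_sd_um_s == 0:
            return self.v_mean_um_s
        return float(stats.truncnorm.mean(a, np.inf,
                                          loc=self.v_mean_um_s,
                                          scale=self.v_sd_um_s))

    @property
    def expected_event_rate(self) -> float:
        """lambda = C * pi (D/2)^2 * mean(v) / 1e12, events per second."""
        flux_ml_s = math.pi * (self.D_um / 2.0) ** 2 * self.truncated_v_mean / UM3_PER_ML
        return self.concentration_per_ml * flux_ml_s

    def metadata(self) -> ScanMetadata:
        return ScanMetadata(
            scan_rate_hz=self.scan_rate_hz,
            pixel_size_um=self.pixel_size_um,
            n_lines=self.n_lines,
            n_pixels=self.n_pixels,
            channel_names=self.channel_names,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown simulation parameters {sorted(unknown)}")
        return cls(**doc)


@dataclass
class GroundTruth:
    """The simulator's truth: generating parameters and the per-event table.

    ``events`` columns: ``arrival_s`` (scan-line crossing time of the cell
    centre), ``d_um``, ``v_um_s``, ``t_ms``, ``lane_px`` (centre pixel),
    ``reporter_positive``, ``antibody_positive``, rendered bounding box
    (``line_start``/``line_end``/``px_start``/``px_end``, half-open) and
    ``truncated``.  Only events visible in the record appear.
    """

    params: SimulationParams
    events: pd.DataFrame
    expected_event_rate: float

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False, float_format="%.12g")


_TRUTH_COLUMNS = [
    "event_id", "arrival_s", "d_um", "v_um_s", "t_ms", "lane_px",
    "reporter_positive", "antibody_positive",
    "line_start", "line_end", "px_start", "px_end", "truncated",
]


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    size: int) -> np.ndarray:
    """Positive-truncated normal draws by rejection."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _lattice_span(center: float, half_extent: float, n: int) -> tuple[int, int]:
    """Half-open index range of lattice cells whose centres lie within
    ``[center - half_extent, center + half_extent]``, clipped to ``[0, n)``;
    never empty (falls back to the cell containing ``center``)."""
    lo = int(np.ceil(center - half_extent - 0.5))
    hi = int(np.floor(center + half_extent - 0.5)) + 1
    if hi <= lo:  # sub-cell extent: keep the containing cell
        lo = int(np.floor(center))
        hi = lo + 1
    return max(lo, 0), min(hi, n)


def draw_ground_truth(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw the Poisson arrival process and per-cell properties (no rendering).

    Separated from :func:`simulate_record` so count statistics (e.g. Poisson
    dispersion across replicates) can be studied without paying for pixels.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params
    md = p.metadata()
    n_lines, n_px = md.n_lines, md.n_pixels

    # arrival margin: generous bound on a single traverse time
    t_max_s = (p.d_mean_um + 6 * p.d_sd_um) / max(p.v_mean_um_s - 3 * p.v_sd_um_s,
                                                  p.v_mean_um_s * 0.05)
    lam = p.expected_event_rate
    window = p.T_s + 2 * t_max_s
    n_arrivals = rng.poisson(lam * window)

    lumen_half_px = p.D_um / p.pixel_size_um / 2.0
    center_px = n_px / 2.0

    rows = []
    occupied: list[tuple[int, int, int, int]] = []
    for _ in range(n_arrivals):
        for _attempt in range(200):
            arrival = rng.uniform(-t_max_s, p.T_s + t_max_s)
            d = float(_truncnorm_draw(rng, p.d_mean_um, p.d_sd_um, 1)[0])
            v = float(_truncnorm_draw(rng, p.v_mean_um_s, p.v_sd_um_s, 1)[0])
            if p.parabolic_profile:
                # Poiseuille sensitivity mode: scale v by the profile at the lane.
                rel = rng.uniform(-1.0, 1.0)
                v *= max(1.0 - rel ** 2, 0.05) * 1.5
            r_px = d / p.pixel_size_um / 2.0
            lane_lo = center_px - lumen_half_px + r_px
            lane_hi = center_px + lumen_half_px - r_px
            lane = rng.uniform(lane_lo, lane_hi) if lane_hi > lane_lo else center_px

            l_center = arrival * p.scan_rate_hz
            b_lines = (d / v) * p.scan_rate_hz / 2.0
            if l_center + b_lines < 0 or l_center - b_lines >= n_lines:
                break  # entirely outside the record; not an event
            l0, l1 = _lattice_span(l_center, b_lines, n_lines)
            p0, p1 = _lattice_span(lane, r_px, n_px)
            if l1 <= l0 or p1 <= p0:
                break
            if p.avoid_overlap:
                m = p.overlap_margin_px
                clash = any(
                    l0 - m < ol1 and ol0 < l1 + m and p0 - m < op1 and op0 < p1 + m
                    for ol0, ol1, op0, op1 in occupied
                )
                if clash:
                    continue  # redraw this cell's placement
            occupied.append((l0, l1, p0, p1))
            truncated = l0 == 0 or l1 == n_lines
            reporter_pos = (bool(rng.random() < p.reporter_fraction)
                            if p.two_color else True)
            antibody_pos = bool(rng.random() < p.positive_fraction) if p.two_color else False
            if p.two_color and not reporter_pos and not antibody_pos:
                antibody_pos = True  # unlabeled cells would be invisible
            rows.append({
                "arrival_s": arrival, "d_um": d, "v_um_s": v,
                "t_ms": d / v * 1000.0, "lane_px": lane,
                "reporter_positive": reporter_pos, "antibody_positive": antibody_pos,
                "line_start": l0, "line_end": l1, "px_start": p0, "px_end": p1,
                "truncated": truncated,
            })
            break

    events = pd.DataFrame(rows, columns=[c for c in _TRUTH_COLUMNS if c != "event_id"])
    if len(events):
        events = events.sort_values(["line_start", "px_start"]).reset_index(drop=True)
    events.insert(0, "event_id", np.arange(len(events)))
    return GroundTruth(params=p, events=events, expected_event_rate=lam)


def _render_event_mask(row: pd.Series, p: SimulationParams) -> np.ndarray:
    """Rasterize one cell as a filled ellipse over its truth bounding box.

    The mask is the ellipse through pixel centres (axes inflated by half a
    pixel) unioned with its equatorial row and column, which guarantees the
    rendered bounding box equals the truth bounding box exactly.
    """
    l0, l1, p0, p1 = (int(row.line_start), int(row.line_end),
                      int(row.px_start), int(row.px_end))
    l_center = row.arrival_s * p.scan_rate_hz
    b = (row.d_um / row.v_um_s) * p.scan_rate_hz / 2.0
    a = row.d_um / p.pixel_size_um / 2.0
    ll = np.arange(l0, l1)[:, None] + 0.5 - l_center
    pp = np.arange(p0, p1)[None, :] + 0.5 - row.lane_px
    mask = (ll / (b + 0.5)) ** 2 + (pp / (a + 0.5)) ** 2 <= 1.0
    mask[np.argmin(np.abs(ll[:, 0])), :] = True  # equator row: full spatial extent
    mask[:, np.argmin(np.abs(pp[0, :]))] = True  # equator column: full temporal extent
    return mask


def simulate_record(
    params: SimulationParams,
    seed: int | None = None,
    *,
    render: bool = True,
    dtype=np.float32,
) -> tuple[Kymograph | None, GroundTruth]:
    """Simulate one line-scan record: (kymograph, ground truth).

    Fully reproducible: the same parameters and seed give a bit-identical
    image and truth table.  With ``render=False`` only the truth is drawn
    and the kymograph is ``None``.
    """
    p = params if seed is None else dataclasses.replace(params, seed=seed)
    rng = np.random.default_rng(p.seed)
    truth = draw_ground_truth(p, rng)
    if not render:
        return None, truth

    md = p.metadata()
    n_lines, n_px = md.n_lines, md.n_pixels
    lumen_half_px = p.D_um / p.pixel_size_um / 2.0
    center_px = n_px / 2.0
    col_centers = np.arange(n_px) + 0.5
    lumen_cols = np.abs(col_centers - center_px) <= lumen_half_px

    n_ch = len(p.channel_names)
    pixels = np.full((n_lines, n_px, n_ch), p.background_level, dtype=dtype)
    pixels[:, lumen_cols, 0] = p.vessel_dye_level
    if p.two_color:
        pixels[:, lumen_cols, 2] = p.antibody_plasma_level

    for _, row in truth.events.iterrows():
        mask = _render_event_mask(row, p)
        l0, l1, p0, p1 = (int(row.line_start), int(row.line_end),
                          int(row.px_start), int(row.px_end))
        if row.reporter_positive:
            patch = pixels[l0:l1, p0:p1, 1]
            np.maximum(patch, np.where(mask, p.reporter_level, patch), out=patch)
        if p.two_color and row.antibody_positive:
            patch = pixels[l0:l1, p0:p1, 2]
            np.maximum(patch, np.where(mask, p.antibody_level, patch), out=patch)
        if p.cells_in_dye_level:
            patch = pixels[l0:l1, p0:p1, 0]
            np.maximum(patch, np.where(mask, p.cells_in_dye_level, patch), out=patch)

    if p.noise_sd > 0:
        pixels += rng.standard_normal(pixels.shape, dtype=np.float32) * dtype(p.noise_sd)
        np.maximum(pixels, 0, out=pixels)

    return Kymograph(pixels=pixels, metadata=md), truth


def write_record(
    kymo: Kymograph,
    truth: GroundTruth,
    out_dir: str | Path,
    stem: str = "record",
) -> dict[str, Path]:
    """Write a simulated record as TIFF + metadata JSON + truth CSV + params JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.tif",
        "metadata": out / f"{stem}.json",
        "truth": out / f"{stem}_truth.csv",
        "params": out / f"{stem}_params.json",
    }
    scan_io.write_kymograph(kymo, paths["image"])
    scan_io.write_scan_metadata_json(kymo.metadata, paths["metadata"])
    truth.to_csv(paths["truth"])
    paths["params"].write_text(
        json.dumps(truth.params.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

#: Measurement schedule (minutes relative to challenge) of the reference
#: longitudinal experiment: baseline plus eight post-injection timepoints.
DEFAULT_SCHEDULE_MIN = (0.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


def simulate_timecourse(
    baseline: SimulationParams,
    effect: dict[str, dict[float, float]],
    *,
    subjects_per_group: int = 6,
    schedule_min: tuple[float, ...] = DEFAULT_SCHEDULE_MIN,
    seed: int | None = None,
    render: bool = True,
):
    """Yield ``(subject_id, group, time_min, kymograph, truth)`` per record.

    ``effect`` maps group label -> {time_min: multiplier on the baseline
    concentration}; missing times default to 1.0.  A 2x step at 60 min for
    the treated group over a flat control reproduces the reference
    inflammation scenario.
    """
    for group, mults in effect.items():
        for t, m in mults.items():
            if m < 0:
                raise ConfigError(
                    f"negative concentration multiplier {m} for group {group!r} at {t}"
                )
    root_seed = baseline.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    child_seeds = iter(ss.generate_state(
        len(effect) * subjects_per_group * len(schedule_min)) % (2 ** 31))
    for group, mults in effect.items():
        for s in range(subjects_per_group):
            subject = f"{group}_{s:02d}"
            for t in schedule_min:
                mult = float(mults.get(t, 1.0))
                p = dataclasses.replace(
                    baseline,
                    concentration_per_ml=baseline.concentration_per_ml * mult,
                    seed=int(next(child_seeds)),
                )
                kymo, truth = simulate_record(p, render=render)
                yield subject, group, float(t), kymo, truth
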