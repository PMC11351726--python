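"""Plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np


def plot_record(results, ax=None, max_lines: int = 4000):
    """Reporter-channel kymograph with detected-event boxes overlaid.

    Long records are cropped to the first ``max_lines`` scan lines for
    display.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    kymo = results.model.kymograph
    cfg = results.model.config
    channel = kymo.channel(cfg.reporter_channel)[:max_lines]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 8))
    md = kymo.metadata
    ax.imshow(channel, aspect="auto", cmap="viridis", origin="upper",
              extent=(0, md.n_pixels * md.pixel_size_um,
                      channel.shape[0] / md.scan_rate_hz * 1000.0, 0))
    for ev in results.events:
        l0, l1, p0, p1 = ev.bbox
        if l0 >= channel.shape[0]:
            continue
        ax.add_patch(Rectangle(
            (p0 * md.pixel_size_um, l0 / md.scan_rate_hz * 1000.0),
            (p1 - p0) * md.pixel_size_um, (l1 - l0) / md.scan_rate_hz * 1000.0,
            fill=False, edgecolor="red", linewidth=0.8,
        ))
    ax.set_xlabel("position along scan line (um)")
    ax.set_ylabel("time (ms)")
    return ax


def plot_timecourse(timecourse, ax=None):
    """Mean +/- SEM concentration curves per group."""
    import matplotlib.pyplot as plt

    stats = timecourse.group_stats()
    if ax is None:
        _, ax = plt.subplots()
    for group, sub in stats.groupby("group"):
        sub = sub.sort_values("time_min")
        ax.errorbar(sub["time_min"], sub["mean"], yerr=sub["sem"],
                    marker="o", capsize=3, label=str(group))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (cells/mL)")
    ax.legend()
    return ax


def plot_dotplot(table, reporter_threshold=None, antibody_threshold=None, ax=None):
    """Two-color dot plot (log-log), with optional gate lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(np.maximum(table["reporter_intensity"], 1e-3),
               np.maximum(table["antibody_intensity"], 1e-3), s=8, alpha=0.7)
    ax.set_xscale("log")
    ax.set_yscale("log")
    if reporter_threshold is not None:
        ax.axvline(reporter_threshold, color="gray", ls="--", lw=0.8)
    if antibody_threshold is not None:
        ax.axhline(antibody_threshold, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("reporter intensity")
    ax.set_ylabel("antibody intensity")
    return ax
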