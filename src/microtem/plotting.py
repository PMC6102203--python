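"""Figure helpers: occupancy maps, count series, hot-spot overlays.

All functions draw onto a supplied matplotlib Axes (or create one) and
return it, so they compose with user figure layouts.
"""

from __future__ import annotations

import numpy as np

CATEGORY_COLORS = {"channel": "tab:blue", "barrier": "tab:orange",
                   "collagen": "tab:red"}


def plot_occupancy(points, ax=None, barrier_thickness_um: float = 40.0):
    """x-z scatter of cell positions, coloured by eventual region.

    Each dot is one (track, frame) record; vertical lines mark the barrier
    band (x = -thickness and x = 0 at the gel face).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for cat, grp in points.groupby("category"):
        ax.scatter(grp["x_um"], grp["z_um"], s=4, alpha=0.4,
                   color=CATEGORY_COLORS.get(cat, "gray"), label=cat)
    for x in (-barrier_thickness_um, 0.0):
        ax.axvline(x, color="k", lw=0.8, ls="--")
    ax.set_xlabel("x (µm, 0 = barrier gel face)")
    ax.set_ylabel("z (µm)")
    ax.legend(markerscale=3, fontsize=8)
    return ax


def plot_count_series(stats, frame_interval_min: float = 20.0, ax=None):
    """n_t over time for the total, barrier and transmigrated counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    t = np.arange(stats.n_frames) * frame_interval_min / 60.0
    ax.plot(t, stats.n_t_tot, label="total (channel+barrier)")
    ax.plot(t, stats.n_t_barrier, label="at barrier")
    ax.plot(t, stats.n_t_ext, label="transmigrated (cumulative)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    return ax


def plot_hotspots(hotspot_set, crossing_events=None, ax=None):
    """Hot spots on the barrier plane, optionally with the crossing events."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if crossing_events is not None and len(crossing_events):
        ax.scatter(crossing_events["crossing_y_um"],
                   crossing_events["crossing_z_um"],
                   s=12, color="gray", label="crossings")
    for h in hotspot_set.hotspots:
        ax.scatter([h.y_um], [h.z_um], s=120, facecolors="none",
                   edgecolors="red", linewidths=1.5)
    ly, lz = hotspot_set.params.get("plane_extent_um", (150.0, 100.0))
    ax.set_xlim(0, ly)
    ax.set_ylim(0, lz)
    ax.set_xlabel("y (µm, along channel)")
    ax.set_ylabel("z (µm)")
    return ax
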