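"""Count, ratio, velocity, occupancy and hot-spot statistics.

The central quantities are time-averaged cell counts
``N_av = (sum_t n_t) / T`` — over all lumen+barrier cells (``N_av_tot``), over
barrier cells (``N_av_barrier``) and over cumulative transmigrated cells
(``N_av_ext``) — and their ratios, which quantify the propensity of cancer
cells to cross the endothelial barrier.  Velocities are pooled across samples
with the inverse-variance weighted mean
``mean = sum_i w_i v_i / sum_i w_i``, ``error = 1 / sqrt(sum_i w_i)``,
``w_i = n_i / sigma_i^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .behavior import classify_all, smooth_regions
from .regions import BARRIER, CHANNEL, GEL


# ---------------------------------------------------------------------------
# count series and transmigration ratios

@dataclass
class SampleStats:
    n_frames: int
    n_t_tot: np.ndarray
    n_t_barrier: np.ndarray
    n_t_ext: np.ndarray
    N_av_tot: float
    N_av_barrier: float
    N_av_ext: float
    behavior_frequencies: dict = field(default_factory=dict)


def count_series(
    tracks: pd.DataFrame,
    n_frames: int,
    region_filter: str = "total",
    min_visit: int = 2,
) -> tuple[np.ndarray, float]:
    """Per-frame count series ``n_t`` and its time average ``N_av``.

    ``region_filter``:

    - ``"total"`` — cells whose smoothed region at frame t is lumen or
      barrier (the cells "in the channel and at the barrier");
    - ``"barrier"`` — smoothed region is barrier;
    - ``"ext"`` — cumulative count of tracks whose first smoothed gel frame is
      <= t (crossings are irreversible, so the count is monotone);
    - ``"gel"`` — the per-frame gel-resident count (the non-cumulative
      variant of the transmigrated population).

    ``N_av = (sum_t n_t) / T`` over the ``n_frames`` frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_t = np.zeros(n_frames, dtype=float)
    if region_filter == "ext":
        behavior = classify_all(tracks, min_visit=min_visit)
        for fg in behavior["first_gel_frame"].dropna():
            n_t[int(fg):] += 1
    elif region_filter in ("total", "barrier", "gel"):
        wanted = ({CHANNEL, BARRIER} if region_filter == "total"
                  else {BARRIER} if region_filter == "barrier" else {GEL})
        for _, grp in tracks.groupby("track_id"):
            grp = grp.sort_values("frame")
            smoothed = smooth_regions(list(grp["region"]), min_visit=min_visit)
            for f, r in zip(grp["frame"], smoothed):
                if r in wanted and 0 <= f < n_frames:
                    n_t[int(f)] += 1
    else:
        raise ValueError(f"unknown region_filter {region_filter!r}")
    return n_t, float(n_t.mean())


def sample_stats(tracks: pd.DataFrame, n_frames: int, min_visit: int = 2) -> SampleStats:
    from .behavior import behavior_frequencies

    n_tot, N_tot = count_series(tracks, n_frames, "total", min_visit)
    n_bar, N_bar = count_series(tracks, n_frames, "barrier", min_visit)
    n_ext, N_ext = count_series(tracks, n_frames, "ext", min_visit)
    freqs = behavior_frequencies(classify_all(tracks, min_visit=min_visit))
    return SampleStats(
        n_frames=n_frames, n_t_tot=n_tot, n_t_barrier=n_bar, n_t_ext=n_ext,
        N_av_tot=N_tot, N_av_barrier=N_bar, N_av_ext=N_ext,
        behavior_frequencies=freqs,
    )


@dataclass
class TransmigrationRatios:
    r_tot: float        # N_av_ext / N_av_tot
    r_barrier: float    # N_av_ext / N_av_barrier
    no_transmigration: bool
    flags: list = field(default_factory=list)


def transmigration_ratios(stats: SampleStats) -> TransmigrationRatios:
    """The two transmigration ratios; zero denominators flag, not raise."""
    flags = []
    if stats.N_av_ext == 0:
        return TransmigrationRatios(0.0, 0.0, True, ["no transmigration"])
    if stats.N_av_tot <= 0:
        flags.append("zero total denominator")
        r_tot = np.nan
    else:
        r_tot = stats.N_av_ext / stats.N_av_tot
    if stats.N_av_barrier <= 0:
        flags.append("zero barrier denominator")
        r_barrier = np.nan
    else:
        r_barrier = stats.N_av_ext / stats.N_av_barrier
    return TransmigrationRatios(float(r_tot), float(r_barrier), False, flags)


def pooled_ratios(stats_list: list[SampleStats]) -> TransmigrationRatios:
    """Ratios of summed time-averaged counts across samples."""
    ext = sum(s.N_av_ext for s in stats_list)
    tot = sum(s.N_av_tot for s in stats_list)
    bar = sum(s.N_av_barrier for s in stats_list)
    pooled = SampleStats(
        n_frames=max(s.n_frames for s in stats_list),
        n_t_tot=np.zeros(1), n_t_barrier=np.zeros(1), n_t_ext=np.zeros(1),
        N_av_tot=tot, N_av_barrier=bar, N_av_ext=ext,
    )
    return transmigration_ratios(pooled)


def fit_zero_intercept(x, y) -> tuple[float, float]:
    """Least-squares slope through the origin, with its standard error.

    ``slope = sum(x y) / sum(x^2)``; the SE comes from the residual variance
    with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x are zero: slope undefined")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    se = float(np.sqrt(np.sum(resid**2) / ((x.size - 1) * sxx)))
    return slope, se


# ---------------------------------------------------------------------------
# velocities

def velocities(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-interval velocity records from a tidy tracks table.

    For each pair of consecutive records of a track: ``v_x = dx/dt``,
    ``v_y = dy/dt`` and ``speed = sqrt(dx^2 + dy^2)/dt`` in µm/min.  The
    speed is the in-plane displacement rate: the x and y components are the
    measured ones, while the z-sampling (coarse slice argmax) is too noisy to
    contribute a meaningful velocity component.  Each record is attributed to
    the region at the interval's start frame.
    """
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"track {tid} has duplicate frames")
        t = grp["t_min"].to_numpy(dtype=float)
        x = grp["x_um"].to_numpy(dtype=float)
        y = grp["y_um"].to_numpy(dtype=float)
        regions = grp["region"].to_numpy()
        dt = np.diff(t)
        dx = np.diff(x)
        dy = np.diff(y)
        for i in range(len(dt)):
            rows.append({
                "track_id": tid,
                "frame": int(frames[i]),
                "region": regions[i],
                "v_x": dx[i] / dt[i],
                "v_y": dy[i] / dt[i],
                "speed": float(np.hypot(dx[i], dy[i]) / dt[i]),
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "region", "v_x", "v_y", "speed"])


@dataclass
class VelocitySummary:
    """One sample's velocity summary: mean, SD, cell count and weight."""

    mean: float
    sd: float
    n: int

    @property
    def weight(self) -> float:
        if self.sd <= 0:
            raise ValueError(
                "sample SD is zero; configure a variance floor before pooling"
            )
        return self.n / self.sd**2


@dataclass
class PooledVelocity:
    mean: float
    error: float
    n_samples: int


def sample_velocity_summary(
    vel: pd.DataFrame, region: str | None = None, quantity: str = "speed",
) -> VelocitySummary:
    """Mean/SD/cell-count of one sample's per-interval velocities.

    ``n`` is the number of cells (distinct tracks) contributing, matching the
    weight definition ``w = n / sigma^2`` with n the cells of the sample.
    """
    if region is not None:
        vel = vel[vel["region"] == region]
    vals = vel[quantity].to_numpy(dtype=float)
    if vals.size == 0:
        return VelocitySummary(np.nan, np.nan, 0)
    n_cells = int(vel["track_id"].nunique())
    return VelocitySummary(float(vals.mean()), float(vals.std(ddof=1)), n_cells)


def pooled_velocity(summaries: list[VelocitySummary]) -> PooledVelocity:
    """Inverse-variance weighted pooling across samples (exact formulas)."""
    if not summaries:
        raise ValueError("no samples to pool")
    weights = np.array([s.weight for s in summaries])  # raises on sd == 0
    means = np.array([s.mean for s in summaries])
    wsum = weights.sum()
    return PooledVelocity(
        mean=float((weights * means).sum() / wsum),
        error=float(1.0 / np.sqrt(wsum)),
        n_samples=len(summaries),
    )


# ---------------------------------------------------------------------------
# occupancy maps and hot spots

#: Fig-6-style eventual-region categories
CATEGORY_BY_FINAL = {CHANNEL: "channel", BARRIER: "barrier", GEL: "collagen"}


def occupancy_map(
    tracks: pd.DataFrame,
    min_visit: int = 2,
    grid_step_um: float | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """(x, z) occupancy records categorized by each track's eventual region.

    Every (track, frame) record contributes one point; the category says
    whether the cell eventually entered the channel, barrier or collagen.
    Optionally also returns a 2D histogram on a ``grid_step_um`` grid.
    """
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        smoothed = smooth_regions(list(grp["region"]), min_visit=min_visit)
        if GEL in smoothed:
            cat = "collagen"
        else:
            cat = CATEGORY_BY_FINAL[smoothed[-1]]
        for _, row in grp.iterrows():
            rows.append({
                "x_um": row["x_um"], "z_um": row["z_um"],
                "frame": int(row["frame"]), "track_id": tid, "category": cat,
            })
    points = pd.DataFrame(rows, columns=["x_um", "z_um", "frame", "track_id", "category"])
    hist = None
    if grid_step_um is not None and len(points):
        x = points["x_um"].to_numpy()
        z = points["z_um"].to_numpy()
        x_edges = np.arange(x.min(), x.max() + 2 * grid_step_um, grid_step_um)
        z_edges = np.arange(z.min(), z.max() + 2 * grid_step_um, grid_step_um)
        counts, _, _ = np.histogram2d(x, z, bins=[x_edges, z_edges])
        hist = {"counts": counts, "x_edges": x_edges, "z_edges": z_edges}
    return points, hist


@dataclass
class Hotspot:
    y_um: float
    z_um: float
    density: float
    percentile: float


@dataclass
class HotspotSet:
    hotspots: list[Hotspot]
    no_transmigration: bool
    params: dict = field(default_factory=dict)


def _kde_grid(points: np.ndarray, gy: np.ndarray, gz: np.ndarray, bw: float) -> np.ndarray:
    """Gaussian KDE with fixed isotropic bandwidth, evaluated on a grid."""
    yy = gy[:, None, None] - points[None, None, :, 0]
    zz = gz[None, :, None] - points[None, None, :, 1]
    dens = np.exp(-(yy**2 + zz**2) / (2 * bw**2)).sum(axis=2)
    return dens / (2 * np.pi * bw**2 * len(points))


def detect_hotspots(
    crossing_events: pd.DataFrame,
    plane_extent_um: tuple[float, float] = (150.0, 100.0),
    bandwidth_um: float = 10.0,
    n_null: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    grid_step_um: float = 2.0,
) -> HotspotSet:
    """Significant clusters of crossing positions on the barrier plane.

    A fixed-bandwidth Gaussian KDE of the crossing (y, z) positions is
    evaluated on a grid over the accessible barrier area; local density
    maxima are hot-spot candidates.  Significance is Monte-Carlo: the same
    number of events is redistributed uniformly over the plane ``n_null``
    times and each candidate's density is ranked against the null
    distribution of *maximum* grid densities (so the family-wise false-positive
    rate under a uniform pattern is at most ``alpha``).  Candidates at
    percentile >= 1 - alpha are declared hot spots.
    """
    params = {"bandwidth_um": bandwidth_um, "n_null": n_null, "alpha": alpha,
              "plane_extent_um": plane_extent_um}
    if len(crossing_events) == 0:
        return HotspotSet([], True, params)
    pts = crossing_events[["crossing_y_um", "crossing_z_um"]].dropna().to_numpy(dtype=float)
    if len(pts) == 0:
        return HotspotSet([], True, params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ly, lz = plane_extent_um
    gy = np.arange(0, ly + grid_step_um, grid_step_um)
    gz = np.arange(0, lz + grid_step_um, grid_step_um)
    dens = _kde_grid(pts, gy, gz, bandwidth_um)

    min_dist = max(1, int(round(bandwidth_um / grid_step_um)))
    peaks = peak_local_max(dens, min_distance=min_dist, exclude_border=False)
    if len(peaks) == 0:
        peaks = np.array([np.unravel_index(np.argmax(dens), dens.shape)])

    null_max = np.empty(n_null)
    n_events = len(pts)
    for k in range(n_null):
        u = np.column_stack([rng.uniform(0, ly, n_events), rng.uniform(0, lz, n_events)])
        null_max[k] = _kde_grid(u, gy, gz, bandwidth_um).max()

    hotspots = []
    for iy, iz in peaks:
        d = dens[iy, iz]
        pct = float((null_max < d).mean())
        if pct >= 1 - alpha:
            hotspots.append(Hotspot(float(gy[iy]), float(gz[iz]), float(d), pct))
    hotspots.sort(key=lambda h: -h.density)
    return HotspotSet(hotspots, False, params)
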