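"""Synthetic two-channel confocal time-lapses with complete ground truth.

The generator emulates the imaging conditions of the microvessel assay — a
two-channel (brightfield + GFP) z-stack over the ~100 µm channel height at
1.5 µm steps, acquired every 20 min over 15 h, of a field of view holding
10–50 GFP-labelled cancer cells — so that every downstream stage (focus
stacking, registration, segmentation, tracking, statistics) is testable
against known cell masks, nucleus positions, trajectories and crossing
events without any external data.

Cells are ellipsoids with a bright GFP bulk and a dark spherical nucleus
core; brightfield shows a dark cell edge, sharp at the slice nearest the
cell's z-centre and Gaussian-blurred in proportion to axial distance, plus
static dark pillar rectangles.  Motion is a persistent random walk with
region-dependent mean speed, a constant gravity drift in z with a reflecting
floor, stochastic barrier crossing, and irreversible gel entry.  A bounded
random-walk stage drift shifts both channels; noise (Gaussian read noise plus
a Gaussian shot-noise approximation) is added last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .regions import BARRIER, GEL, RegionLayout, region_of_x
from .stack_io import StackSeries, write_stack

#: region mean speeds (µm/min) observed in the endothelialised microvessel
MICROVESSEL_SPEEDS = {"channel": 0.52, "barrier": 0.51, "gel": 0.50}
#: region mean speeds (µm/min) observed in the endothelium-free reference system
REFERENCE_SPEEDS = {"channel": 0.57, "barrier": 0.45, "gel": 0.45}


@dataclass
class SimulationConfig:
    """Study conditions of one simulated sample.

    Geometry: the imaged width covers the 120 µm lumen, the 40 µm barrier
    band and a 60 µm gel margin (x from -160 to +60 µm, matching the
    occupancy-map axis extents); length ~413 µm along the channel; 1.5 µm
    z-step over ~100 µm; frames every 20 min over 15 h.
    """

    fov_width_um: float = 220.0
    fov_length_um: float = 413.0
    pixel_size_um: float = 0.8
    z_slices: int = 67
    z_step_um: float = 1.5
    n_frames: int = 45
    frame_interval_min: float = 20.0
    n_cells: int = 22
    channel_width_um: float = 120.0
    barrier_thickness_um: float = 40.0
    speed_by_region_um_per_min: dict = field(
        default_factory=lambda: dict(MICROVESSEL_SPEEDS))
    speed_cv: float = 0.3
    persistence_sd_rad: float = 1.2
    p_cross_per_frame: float = 0.015
    crossing_proximity_um: float = 12.0  # cells must be this close to the gel face
    initial_x_max_um: float = -1.0       # seeding edge: how close to the gel
                                         # face cells start (rounded-lumen
                                         # geometry keeps cells off the wall)
    gravity_bias_um_per_min: float = 0.2
    z_step_sd_um: float = 2.0
    drift_amplitude_px: float = 5.0
    drift_step_sd_px: float = 0.8
    hotspot_centers_yz_um: list | None = None
    hotspot_radius_um: float = 20.0
    # cell geometry
    cell_radius_um_mean: float = 8.5
    cell_radius_um_sd: float = 1.2
    cell_aspect_max: float = 1.5
    nucleus_radius_um: float = 3.5
    nucleus_offset_sd_um: float = 1.2
    cell_z_halfwidth_um: float = 5.0
    # optics / noise
    gfp_amplitude: float = 0.9
    gfp_background: float = 0.02
    bf_background: float = 0.55
    edge_sigma_px: float = 1.2
    defocus_sigma0_px: float = 0.8
    defocus_k_px_per_um: float = 0.25
    defocus_range_um: float = 18.0
    gaussian_sd: float = 0.01
    poisson_scale: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fov_width_um", "fov_length_um", "pixel_size_um",
                     "z_step_um", "frame_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z_slices < 1 or self.n_frames < 1 or self.n_cells < 1:
            raise ValueError("z_slices, n_frames and n_cells must be >= 1")
        if not 0.0 <= self.p_cross_per_frame <= 1.0:
            raise ValueError("p_cross_per_frame must be in [0, 1]")
        if self.barrier_thickness_um > self.fov_width_um:
            raise ValueError("barrier band wider than the field of view")
        if self.channel_width_um + self.barrier_thickness_um >= self.fov_width_um:
            raise ValueError(
                "no gel margin: fov_width_um must exceed channel + barrier width"
            )
        lumen_area = (self.channel_width_um + self.barrier_thickness_um) * self.fov_length_um
        mean_cell_area = np.pi * self.cell_radius_um_mean**2
        if self.n_cells * mean_cell_area > 0.6 * lumen_area:
            raise ValueError(
                f"n_cells={self.n_cells} exceeds the packable lumen area"
            )

    # --- derived geometry -------------------------------------------------
    @property
    def x_min_um(self) -> float:
        return -(self.channel_width_um + self.barrier_thickness_um)

    @property
    def x_max_um(self) -> float:
        return self.x_min_um + self.fov_width_um

    @property
    def shape_yx(self) -> tuple[int, int]:
        return (int(round(self.fov_length_um / self.pixel_size_um)),
                int(round(self.fov_width_um / self.pixel_size_um)))

    @property
    def z_max_um(self) -> float:
        return (self.z_slices - 1) * self.z_step_um


def pillar_rects_um(config: SimulationConfig) -> list[tuple[float, float, float, float]]:
    """(y0, y1, x0, x1) µm boxes of the static pillars flanking the gel face.

    Pillars 15 µm long with 150 µm gaps (the accessible barrier area between
    pillars is 150 µm along the channel), sitting just inside the gel.
    """
    rects = []
    pitch, length = 165.0, 15.0
    y = 0.0
    while y < config.fov_length_um:
        rects.append((y, min(y + length, config.fov_length_um), 2.0, 22.0))
        y += pitch
    return rects


def generate_layout(config: SimulationConfig) -> RegionLayout:
    """Region layout (bands + pillar-corner fiducial windows) for a config."""
    ny, nx = config.shape_yx
    px = config.pixel_size_um
    windows = []
    for (y0, y1, x0, x1) in pillar_rects_um(config):
        # a window around the pillar's lower-left corner, clipped to the image
        cy = int(round(y0 / px))
        cx = int(round((x0 - config.x_min_um) / px))
        half = int(round(12.0 / px))
        wy0, wy1 = max(0, cy - half), min(ny, cy + half)
        wx0, wx1 = max(0, cx - half), min(nx, cx + half)
        if wy1 - wy0 >= half and wx1 - wx0 >= half:
            windows.append((wy0, wy1, wx0, wx1))
    return RegionLayout(
        shape=(ny, nx),
        pixel_size_um=px,
        x_origin_um=config.x_min_um,
        barrier_thickness_um=config.barrier_thickness_um,
        pillar_windows=windows,
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Complete per-frame truth of one simulated sample."""

    config: SimulationConfig
    tracks: pd.DataFrame      # track_id, frame, t_min, x_um, y_um, z_um, region,
                              # nucleus_x_um, nucleus_y_um
    crossings: pd.DataFrame   # track_id, frame, y_um, z_um
    cells: pd.DataFrame       # track_id, a_um, b_um, phi, nuc_dx_um, nuc_dy_um
    drift_px: np.ndarray      # (n_frames, 2) float (dx, dy)

    def positions(self, frame: int) -> pd.DataFrame:
        return self.tracks[self.tracks["frame"] == frame]

    def mask(self, frame: int, track_id: int) -> np.ndarray:
        """Boolean footprint (ellipse) of one cell at one frame, undrifted."""
        cfg = self.config
        ny, nx = cfg.shape_yx
        row = self.tracks[(self.tracks["frame"] == frame)
                          & (self.tracks["track_id"] == track_id)].iloc[0]
        cell = self.cells[self.cells["track_id"] == track_id].iloc[0]
        yy, xx = np.mgrid[0:ny, 0:nx]
        px = cfg.pixel_size_um
        dx = xx * px + cfg.x_min_um - row["x_um"]
        dy = yy * px - row["y_um"]
        c, s = np.cos(cell["phi"]), np.sin(cell["phi"])
        u = (dx * c + dy * s) / cell["a_um"]
        v = (-dx * s + dy * c) / cell["b_um"]
        return u**2 + v**2 <= 1.0

    def label_image(self, frame: int) -> np.ndarray:
        """Ground-truth label mask of one frame (later track ids overwrite
        earlier ones where footprints overlap)."""
        ny, nx = self.config.shape_yx
        out = np.zeros((ny, nx), dtype=np.int32)
        for tid in self.positions(frame)["track_id"]:
            out[self.mask(frame, int(tid))] = int(tid) + 1
        return out

    def area_um2(self, track_id: int) -> float:
        cell = self.cells[self.cells["track_id"] == track_id].iloc[0]
        return float(np.pi * cell["a_um"] * cell["b_um"])


def _reflect_array(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.full_like(v, lo)
    v = (v - lo) % (2 * span)
    return lo + (span - np.abs(v - span))


def simulate_tracks(config: SimulationConfig, seed=None) -> GroundTruth:
    """Simulate motion, crossings and drift (no image rendering).

    Ground truth obeys the hard invariants of the system: once a track's
    region is gel it never returns (irreversible transendothelial migration),
    and crossing only happens from the proximal barrier with probability
    ``p_cross_per_frame`` per frame (optionally gated to hot-spot attractors).
    """
    cfg = config
    seed_val = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed_val)
    # separate streams with fixed per-frame consumption, so that a change in
    # the crossing probability alone never perturbs another cell's randomness
    seed_seq = seed_val if isinstance(seed_val, (list, tuple)) else [seed_val]
    rng_cross = np.random.default_rng(list(seed_seq) + [104_729])
    rng_motion = np.random.default_rng(list(seed_seq) + [1_299_709])
    n, T, dt = cfg.n_cells, cfg.n_frames, cfg.frame_interval_min

    # fixed per-cell geometry
    r = np.clip(rng.normal(cfg.cell_radius_um_mean, cfg.cell_radius_um_sd, n),
                0.6 * cfg.cell_radius_um_mean, 1.5 * cfg.cell_radius_um_mean)
    aspect = rng.uniform(1.0, cfg.cell_aspect_max, n)
    a = r * np.sqrt(aspect)
    b = r / np.sqrt(aspect)
    phi = rng.uniform(0, np.pi, n)
    nuc_off = rng.normal(0, cfg.nucleus_offset_sd_um, (n, 2))

    # the barrier constrains the *nucleus* (the tracked point): a cell whose
    # centre hugs the wall must not place its nucleus across the gel face
    nuc_dx_pos = np.maximum(nuc_off[:, 0], 0.0)
    nuc_dx_neg = np.minimum(nuc_off[:, 0], 0.0)

    # initial state
    x = np.minimum(rng.uniform(cfg.x_min_um + 6.0, cfg.initial_x_max_um, n),
                   -1.0 - nuc_dx_pos)
    y = rng.uniform(4.0, cfg.fov_length_um - 4.0, n)
    z = np.minimum(np.abs(rng.normal(0, 15.0, n)) + 0.5, cfg.z_max_um - 0.5)
    theta = rng.uniform(0, 2 * np.pi, n)
    crossed = np.zeros(n, dtype=bool)

    speed_cv2 = cfg.speed_cv**2
    events = []
    frames_x = np.empty((T, n))
    frames_y = np.empty((T, n))
    frames_z = np.empty((T, n))
    frames_region = np.empty((T, n), dtype=object)
    speed_codes = {name: cfg.speed_by_region_um_per_min[name] * dt
                   for name in (GEL, BARRIER, "channel")}

    def regions_now() -> np.ndarray:
        # region membership is decided by the nucleus, the tracked point
        base = region_of_x(x + nuc_off[:, 0], cfg.barrier_thickness_um)
        return np.where(crossed, GEL, base)

    def record(frame: int) -> None:
        frames_x[frame] = x
        frames_y[frame] = y
        frames_z[frame] = z
        frames_region[frame] = regions_now()

    record(0)
    for frame in range(1, T):
        # barrier crossing decisions (before the step); only cells in contact
        # with the gel face (proximal barrier) can transmigrate
        eligible = (~crossed) & (x >= -cfg.crossing_proximity_um)
        if cfg.hotspot_centers_yz_um:
            near = np.zeros(n, dtype=bool)
            for hy, hz in cfg.hotspot_centers_yz_um:
                near |= np.hypot(y - hy, z - hz) <= cfg.hotspot_radius_um
            eligible &= near
        draws = rng_cross.random(n)
        jumps = rng_cross.uniform(0.5, 3.5, n)  # drawn for all cells: fixed count
        crossers = np.flatnonzero(eligible & (draws < cfg.p_cross_per_frame))
        if crossers.size:
            crossed[crossers] = True
            for i in crossers:
                events.append((int(i), frame, y[i], z[i]))
            x[crossers] = 0.5 - nuc_dx_neg[crossers] + jumps[crossers]

        # persistent random walk; direction retries at the walls keep the
        # step length (and hence the per-interval speed) unbiased.  Retries
        # use deterministic golden-angle rotations so wall contact does not
        # consume stream randomness.
        mean_step = np.array([speed_codes[r] for r in regions_now()])
        step = rng_motion.gamma(1.0 / speed_cv2, 1.0, n) * (mean_step * speed_cv2)
        theta += rng_motion.normal(0, cfg.persistence_sd_rad, n)
        x_lo = np.where(crossed, 0.5 - nuc_dx_neg, cfg.x_min_um + 1.0)
        x_hi = np.where(crossed, cfg.x_max_um - 1.0, -0.5 - nuc_dx_pos)
        y_lo, y_hi = 1.0, cfg.fov_length_um - 1.0
        ang = theta.copy()
        nx_ = x + step * np.cos(ang)
        ny_ = y + step * np.sin(ang)
        bad = ~((x_lo <= nx_) & (nx_ <= x_hi) & (y_lo <= ny_) & (ny_ <= y_hi))
        golden = 2.399963229728653
        for k in range(1, 61):
            if not bad.any():
                break
            ang[bad] = theta[bad] + k * golden
            nx_[bad] = x[bad] + step[bad] * np.cos(ang[bad])
            ny_[bad] = y[bad] + step[bad] * np.sin(ang[bad])
            bad = ~((x_lo <= nx_) & (nx_ <= x_hi) & (y_lo <= ny_) & (ny_ <= y_hi))
        if bad.any():  # cornered: stay put this frame
            nx_[bad] = np.minimum(np.maximum(x[bad], x_lo[bad]), x_hi[bad])
            ny_[bad] = np.minimum(np.maximum(y[bad], y_lo), y_hi)
            ang[bad] = theta[bad]
        x, y, theta = nx_, ny_, ang
        z_new = (z - cfg.gravity_bias_um_per_min * dt
                 + rng_motion.normal(0, cfg.z_step_sd_um, n))
        z = _reflect_array(z_new, 0.5, cfg.z_max_um - 0.5)
        record(frame)

    # bounded random-walk stage drift, zero at frame 0
    drift = np.zeros((T, 2))
    for frame in range(1, T):
        drift[frame] = np.clip(
            drift[frame - 1] + rng.normal(0, cfg.drift_step_sd_px, 2),
            -cfg.drift_amplitude_px, cfg.drift_amplitude_px,
        )

    frame_idx = np.repeat(np.arange(T), n)
    tracks = pd.DataFrame({
        "track_id": np.tile(np.arange(n), T),
        "frame": frame_idx,
        "t_min": frame_idx * dt,
        "x_um": frames_x.ravel(),
        "y_um": frames_y.ravel(),
        "z_um": frames_z.ravel(),
        "region": frames_region.ravel(),
        "nucleus_x_um": frames_x.ravel() + np.tile(nuc_off[:, 0], T),
        "nucleus_y_um": frames_y.ravel() + np.tile(nuc_off[:, 1], T),
    })
    crossings = pd.DataFrame(events, columns=["track_id", "frame", "y_um", "z_um"])
    cells = pd.DataFrame({
        "track_id": np.arange(n), "a_um": a, "b_um": b, "phi": phi,
        "nuc_dx_um": nuc_off[:, 0], "nuc_dy_um": nuc_off[:, 1],
    })
    return GroundTruth(config=cfg, tracks=tracks, crossings=crossings,
                       cells=cells, drift_px=drift)


# ---------------------------------------------------------------------------
# rendering


def _soft_rect(coords: np.ndarray, lo: float, hi: float, soft: float = 1.0) -> np.ndarray:
    return np.clip((coords - lo) / soft, 0, 1) * np.clip((hi - coords) / soft, 0, 1)


def render_frame(config: SimulationConfig, truth: GroundTruth, frame: int,
                 noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame: (brightfield, gfp) volumes of shape (z, y, x)."""
    cfg = config
    ny, nx = cfg.shape_yx
    px = cfg.pixel_size_um
    nz = cfg.z_slices
    dx_px, dy_px = truth.drift_px[frame]

    gfp = np.full((nz, ny, nx), cfg.gfp_background, dtype=np.float32)
    bf = np.full((nz, ny, nx), cfg.bf_background, dtype=np.float32)

    # static pillars (drift applies: the whole image shifts together)
    ygrid = np.arange(ny, dtype=np.float32)[:, None]
    xgrid = np.arange(nx, dtype=np.float32)[None, :]
    pillar = np.zeros((ny, nx), dtype=np.float32)
    for (y0, y1, x0, x1) in pillar_rects_um(cfg):
        ry = _soft_rect(ygrid, y0 / px + dy_px, y1 / px + dy_px)
        rx = _soft_rect(xgrid, (x0 - cfg.x_min_um) / px + dx_px,
                        (x1 - cfg.x_min_um) / px + dx_px)
        pillar = np.maximum(pillar, ry * rx)
    bf -= 0.35 * pillar[np.newaxis]

    z_levels = np.arange(nz, dtype=np.float32) * cfg.z_step_um
    positions = truth.positions(frame)
    for _, row in positions.iterrows():
        cell = truth.cells[truth.cells["track_id"] == row["track_id"]].iloc[0]
        a_px, b_px = cell["a_um"] / px, cell["b_um"] / px
        cx = (row["x_um"] - cfg.x_min_um) / px + dx_px
        cy = row["y_um"] / px + dy_px
        zc = row["z_um"]

        pad = int(np.ceil(max(a_px, b_px))) + 20
        wx0, wx1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
        wy0, wy1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
        sx0, sx1 = max(0, wx0), min(nx, wx1)
        sy0, sy1 = max(0, wy0), min(ny, wy1)
        if sx0 >= sx1 or sy0 >= sy1:
            continue
        yy = np.arange(wy0, wy1, dtype=np.float32)[:, None] - cy
        xx = np.arange(wx0, wx1, dtype=np.float32)[None, :] - cx
        c, s = np.cos(cell["phi"]), np.sin(cell["phi"])
        u = (xx * c + yy * s) / a_px
        v = (-xx * s + yy * c) / b_px
        ellipse = (u**2 + v**2 <= 1.0).astype(np.float32)
        body = ndimage.gaussian_filter(ellipse, cfg.edge_sigma_px)

        # dark nucleus core, constant through the cell height so the
        # max-projection keeps the dark spot
        nyy = yy - (cell["nuc_dy_um"] / px)
        nxx = xx - (cell["nuc_dx_um"] / px)
        nuc = (nxx**2 + nyy**2 <= (cfg.nucleus_radius_um / px)**2).astype(np.float32)
        nuc = np.clip(ndimage.gaussian_filter(nuc, 1.0), 0, 1)
        cell2d = cfg.gfp_amplitude * body * (1.0 - 0.75 * nuc)

        crop = (slice(sy0 - wy0, sy1 - wy0), slice(sx0 - wx0, sx1 - wx0))
        tgt = (slice(sy0, sy1), slice(sx0, sx1))

        zw = np.exp(-0.5 * ((z_levels - zc) / cfg.cell_z_halfwidth_um) ** 2)
        zsel = np.flatnonzero(zw > 1e-3)
        for zi in zsel:
            gfp[zi][tgt] += zw[zi] * cell2d[crop]

        # brightfield edge ring, sharp at the cell's own level
        ring = 4.0 * body * (1.0 - body)
        for zi in range(nz):
            dz = abs(z_levels[zi] - zc)
            if dz > cfg.defocus_range_um:
                continue
            sigma = cfg.defocus_sigma0_px + cfg.defocus_k_px_per_um * dz
            blurred = ndimage.gaussian_filter(ring, sigma)
            bf[zi][tgt] -= 0.45 * blurred[crop]

    if noise:
        rng = np.random.default_rng([cfg.seed, 7919, frame])
        for vol in (gfp, bf):
            # read noise + Gaussian approximation of photon shot noise
            sd = np.sqrt(cfg.gaussian_sd**2
                         + np.clip(vol, 0, None) / cfg.poisson_scale)
            vol += rng.standard_normal(vol.shape, dtype=np.float32) * sd
    np.clip(gfp, 0, None, out=gfp)
    np.clip(bf, 0, None, out=bf)
    return bf, gfp


class SyntheticSource:
    """Frame-on-demand view of a simulated sample (streams, never stores the
    full 4D stack)."""

    def __init__(self, config: SimulationConfig, truth: GroundTruth | None = None,
                 noise: bool = True):
        self.config = config
        self.truth = truth if truth is not None else simulate_tracks(config)
        self.noise = noise

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def get_frame(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        return render_frame(self.config, self.truth, t, noise=self.noise)


def simulate_timelapse(config: SimulationConfig,
                       noise: bool = True) -> tuple[StackSeries, GroundTruth]:
    """Full in-memory simulation: a canonical StackSeries plus ground truth.

    Suitable for small configurations; for long runs prefer the streaming
    :class:`SyntheticSource`.
    """
    truth = simulate_tracks(config)
    ny, nx = config.shape_yx
    data = np.empty((config.n_frames, config.z_slices, 2, ny, nx), dtype=np.float32)
    for t in range(config.n_frames):
        bf, gfp = render_frame(config, truth, t, noise=noise)
        data[t, :, 0] = bf
        data[t, :, 1] = gfp
    series = StackSeries(
        data=data,
        channels=["brightfield", "gfp"],
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        frame_interval_min=config.frame_interval_min,
        metadata={"seed": config.seed},
    )
    return series, truth


def write_dataset(series: StackSeries, truth: GroundTruth, out_dir: str | Path) -> dict:
    """Write OME-TIFF (TZCYX) plus ground-truth CSVs and a config manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": write_stack(series, out_dir / "stack.ome.tif"),
        "tracks": out_dir / "truth_tracks.csv",
        "crossings": out_dir / "truth_crossings.csv",
        "manifest": out_dir / "manifest.json",
    }
    truth.tracks.to_csv(paths["tracks"], index=False)
    truth.crossings.to_csv(paths["crossings"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": asdict(truth.config),
                   "drift_px": truth.drift_px.tolist()}, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# ground-truth statistics and calibration


def ground_truth_ratios(truth: GroundTruth) -> tuple[float, float, float, float]:
    """(N_av_ext, N_av_tot, N_av_barrier, r_barrier) from ground-truth tracks.

    Uses the same count definitions as the pipeline statistics (including the
    2-frame visit smoothing), so a calibration on ground truth and a
    measurement on pipeline output quantify the same estimand.
    """
    from .stats import sample_stats

    s = sample_stats(truth.tracks, truth.config.n_frames)
    r_barrier = s.N_av_ext / s.N_av_barrier if s.N_av_barrier > 0 else np.nan
    return s.N_av_ext, s.N_av_tot, s.N_av_barrier, float(r_barrier)


def calibrate_crossing_probability(
    config: SimulationConfig,
    target_r_barrier: float,
    n_reps: int = 40,
    seed: int = 202_306,
    seeds: list | None = None,
    bracket: tuple[float, float] = (1e-4, 0.2),
) -> float:
    """Solve for the per-frame crossing probability at which the pooled
    ground-truth ``N_av_ext / N_av_barrier`` equals ``target_r_barrier``.

    With ``seeds`` given, the calibration is on the *realized* ground truth
    of exactly those samples (the study-condition calibration: the generated
    samples' ground-truth ratio matches the target, so downstream recovery is
    judged against pipeline error only).  Otherwise ``n_reps`` replicates
    seeded from ``seed`` estimate the expected ratio.  Common random numbers
    across candidate probabilities make the objective monotone; only ground
    truth is consulted, never pipeline output.
    """
    from dataclasses import replace

    seed_list = list(seeds) if seeds is not None else [[seed, i] for i in range(n_reps)]

    def pooled_ratio(p: float) -> float:
        ext = bar = 0.0
        for s in seed_list:
            cfg = replace(config, p_cross_per_frame=p)
            truth = simulate_tracks(cfg, seed=s)
            N_ext, _, N_bar, _ = ground_truth_ratios(truth)
            ext += N_ext
            bar += N_bar
        return ext / bar

    f = lambda p: pooled_ratio(p) - target_r_barrier
    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError("target ratio not bracketed by the probability range")
    # the realized ratio is a step function of p under common random numbers:
    # bisect, then keep whichever bracket end lands closer to the target
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid < 0:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return float(lo if abs(f_lo) <= abs(f_hi) else hi)


def calibrate_seeding_edge(
    config: SimulationConfig,
    target_barrier_fraction: float,
    seeds: list,
    bracket: tuple[float, float] = (-130.0, -1.0),
) -> float:
    """Solve for the seeding edge (initial_x_max_um) at which the pooled
    ground-truth barrier-occupancy fraction N_av-barrier / N_av-tot of the
    given samples equals the target.

    The fraction, not the cell count, determines the crossings-to-total
    ratio; the seeding proximity to the gel face is the geometry parameter
    that moves it.  Ground truth only; common random numbers across
    candidates.
    """
    from dataclasses import replace

    def frac(edge: float) -> float:
        bar = tot = 0.0
        for s in seeds:
            cfg = replace(config, initial_x_max_um=edge)
            truth = simulate_tracks(cfg, seed=s)
            _, N_tot, N_bar, _ = ground_truth_ratios(truth)
            bar += N_bar
            tot += N_tot
        return bar / tot

    f = lambda e: frac(e) - target_barrier_fraction
    lo, hi = bracket
    if f(hi) < 0:
        return hi  # even wall-adjacent seeding stays below the target
    if f(lo) > 0:
        raise ValueError("target occupancy fraction not reachable")
    return float(optimize.brentq(f, lo, hi, xtol=0.05))


def calibrate_study_conditions(
    config: SimulationConfig,
    seeds: list,
    target_r_barrier: float = 0.34,
    target_r_tot: float = 0.07,
) -> SimulationConfig:
    """Jointly calibrate seeding edge and crossing probability so that the
    realized ground-truth ratios of the given samples match both targets."""
    from dataclasses import replace

    cfg = config
    for _ in range(2):  # the two knobs interact weakly; two rounds suffice
        edge = calibrate_seeding_edge(
            cfg, target_r_tot / target_r_barrier, seeds)
        cfg = replace(cfg, initial_x_max_um=edge)
        p = calibrate_crossing_probability(cfg, target_r_barrier, seeds=seeds)
        cfg = replace(cfg, p_cross_per_frame=p)
    return cfg


# ---------------------------------------------------------------------------
# dye-diffusion series


def simulate_dextran_series(
    P_true_cm_s: float,
    diameter_um: float = 100.0,
    I_background: float = 100.0,
    I_lumen: float = 1100.0,
    duration_min: float = 30.0,
    dt_s: float = 30.0,
    noise_sd: float = 0.0,
    linear_regime_min: float = 15.0,
    seed: int = 0,
) -> dict:
    """Dye-diffusion intensity series following the early-time transport law.

    The total intensity rises with slope ``P * 4/d`` scaled by the lumen
    contrast ``I_1 - I_b`` while the gel behaves as a perfect sink; beyond
    ``linear_regime_min`` the confined chamber saturates and the slope decays
    exponentially, emulating the sink-condition breakdown.  Returns a dict
    with ``t_s``, ``intensity`` and metadata (including a ``clipped`` flag if
    noise drove any sample below zero).
    """
    if P_true_cm_s < 0:
        raise ValueError("P_true_cm_s must be >= 0")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0, duration_min * 60.0 + dt_s / 2, dt_s)
    d_cm = diameter_um * 1e-4
    rate = P_true_cm_s * 4.0 / d_cm          # fractional rise per second
    contrast = I_lumen - I_background
    t_lin = linear_regime_min * 60.0
    tau = 0.5 * t_lin if t_lin > 0 else 1.0
    ramp = np.where(
        t <= t_lin,
        t,
        t_lin + tau * (1.0 - np.exp(-(t - t_lin) / tau)),
    )
    intensity = I_lumen + contrast * rate * ramp
    clipped = False
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0, noise_sd, intensity.shape)
        if (intensity < 0).any():
            clipped = True
            intensity = np.clip(intensity, 0, None)
    return {
        "t_s": t,
        "intensity": intensity,
        "I_background": I_background,
        "I_lumen": I_lumen,
        "diameter_um": diameter_um,
        "P_true_cm_s": P_true_cm_s,
        "clipped": clipped,
    }
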