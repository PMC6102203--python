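"""End-to-end orchestration: register -> focus -> segment -> track -> stats.

Every stage is a pure function of (inputs, parameters, seed); rerunning a
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import stats as st
from .focus import FocusParams, focus_frame
from .regions import RegionLayout
from .registration import DriftTable, estimate_drift
from .segmentation import add_z_estimates, segment_cells
from .stack_io import write_tables
from .tracking import add_regions, link_tracks

log = logging.getLogger("microtem")


@dataclass
class SegmentationParams:
    min_area_um2: float = 50.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    dark_fraction: float = 0.6
    min_nucleus_area_um2: float = 20.0


@dataclass
class TrackingParams:
    gate_um_per_frame: float = 30.0
    max_gap: int = 2


@dataclass
class StatsParams:
    min_visit: int = 2
    hotspot_bandwidth_um: float = 10.0
    hotspot_n_null: int = 999
    hotspot_alpha: float = 0.05
    barrier_plane_um: tuple[float, float] = (150.0, 100.0)


@dataclass
class PipelineConfig:
    layout: RegionLayout
    focus: FocusParams = field(default_factory=FocusParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    stats: StatsParams = field(default_factory=StatsParams)
    frame_interval_min: float = 20.0
    z_step_um: float = 1.5
    max_drift_px: int = 5
    seed: int = 0


REQUIRED_LAYOUT_KEYS = ("shape", "pixel_size_um", "barrier_x_um", "barrier_thickness_um")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline configuration; schema errors are raised
    before any computation starts."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "layout" not in raw:
        raise ValueError("config must be a mapping with a 'layout' section")
    lay = raw["layout"]
    missing = [k for k in REQUIRED_LAYOUT_KEYS if k not in lay]
    if missing:
        raise ValueError(f"layout config missing required keys: {missing}")
    layout = RegionLayout(
        shape=tuple(lay["shape"]),
        pixel_size_um=float(lay["pixel_size_um"]),
        x_origin_um=float(lay["barrier_x_um"]) - float(lay.get("channel_span_um",
            lay["shape"][1] * lay["pixel_size_um"] * 0.7)),
        barrier_thickness_um=float(lay["barrier_thickness_um"]),
        pillar_windows=[tuple(w) for w in lay.get("pillar_windows", [])],
    )
    if "x_origin_um" in lay:
        layout.x_origin_um = float(lay["x_origin_um"])
    kwargs = {}
    if "focus" in raw:
        kwargs["focus"] = FocusParams(**raw["focus"])
    if "segmentation" in raw:
        kwargs["segmentation"] = SegmentationParams(**raw["segmentation"])
    if "tracking" in raw:
        kwargs["tracking"] = TrackingParams(**raw["tracking"])
    if "stats" in raw:
        sp = dict(raw["stats"])
        if "barrier_plane_um" in sp:
            sp["barrier_plane_um"] = tuple(sp["barrier_plane_um"])
        kwargs["stats"] = StatsParams(**sp)
    for key in ("frame_interval_min", "z_step_um", "max_drift_px", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(layout=layout, **kwargs)


def process_frames(frame_source, config: PipelineConfig,
                   overrides: pd.DataFrame | None = None) -> dict:
    """Run the image stages over a frame source.

    ``frame_source`` needs ``n_frames`` and ``get_frame(t) -> (bf, gfp)``
    volumes of shape (z, y, x) — a :class:`~microtem.stack_io.StackSeries` or
    a streaming :class:`~microtem.synthetic.SyntheticSource`.

    Returns a dict with the tracks table, per-frame detections, composites,
    projections and the drift table.
    """
    n_frames = frame_source.n_frames
    layout = config.layout
    composites, projections, level_maps = [], [], []
    detections = {}
    seg = config.segmentation
    log.info("focus + segmentation: %d frames", n_frames)
    for t in range(n_frames):
        bf, gfp = frame_source.get_frame(t)
        res = focus_frame(bf, gfp, config.focus)
        composites.append(res.bf_composite)
        projections.append(res.gfp_projection)
        level_maps.append(res.level_map)
        det = segment_cells(
            res.gfp_projection, res.bf_composite, layout.pixel_size_um,
            min_area_um2=seg.min_area_um2,
            threshold_method=seg.threshold_method,
            threshold_value=seg.threshold_value,
            dark_fraction=seg.dark_fraction,
            min_nucleus_area_um2=seg.min_nucleus_area_um2,
            frame=t,
        )
        det = add_z_estimates(det, gfp, config.z_step_um)
        detections[t] = det.cells
    n_det = sum(len(d) for d in detections.values())
    log.info("segmentation: %d detections over %d frames", n_det, n_frames)

    # drift estimated on composites; segmentation is translation-equivariant,
    # so the correction is applied to the nucleus coordinates directly
    if layout.pillar_windows and n_frames > 1:
        drift = estimate_drift(composites, layout.pillar_windows,
                               max_shift=config.max_drift_px)
    else:
        drift = DriftTable(np.zeros((n_frames, 2), dtype=int),
                           method={"skipped": True})
    log.info("registration: max |shift| = %d px", int(np.abs(drift.shifts).max()))
    for t in range(n_frames):
        dx, dy = drift.shifts[t]
        cells = detections[t]
        # pixel-frame coordinates -> drift-free physical coordinates
        cells["nucleus_x_um"] = (cells["nucleus_x_um"]
                                 - dx * layout.pixel_size_um + layout.x_origin_um)
        cells["nucleus_y_um"] = cells["nucleus_y_um"] - dy * layout.pixel_size_um
        # the shift can push border detections just outside the field of view
        lo, hi = layout.x_extent_um
        cells["nucleus_x_um"] = cells["nucleus_x_um"].clip(lo, hi)
        cells["nucleus_y_um"] = cells["nucleus_y_um"].clip(
            0.0, (layout.shape[0] - 1) * layout.pixel_size_um)

    tracks = link_tracks(
        detections, gate_um_per_frame=config.tracking.gate_um_per_frame,
        max_gap=config.tracking.max_gap,
        frame_interval_min=config.frame_interval_min,
        overrides=overrides,
    )
    tracks = add_regions(tracks, layout)
    log.info("tracking: %d tracks", tracks["track_id"].nunique())
    return {
        "tracks": tracks,
        "detections": detections,
        "composites": composites,
        "projections": projections,
        "level_maps": level_maps,
        "drift": drift,
    }


def compute_stats(tracks: pd.DataFrame, n_frames: int,
                  params: StatsParams | None = None,
                  seed: int | np.random.Generator = 0) -> dict:
    """Behaviour classes, count series, ratios, velocities, occupancy and
    hot spots for one sample's tracks table."""
    params = params or StatsParams()
    behavior = bh.classify_all(tracks, min_visit=params.min_visit)
    stats = st.sample_stats(tracks, n_frames, min_visit=params.min_visit)
    ratios = st.transmigration_ratios(stats)
    vel = st.velocities(tracks)
    occupancy, _ = st.occupancy_map(tracks, min_visit=params.min_visit)
    crossing = behavior[behavior["behavior_type"] == bh.TYPE_I]
    hotspots = st.detect_hotspots(
        crossing, plane_extent_um=params.barrier_plane_um,
        bandwidth_um=params.hotspot_bandwidth_um,
        n_null=params.hotspot_n_null, alpha=params.hotspot_alpha, seed=seed,
    )
    return {
        "behavior": behavior,
        "sample_stats": stats,
        "ratios": ratios,
        "velocities": vel,
        "occupancy": occupancy,
        "hotspots": hotspots,
    }


def run_pipeline(frame_source, config: PipelineConfig,
                 out_dir: str | Path | None = None,
                 overrides: pd.DataFrame | None = None) -> dict:
    """Full pipeline over one sample; optionally writes the result bundle."""
    result = process_frames(frame_source, config, overrides=overrides)
    n_frames = frame_source.n_frames
    stats = compute_stats(result["tracks"], n_frames,
                          params=config.stats, seed=config.seed)
    result.update(stats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        tracks = result["tracks"].merge(
            result["behavior"][["track_id", "behavior_type"]],
            on="track_id", how="left",
        )
        s = result["sample_stats"]
        summary = {
            "n_frames": n_frames,
            "N_av_tot": s.N_av_tot,
            "N_av_barrier": s.N_av_barrier,
            "N_av_ext": s.N_av_ext,
            "r_tot": result["ratios"].r_tot,
            "r_barrier": result["ratios"].r_barrier,
            "no_transmigration": result["ratios"].no_transmigration,
            "behavior_frequencies": s.behavior_frequencies,
            "n_hotspots": len(result["hotspots"].hotspots),
            "config_sha256": _config_hash(config),
        }
        paths = write_tables(tracks, summary, out_dir)
        manifest = {
            "config": _jsonable_config(config),
            "config_sha256": summary["config_sha256"],
            "n_frames": n_frames,
            "drift_px": result["drift"].shifts.tolist(),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        result["behavior"].to_csv(out_dir / "behavior.csv", index=False)
        result["occupancy"].to_csv(out_dir / "occupancy.csv", index=False)
        hs = pd.DataFrame(
            [{"y_um": h.y_um, "z_um": h.z_um, "density": h.density,
              "percentile": h.percentile} for h in result["hotspots"].hotspots]
        )
        hs.to_csv(out_dir / "hotspots.csv", index=False)
        result["paths"] = paths
    return result


def _jsonable_config(config: PipelineConfig) -> dict:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    return json.loads(json.dumps(asdict(config), sort_keys=True, default=default))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable_config(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
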