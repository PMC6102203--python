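"""Validation experiments against the method's published performance bounds.

Each benchmark regenerates synthetic study-condition data from a seed, runs
the relevant part of the pipeline from scratch and measures its recovery:
segmentation accuracy against ground-truth masks, transmigration-ratio
recovery through the full image→stats chain, pooled velocity recovery, and
permeability round trips.  The problem sizes mirror the assay (45 frames at
20-min intervals, 10–50 cells per ~413 µm field of view, 67 z-slices); the
segmentation benchmark uses sparser single-frame fields so every cell can be
matched unambiguously to its ground-truth mask.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import stats as st
from .focus import FocusParams, focus_frame
from .permeability import fit_permeability
from .pipeline import PipelineConfig, process_frames
from .segmentation import segment_cells
from .stats import sample_stats, pooled_ratios
from .synthetic import (MICROVESSEL_SPEEDS, REFERENCE_SPEEDS, SimulationConfig,
                        SyntheticSource, calibrate_crossing_probability,
                        generate_layout, ground_truth_ratios,
                        simulate_dextran_series, simulate_tracks)

MOD = 2**31 - 1


def _sample_seed(base: int, k: int) -> int:
    return (base * 9973 + k) % MOD


def match_detections(det_labels: np.ndarray, truth, frame: int):
    """Match ground-truth cells to detected labels by maximal overlap.

    Yields (track_id, detected_label, true_mask) for every ground-truth cell
    with any overlapping detection.
    """
    for tid in truth.positions(frame)["track_id"]:
        gt_mask = truth.mask(frame, int(tid))
        labels, counts = np.unique(det_labels[gt_mask], return_counts=True)
        keep = labels > 0
        labels, counts = labels[keep], counts[keep]
        if len(labels) == 0:
            continue
        yield int(tid), int(labels[np.argmax(counts)]), gt_mask


def segmentation_benchmark(seed: int = 0, n_frames: int = 30) -> dict:
    """Projected-area and nucleus-localization errors over seeded frames.

    Each frame is an independent single-time-point field with 3–10 cells and
    the default noise; detections are matched to ground-truth masks by
    maximal overlap.
    """
    area_err, dx_err, dy_err = [], [], []
    n_matched = n_total = 0
    for k in range(1, n_frames + 1):
        s = _sample_seed(seed, k)
        rng = np.random.default_rng(s)
        cfg = SimulationConfig(n_cells=int(rng.integers(3, 11)), n_frames=1, seed=s)
        src = SyntheticSource(cfg)
        bf, gfp = src.get_frame(0)
        res = focus_frame(bf, gfp, FocusParams())
        det = segment_cells(res.gfp_projection, res.bf_composite, cfg.pixel_size_um)
        truth = src.truth
        px_area = cfg.pixel_size_um**2
        n_total += cfg.n_cells
        for tid, lab, gt_mask in match_detections(det.labels, truth, 0):
            n_matched += 1
            a_est = float((det.labels == lab).sum()) * px_area
            a_true = float(gt_mask.sum()) * px_area
            area_err.append(abs(a_est - a_true) / a_true)
            row = truth.positions(0)
            row = row[row["track_id"] == tid].iloc[0]
            cell = det.cells[det.cells["label"] == lab].iloc[0]
            dx_err.append(abs(cell["nucleus_x_um"]
                              - (row["nucleus_x_um"] - cfg.x_min_um)))
            dy_err.append(abs(cell["nucleus_y_um"] - row["nucleus_y_um"]))
    return {
        "median_area_error_pct": float(np.median(area_err) * 100),
        "median_nucleus_dx_um": float(np.median(dx_err)),
        "median_nucleus_dy_um": float(np.median(dy_err)),
        "n_cells_matched": n_matched,
        "n_cells_total": n_total,
        "n_frames": n_frames,
    }


def transmigration_benchmark(
    seed: int = 0,
    n_samples: int = 6,
    target_r_barrier: float = 0.34,
) -> dict:
    """Image→stats recovery of the transmigration ratios.

    The per-frame crossing probability is calibrated so that the *realized*
    pooled ground-truth N_av-ext/N_av-barrier of these exact samples equals
    the target; the full pipeline (focus, registration, segmentation,
    tracking, behaviour statistics) then recovers the ratios from the
    rendered images alone.
    """
    base = SimulationConfig(seed=0)
    sample_seeds = [_sample_seed(seed, k) for k in range(n_samples)]
    from .synthetic import calibrate_study_conditions
    calibrated = calibrate_study_conditions(base, sample_seeds,
                                            target_r_barrier=target_r_barrier,
                                            target_r_tot=0.07)

    gt_stats, pipe_stats = [], []
    for s in sample_seeds:
        cfg = replace(calibrated, seed=s)
        src = SyntheticSource(cfg)
        layout = generate_layout(cfg)
        pc = PipelineConfig(layout=layout, z_step_um=cfg.z_step_um,
                            frame_interval_min=cfg.frame_interval_min, seed=s)
        res = process_frames(src, pc)
        pipe_stats.append(sample_stats(res["tracks"], cfg.n_frames))
        gt_stats.append(ground_truth_ratios(src.truth))

    pipe = pooled_ratios(pipe_stats)
    gt_ext = sum(g[0] for g in gt_stats)
    gt_tot = sum(g[1] for g in gt_stats)
    gt_bar = sum(g[2] for g in gt_stats)
    return {
        "r_barrier": pipe.r_barrier,
        "r_tot": pipe.r_tot,
        "gt_r_barrier": gt_ext / gt_bar,
        "gt_r_tot": gt_ext / gt_tot,
        "p_cross_calibrated": calibrated.p_cross_per_frame,
        "seeding_edge_um": calibrated.initial_x_max_um,
        "n_samples": n_samples,
    }


def velocity_benchmark(
    seed: int = 0,
    system: str = "microvessel",
    n_samples: int | None = None,
) -> dict:
    """Pooled weighted-mean channel speed from simulated samples.

    Motion parameters are the region speeds observed for the chosen system;
    per-sample mean/SD/cell-count of per-interval in-plane channel speeds are
    pooled with the inverse-variance weights (w_i = n_i / sigma_i^2).
    """
    if system == "microvessel":
        speeds, default_n = MICROVESSEL_SPEEDS, 6
    elif system == "reference":
        speeds, default_n = REFERENCE_SPEEDS, 5
    else:
        raise ValueError(f"unknown system {system!r}")
    n_samples = n_samples or default_n
    summaries = []
    for k in range(n_samples):
        s = _sample_seed(seed + 7, k)
        rng = np.random.default_rng(s)
        cfg = SimulationConfig(
            n_cells=int(rng.integers(10, 51)),
            speed_by_region_um_per_min=dict(speeds),
            seed=s,
        )
        truth = simulate_tracks(cfg)
        vel = st.velocities(truth.tracks)
        summaries.append(st.sample_velocity_summary(vel, region="channel"))
    pooled = st.pooled_velocity(summaries)
    return {
        "pooled_channel_speed_um_min": pooled.mean,
        "pooled_error_um_min": pooled.error,
        "n_samples": n_samples,
        "system": system,
    }


def permeability_benchmark(
    P_true_cm_s: float,
    seed: int = 0,
    noise_fraction: float = 0.02,
) -> dict:
    """Round-trip permeability recovery at 30-s sampling, 15-min window."""
    I_b, I_1 = 100.0, 1100.0
    series = simulate_dextran_series(
        P_true_cm_s, I_background=I_b, I_lumen=I_1,
        noise_sd=noise_fraction * (I_1 - I_b), seed=seed,
    )
    fit = fit_permeability(series["t_s"], series["intensity"], I_b=I_b,
                           diameter_um=series["diameter_um"], window_min=15.0)
    return {
        "P_true_cm_s": P_true_cm_s,
        "P_est_cm_s": fit.P_cm_s,
        "P_se_cm_s": fit.P_se_cm_s,
        "abs_error_cm_s": abs(fit.P_cm_s - P_true_cm_s),
    }
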