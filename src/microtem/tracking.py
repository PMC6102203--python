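"""Linking nucleus detections into trajectories.

Frame-to-frame linking is greedy nearest-neighbour on nucleus centroids:
candidate (track, detection) pairs within the gate distance are linked in
ascending order of distance, so each link is mutually nearest among the
remaining candidates.  Tracks survive up to ``max_gap`` missing frames
(detection drop-outs) with the gate scaled by the elapsed frames.  An optional
override table — the stand-in for a manual tracking step — is applied last
and wins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRACK_RECORD_COLUMNS = [
    "track_id", "frame", "t_min", "x_um", "y_um", "z_um",
    "area_um2", "nucleus_fallback", "label",
]


def link_tracks(
    detections_by_frame: dict[int, pd.DataFrame],
    gate_um_per_frame: float = 30.0,
    max_gap: int = 2,
    frame_interval_min: float = 20.0,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Link per-frame detections into a tidy tracks table.

    Parameters
    ----------
    detections_by_frame
        Mapping frame -> cells DataFrame with at least ``nucleus_x_um`` and
        ``nucleus_y_um`` (plus optional ``z_um``, ``area_um2``, ``label``,
        ``nucleus_fallback``).
    gate_um_per_frame
        Maximum linking displacement per elapsed frame.  The default 30 µm
        gives ~3x headroom over a typical 10 µm frame displacement
        (0.5 µm/min at 20-min sampling) while excluding jumps between
        distinct cells.
    overrides
        Optional (frame, label, track_id) table reassigning detections.

    Returns a DataFrame with :data:`TRACK_RECORD_COLUMNS`, sorted by
    (track_id, frame).
    """
    frames = sorted(detections_by_frame)
    records: list[dict] = []
    # active tracks: id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    next_id = 0

    for frame in frames:
        cells = detections_by_frame[frame]
        n_det = len(cells)
        det_xy = cells[["nucleus_x_um", "nucleus_y_um"]].to_numpy(dtype=float) \
            if n_det else np.empty((0, 2))
        # candidate links, ascending distance; ties broken by (track, det)
        candidates = []
        for tid, (last_frame, lx, ly) in active.items():
            gap = frame - last_frame
            if gap > max_gap + 1:
                continue
            d = np.hypot(det_xy[:, 0] - lx, det_xy[:, 1] - ly)
            limit = gate_um_per_frame * gap
            for j in np.flatnonzero(d <= limit):
                candidates.append((d[j], tid, int(j)))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        assignment: dict[int, int] = {}
        for d, tid, j in candidates:
            if tid in used_tracks or j in used_dets:
                continue
            assignment[j] = tid
            used_tracks.add(tid)
            used_dets.add(j)
        for j in range(n_det):
            tid = assignment.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            row = cells.iloc[j]
            active[tid] = (frame, det_xy[j, 0], det_xy[j, 1])
            records.append({
                "track_id": tid,
                "frame": frame,
                "t_min": frame * frame_interval_min,
                "x_um": det_xy[j, 0],
                "y_um": det_xy[j, 1],
                "z_um": float(row["z_um"]) if "z_um" in row else np.nan,
                "area_um2": float(row["area_um2"]) if "area_um2" in row else np.nan,
                "nucleus_fallback": bool(row.get("nucleus_fallback", False)),
                "label": int(row["label"]) if "label" in row else j + 1,
            })
        # drop tracks that exceeded the gap allowance
        active = {tid: v for tid, v in active.items()
                  if frame - v[0] <= max_gap}

    table = pd.DataFrame(records, columns=TRACK_RECORD_COLUMNS)
    if overrides is not None and len(overrides):
        table = _apply_overrides(table, overrides)
    return table.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)


def _apply_overrides(table: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    required = {"frame", "label", "track_id"}
    if not required <= set(overrides.columns):
        raise ValueError(f"override table needs columns {sorted(required)}")
    table = table.copy()
    for _, row in overrides.iterrows():
        sel = (table["frame"] == row["frame"]) & (table["label"] == row["label"])
        if not sel.any():
            raise ValueError(
                f"override references unknown detection frame={row['frame']} "
                f"label={row['label']}"
            )
        table.loc[sel, "track_id"] = row["track_id"]
    return table


def add_regions(tracks: pd.DataFrame, layout) -> pd.DataFrame:
    """Attach the region label of each nucleus position (the nucleus is the
    tracked point, so membership is decided by it, not by mask overlap)."""
    from .regions import assign_region

    tracks = tracks.copy()
    tracks["region"] = [
        assign_region((x, y), layout)
        for x, y in zip(tracks["x_um"], tracks["y_um"])
    ]
    return tracks
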