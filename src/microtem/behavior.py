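"""Classification of trajectories into the three transmigration behaviours.

Type I — the cell transmigrated from the vessel lumen into the collagen
matrix; Type II — the cell reached the endothelial barrier and stayed there;
Type III — the cell remained in the lumen, or returned to the lumen centre
after a stay at the barrier.

A region *visit* requires at least two consecutive frames (the smoothing
rule), so single-frame flicker of the region label — segmentation noise at a
band edge — cannot change a trajectory's class.  Precedence is I > II > III:
any smoothed visit to the gel makes the track Type I regardless of what
follows (gel entry is irreversible in this system).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import BARRIER, GEL

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"


@dataclass
class BehaviorRecord:
    track_id: int
    type: str                       # "I", "II" or "III"
    first_gel_frame: int | None     # frame of the crossing (Type I only)
    barrier_dwell_frames: int       # smoothed frames spent at the barrier
    crossing_y_um: float | None = None
    crossing_z_um: float | None = None


def smooth_regions(regions: list[str], min_visit: int = 2) -> list[str]:
    """Suppress region runs shorter than ``min_visit`` frames.

    Short runs take the label of the preceding accepted visit; a short leading
    run takes the first following accepted visit's label (or, if no run
    reaches ``min_visit``, the first region stands for the whole track).
    """
    if not regions:
        return []
    runs: list[tuple[str, int]] = []
    for r in regions:
        if runs and runs[-1][0] == r:
            runs[-1] = (r, runs[-1][1] + 1)
        else:
            runs.append((r, 1))
    accepted = [r for r, n in runs if n >= min_visit]
    if not accepted:
        return [regions[0]] * len(regions)
    out: list[str] = []
    current: str | None = None
    pending = 0  # leading short-run frames awaiting the first accepted visit
    for r, n in runs:
        if n >= min_visit:
            if current is None and pending:
                out.extend([r] * pending)
                pending = 0
            current = r
            out.extend([r] * n)
        elif current is None:
            pending += n
        else:
            out.extend([current] * n)
    return out


def classify_behavior(track: pd.DataFrame, min_visit: int = 2) -> BehaviorRecord | None:
    """Classify one track (rows of a tidy tracks table, time-ordered).

    Tracks shorter than 2 frames carry no dynamics and are excluded
    (returns ``None``).
    """
    if len(track) < 2:
        return None
    track = track.sort_values("frame")
    regions = list(track["region"])
    smoothed = smooth_regions(regions, min_visit=min_visit)
    frames = track["frame"].to_numpy()
    barrier_dwell = int(sum(r == BARRIER for r in smoothed))
    tid = int(track["track_id"].iloc[0])
    # the crossing frame is the first frame that is gel both raw and smoothed:
    # backfilled leading frames must not backdate the crossing
    gel_idx = [i for i, (r, s) in enumerate(zip(regions, smoothed))
               if s == GEL and r == GEL]
    if GEL in smoothed:
        i = gel_idx[0]
        return BehaviorRecord(
            track_id=tid,
            type=TYPE_I,
            first_gel_frame=int(frames[i]),
            barrier_dwell_frames=barrier_dwell,
            crossing_y_um=float(track["y_um"].iloc[i]),
            crossing_z_um=float(track["z_um"].iloc[i]),
        )
    if smoothed[-1] == BARRIER:
        return BehaviorRecord(tid, TYPE_II, None, barrier_dwell)
    return BehaviorRecord(tid, TYPE_III, None, barrier_dwell)


def classify_all(tracks: pd.DataFrame, min_visit: int = 2) -> pd.DataFrame:
    """Behaviour table for every track of sufficient length."""
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        rec = classify_behavior(grp, min_visit=min_visit)
        if rec is None:
            continue
        rows.append({
            "track_id": rec.track_id,
            "behavior_type": rec.type,
            "first_gel_frame": rec.first_gel_frame,
            "barrier_dwell_frames": rec.barrier_dwell_frames,
            "crossing_y_um": rec.crossing_y_um,
            "crossing_z_um": rec.crossing_z_um,
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "behavior_type", "first_gel_frame",
        "barrier_dwell_frames", "crossing_y_um", "crossing_z_um",
    ])


def behavior_frequencies(behavior: pd.DataFrame) -> dict[str, float]:
    """Fraction of tracks in each behaviour class."""
    n = len(behavior)
    if n == 0:
        return {TYPE_I: np.nan, TYPE_II: np.nan, TYPE_III: np.nan}
    counts = behavior["behavior_type"].value_counts()
    return {t: float(counts.get(t, 0)) / n for t in (TYPE_I, TYPE_II, TYPE_III)}
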