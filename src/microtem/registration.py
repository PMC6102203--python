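"""Stage-drift correction from static device features.

Small x-y shifts of the microscope stage between frames are estimated by
normalized cross-correlation of fiducial windows (pillar corners, which never
move) against the first frame, and undone by an integer-pixel translation.
Sub-pixel registration is deliberately out of scope: the residual nucleus
localization error of the segmentation (~2 µm, i.e. more than one pixel)
dominates any sub-pixel stage component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DriftTable:
    """Per-frame (dx, dy) pixel shift of each frame relative to frame 0."""

    shifts: np.ndarray  # (n_frames, 2) int, columns (dx, dy)
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if tuple(self.shifts[0]) != (0, 0):
            raise ValueError("frame 0 must have zero shift")

    @property
    def n_frames(self) -> int:
        return len(self.shifts)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return -np.inf
    return float(a @ b) / (na * nb)


def estimate_drift(
    frames: list[np.ndarray],
    fiducial_windows: list[tuple[int, int, int, int]],
    max_shift: int = 5,
    min_correlation: float = 0.3,
) -> DriftTable:
    """Estimate per-frame integer shifts from fiducial windows.

    For every frame the (dx, dy) in ``[-max_shift, max_shift]^2`` maximizing
    the mean normalized cross-correlation of all fiducial windows against
    frame 0 is chosen.  Frames whose best correlation falls below
    ``min_correlation`` are rejected and interpolated from their neighbours.
    """
    if not fiducial_windows:
        raise ValueError("at least one fiducial window is required")
    frames = [np.asarray(f) for f in frames]
    ref = frames[0]
    ny, nx = ref.shape
    for w in fiducial_windows:
        y0, y1, x0, x1 = w
        if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValueError(f"fiducial window {w} outside image bounds")
        patch = ref[y0:y1, x0:x1]
        if patch.std() == 0:
            raise ValueError(f"featureless fiducial window {w}: zero variance")

    shifts = np.zeros((len(frames), 2), dtype=int)
    valid = np.ones(len(frames), dtype=bool)
    offsets = range(-max_shift, max_shift + 1)
    for t, frame in enumerate(frames[1:], start=1):
        best, best_shift = -np.inf, (0, 0)
        for dy in offsets:
            for dx in offsets:
                score, n = 0.0, 0
                for (y0, y1, x0, x1) in fiducial_windows:
                    sy0, sy1 = y0 + dy, y1 + dy
                    sx0, sx1 = x0 + dx, x1 + dx
                    if sy0 < 0 or sx0 < 0 or sy1 > ny or sx1 > nx:
                        continue
                    score += _ncc(ref[y0:y1, x0:x1], frame[sy0:sy1, sx0:sx1])
                    n += 1
                if n == 0:
                    continue
                score /= n
                if score > best:
                    best, best_shift = score, (dx, dy)
        shifts[t] = best_shift
        if best < min_correlation:
            valid[t] = False
    # interpolate rejected frames from the nearest accepted neighbours
    if not valid.all():
        idx = np.flatnonzero(valid)
        for axis in range(2):
            shifts[:, axis] = np.round(
                np.interp(np.arange(len(frames)), idx, shifts[idx, axis])
            ).astype(int)
        shifts[0] = 0
    return DriftTable(
        shifts=shifts,
        method={
            "max_shift": max_shift,
            "min_correlation": min_correlation,
            "n_fiducials": len(fiducial_windows),
            "rejected_frames": np.flatnonzero(~valid).tolist(),
        },
    )


def apply_correction(
    frames: list[np.ndarray],
    drift: DriftTable,
    fill: float | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Translate each 2D frame by the negated shift, returning (frames, masks).

    Out-of-view pixels are filled with ``fill`` (default: the frame median as a
    background estimate) and flagged False in the accompanying validity masks
    so downstream stages can exclude them.
    """
    if drift.n_frames != len(frames):
        raise ValueError(
            f"drift table covers {drift.n_frames} frames, got {len(frames)}"
        )
    out_frames, out_masks = [], []
    for frame, (dx, dy) in zip(frames, drift.shifts):
        frame = np.asarray(frame)
        corrected = np.full_like(
            frame, fill if fill is not None else np.median(frame)
        )
        mask = np.zeros(frame.shape, dtype=bool)
        ny, nx = frame.shape
        # feature rendered at p + shift; sampling at p + shift recovers it at p
        src_y0, src_y1 = max(0, dy), min(ny, ny + dy)
        src_x0, src_x1 = max(0, dx), min(nx, nx + dx)
        dst_y0, dst_y1 = src_y0 - dy, src_y1 - dy
        dst_x0, dst_x1 = src_x0 - dx, src_x1 - dx
        corrected[dst_y0:dst_y1, dst_x0:dst_x1] = frame[src_y0:src_y1, src_x0:src_x1]
        mask[dst_y0:dst_y1, dst_x0:dst_x1] = True
        out_frames.append(corrected)
        out_masks.append(mask)
    return out_frames, out_masks
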