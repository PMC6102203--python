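"""Cell segmentation on GFP projections refined by brightfield edges.

The GFP projection locates the bulk of each cell; the all-in-focus brightfield
composite carries sharp dark edges at the true outline.  Segmentation
thresholds the projection into foreground, seeds one marker per dark nucleus
(GFP-negative core) and lets a marker-controlled watershed on the composite
gradient draw the outlines, which also splits touching cells that each carry
a distinct nucleus.

The per-cell z-coordinate is the slice maximizing the summed GFP signal
within the projected cell area, times the z-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg

CELL_COLUMNS = [
    "label", "area_um2", "nucleus_x_um", "nucleus_y_um", "z_um",
    "mean_gfp", "nucleus_fallback",
]


@dataclass
class Detection:
    """Segmentation result of one frame."""

    frame: int
    labels: np.ndarray                 # (y, x) int label mask, 0 = background
    cells: pd.DataFrame                # one row per cell, CELL_COLUMNS
    pixel_size_um: float
    extra: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def segment_cells(
    gfp_projection: np.ndarray,
    bf_composite: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 50.0,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    dark_fraction: float = 0.6,
    min_nucleus_area_um2: float = 20.0,
    frame: int = 0,
    valid_mask: np.ndarray | None = None,
) -> Detection:
    """Segment individual cell bodies in one frame.

    A blank projection yields an empty :class:`Detection`, not an error.
    ``valid_mask`` (e.g. from drift correction) excludes filled border pixels.
    """
    gfp = np.asarray(gfp_projection, dtype=np.float32)
    bf = np.asarray(bf_composite, dtype=np.float32)
    if gfp.shape != bf.shape:
        raise ValueError("projection and composite must share shape")
    if min_area_um2 <= 0:
        raise ValueError("min_area_um2 must be positive")
    px_area = pixel_size_um**2
    min_area_px = max(1, int(round(min_area_um2 / px_area)))
    min_nuc_px = max(1, int(round(min_nucleus_area_um2 / px_area)))

    if threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        thr = threshold_value
    elif threshold_method == "otsu":
        if np.ptp(gfp) == 0:
            return _empty_detection(frame, gfp.shape, pixel_size_um)
        thr = filters.threshold_otsu(gfp)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    fg = gfp > thr
    if valid_mask is not None:
        fg &= valid_mask
    fg = morphology.remove_small_objects(fg, max_size=min_area_px - 1)
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return _empty_detection(frame, gfp.shape, pixel_size_um)

    markers = _nucleus_markers(fg, gfp, dark_fraction, min_nuc_px)
    grad = filters.sobel(bf)
    labels = sk_seg.watershed(grad, markers, mask=fg)
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            labels[labels == region.label] = 0
    labels, _, _ = sk_seg.relabel_sequential(labels)

    rows = []
    for region in measure.regionprops(labels, intensity_image=gfp):
        mask = labels == region.label
        cx, cy, fallback = detect_nucleus(
            mask, gfp, dark_fraction=dark_fraction,
            min_nucleus_area_px=min_nuc_px,
        )
        rows.append({
            "label": region.label,
            "area_um2": region.area * px_area,
            "nucleus_x_um": cx * pixel_size_um,
            "nucleus_y_um": cy * pixel_size_um,
            "z_um": np.nan,
            "mean_gfp": region.intensity_mean,
            "nucleus_fallback": fallback,
        })
    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return Detection(frame=frame, labels=labels, cells=cells,
                     pixel_size_um=pixel_size_um)


def _empty_detection(frame, shape, pixel_size_um) -> Detection:
    return Detection(
        frame=frame,
        labels=np.zeros(shape, dtype=np.int32),
        cells=pd.DataFrame(columns=CELL_COLUMNS),
        pixel_size_um=pixel_size_um,
    )


def _nucleus_markers(fg, gfp, dark_fraction, min_nuc_px) -> np.ndarray:
    """One watershed marker per dark nucleus; components without a detectable
    nucleus keep a single marker so no cell is lost."""
    markers = np.zeros(fg.shape, dtype=np.int32)
    comp_labels = measure.label(fg)
    next_id = 1
    for comp in measure.regionprops(comp_labels):
        comp_mask = comp_labels == comp.label
        med = np.median(gfp[comp_mask])
        dark = comp_mask & (gfp < dark_fraction * med)
        dark = morphology.remove_small_objects(dark, max_size=min_nuc_px - 1)
        dark_labels = measure.label(dark)
        n_dark = dark_labels.max()
        if n_dark == 0:
            markers[comp_mask] = next_id
            next_id += 1
        else:
            for k in range(1, n_dark + 1):
                markers[dark_labels == k] = next_id
                next_id += 1
    return markers


def detect_nucleus(
    cell_mask: np.ndarray,
    gfp_projection: np.ndarray,
    dark_fraction: float = 0.6,
    min_nucleus_area_px: int = 1,
) -> tuple[float, float, bool]:
    """Locate the dark (GFP-negative) nucleus inside one cell mask.

    Returns ``(x_px, y_px, fallback)``: the centroid of the largest connected
    dark region (intensity below ``dark_fraction`` times the cell median, area
    at least ``min_nucleus_area_px``).  Cells without such a region fall back
    to the intensity-weighted mask centroid, flagged ``fallback=True``.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell mask is empty")
    gfp = np.asarray(gfp_projection)
    med = np.median(gfp[mask])
    dark = mask & (gfp < dark_fraction * med)
    dark_labels = measure.label(dark)
    best_area, best = 0, None
    for region in measure.regionprops(dark_labels):
        if region.area >= min_nucleus_area_px and region.area > best_area:
            best_area, best = region.area, region
    if best is not None:
        cy, cx = best.centroid
        return float(cx), float(cy), False
    weights = gfp * mask
    total = weights.sum()
    if total <= 0:
        cy, cx = ndimage.center_of_mass(mask)
    else:
        cy, cx = ndimage.center_of_mass(weights)
    return float(cx), float(cy), True


def estimate_z(
    cell_mask: np.ndarray,
    gfp_volume: np.ndarray,
    z_step_um: float,
    method: str = "sum",
) -> float:
    """z-coordinate (µm) of one cell from the GFP signal within its mask.

    ``method="sum"`` (default) takes the slice maximizing the masked GFP sum,
    which is robust to shot noise; ``method="voxel_max"`` takes the slice of
    the single brightest voxel.  Ties resolve to the lowest slice, making the
    estimate deterministic.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    vol = np.asarray(gfp_volume)
    if mask.shape != vol.shape[1:]:
        raise ValueError(
            f"mask {mask.shape} does not fit volume lateral shape {vol.shape[1:]}"
        )
    if not mask.any():
        raise ValueError("cell mask is empty")
    masked = vol[:, mask]
    if method == "sum":
        profile = masked.sum(axis=1)
    elif method == "voxel_max":
        profile = masked.max(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return int(np.argmax(profile)) * z_step_um


def add_z_estimates(detection: Detection, gfp_volume: np.ndarray, z_step_um: float) -> Detection:
    """Fill the z_um column of a detection from the frame's GFP volume."""
    z_vals = []
    for label in detection.cells["label"]:
        z_vals.append(estimate_z(detection.labels == label, gfp_volume, z_step_um))
    detection.cells["z_um"] = z_vals
    return detection
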