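"""Spatial regions of the microvessel device.

The field of view is partitioned along x into three bands: the vessel lumen
(*channel*), the endothelium/collagen interface band (*barrier*, ~40 µm thick
owing to the curvature of the collagen interface at the pillar gaps), and the
collagen bulk (*gel*).

Coordinate convention (fixed throughout the package): physical x in µm with
x = 0 at the barrier's gel face and positive toward the collagen; y along the
channel; z from the channel bottom upward.  Pixel indices are 0-based; the
physical x of pixel column ``c`` is ``x_origin_um + c * pixel_size_um``.

Band boundaries are closed on the barrier side: ``channel`` is x < -thickness,
``barrier`` is -thickness <= x <= 0 and ``gel`` is x > 0, so a nucleus sitting
exactly on either barrier edge is counted as "at the barrier".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL = "channel"
BARRIER = "barrier"
GEL = "gel"

#: integer codes used in label images
REGION_CODES = {CHANNEL: 0, BARRIER: 1, GEL: 2}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


@dataclass
class RegionLayout:
    """Device layout of one field of view.

    Parameters
    ----------
    shape : (ny, nx)
        Image shape in pixels.
    pixel_size_um : float
        Lateral calibration.
    x_origin_um : float
        Physical x (µm) of pixel column 0, with x = 0 at the barrier gel face.
    barrier_thickness_um : float
        Width of the interface band (default 40 µm).
    pillar_windows : list of (y0, y1, x0, x1)
        Pixel boxes around pillar corners, used as registration fiducials.
    """

    shape: tuple[int, int]
    pixel_size_um: float
    x_origin_um: float
    barrier_thickness_um: float = 40.0
    pillar_windows: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.barrier_thickness_um <= 0:
            raise ValueError("barrier thickness must be positive")
        ny, nx = self.shape
        width_um = nx * self.pixel_size_um
        if self.barrier_thickness_um > width_um:
            raise ValueError(
                f"barrier band ({self.barrier_thickness_um} um) wider than the "
                f"field of view ({width_um:.1f} um)"
            )
        for w in self.pillar_windows:
            y0, y1, x0, x1 = w
            if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
                raise ValueError(f"pillar window {w} outside image bounds {self.shape}")

    @property
    def x_extent_um(self) -> tuple[float, float]:
        """Physical x range covered by pixel column centres."""
        ny, nx = self.shape
        return (self.x_origin_um, self.x_origin_um + (nx - 1) * self.pixel_size_um)

    def x_um(self, col: np.ndarray | float) -> np.ndarray | float:
        return self.x_origin_um + np.asarray(col) * self.pixel_size_um

    def col_of_x(self, x_um: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(x_um) - self.x_origin_um) / self.pixel_size_um


def region_of_x(x_um, thickness_um: float = 40.0):
    """Region label(s) for physical x coordinate(s), vectorised.

    channel: x < -thickness;  barrier: -thickness <= x <= 0;  gel: x > 0.
    """
    x = np.asarray(x_um, dtype=float)
    codes = np.where(x > 0, REGION_CODES[GEL],
                     np.where(x < -thickness_um, REGION_CODES[CHANNEL],
                              REGION_CODES[BARRIER]))
    if np.isscalar(x_um) or np.ndim(x_um) == 0:
        return REGION_NAMES[int(codes)]
    return np.array([REGION_NAMES[int(c)] for c in codes.ravel()]).reshape(codes.shape)


def define_regions(layout: RegionLayout) -> np.ndarray:
    """Label image partitioning the field of view into the three bands.

    Returns an int8 image of shape ``layout.shape`` with the codes in
    :data:`REGION_CODES`.  Every pixel gets exactly one label (partition).
    """
    lo, hi = layout.x_extent_um
    if -layout.barrier_thickness_um < lo - layout.pixel_size_um or hi < 0:
        raise ValueError(
            "barrier band [-thickness, 0] not inside the imaged x range "
            f"[{lo:.1f}, {hi:.1f}] um"
        )
    ny, nx = layout.shape
    x = layout.x_um(np.arange(nx))
    row = np.where(x > 0, REGION_CODES[GEL],
                   np.where(x < -layout.barrier_thickness_um,
                            REGION_CODES[CHANNEL], REGION_CODES[BARRIER]))
    return np.broadcast_to(row.astype(np.int8), (ny, nx)).copy()


def assign_region(point_xy_um: tuple[float, float], layout: RegionLayout) -> str:
    """Region label of the pixel band containing a nucleus position.

    The decision is made on the physical x coordinate with the closed-barrier
    rule, so points exactly on a band edge are classified deterministically.
    """
    x, y = point_xy_um
    lo, hi = layout.x_extent_um
    half = layout.pixel_size_um / 2
    ny, _ = layout.shape
    if not (lo - half <= x <= hi + half):
        raise ValueError(f"point x={x:.2f} um outside the field of view [{lo}, {hi}]")
    if not (-half <= y <= (ny - 1) * layout.pixel_size_um + half):
        raise ValueError(f"point y={y:.2f} um outside the field of view")
    return region_of_x(x, layout.barrier_thickness_um)
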