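"""Reading and writing image stacks and tabular results.

Stacks are held in canonical ``(time, z, channel, y, x)`` order with explicit
physical calibration.  OME-TIFF is the on-disk format (written via
:mod:`tifffile` with a TZCYX axes tag); tables go to CSV with a fixed column
schema and deterministic row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CANONICAL_AXES = "TZCYX"

#: column schema of the tracks table
TRACK_COLUMNS = [
    "track_id", "frame", "t_min", "x_um", "y_um", "z_um",
    "region", "area_um2", "behavior_type",
]


@dataclass
class StackSeries:
    """A two-channel 4D time-lapse with physical calibration.

    ``data`` has axes (time, z, channel, y, x).  ``channels`` names the channel
    axis and must contain at least ``"brightfield"`` and ``"gfp"``.
    """

    data: np.ndarray
    channels: list[str]
    pixel_size_um: float
    z_step_um: float
    frame_interval_min: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError(f"expected 5 axes (T,Z,C,Y,X), got {self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all axis lengths must be >= 1")
        if len(self.channels) != self.data.shape[2]:
            raise ValueError("channel names do not match the channel axis length")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        for cal, name in [(self.pixel_size_um, "pixel_size_um"),
                          (self.z_step_um, "z_step_um"),
                          (self.frame_interval_min, "frame_interval_min")]:
            if cal is None or cal <= 0:
                raise ValueError(f"{name} must be a positive number")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None

    def get_frame(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """(brightfield, gfp) volumes of shape (z, y, x) at frame ``t``."""
        bf = self.data[t, :, self.channel_index("brightfield")]
        gfp = self.data[t, :, self.channel_index("gfp")]
        return bf, gfp


def write_stack(series: StackSeries, path: str | Path) -> Path:
    """Write a canonical series as OME-TIFF with TZCYX axes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        series.data,
        ome=True,
        metadata={
            "axes": CANONICAL_AXES,
            "PhysicalSizeX": series.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": series.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": series.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": series.frame_interval_min,
            "TimeIncrementUnit": "min",
            "Channel": {"Name": series.channels},
        },
    )
    return path


def read_stack(
    path: str | Path,
    axis_spec: str | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_min: float | None = None,
    channels: list[str] | None = None,
) -> StackSeries:
    """Read a TIFF / OME-TIFF stack into canonical (T, Z, C, Y, X) order.

    ``axis_spec`` names the file's axes (e.g. ``"ZTCYX"``); when omitted the
    axes recorded in the file are used.  Calibration fields missing from the
    file must be supplied explicitly — there are no silent defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axis_spec or series.axes
        meta = {}
        if tif.ome_metadata:
            try:
                ome = tifffile.xml2dict(tif.ome_metadata)
                px = ome["OME"]["Image"]["Pixels"]
                meta["pixel_size_um"] = px.get("PhysicalSizeX")
                meta["z_step_um"] = px.get("PhysicalSizeZ")
                meta["frame_interval_min"] = px.get("TimeIncrement")
                ch = px.get("Channel")
                if isinstance(ch, dict):
                    name = ch.get("Name")
                    if isinstance(name, (list, tuple)):
                        meta["channels"] = list(name)
                    elif name:
                        meta["channels"] = [name]
                elif isinstance(ch, list):
                    meta["channels"] = [c.get("Name") for c in ch]
            except (KeyError, TypeError):
                pass

    file_axes = file_axes.upper()
    if len(file_axes) != data.ndim:
        raise ValueError(
            f"axis spec {file_axes!r} does not resolve the file's {data.ndim} axes"
        )
    unknown = set(file_axes) - set(CANONICAL_AXES + "S")
    if unknown:
        raise ValueError(
            f"unknown axis layout: cannot place axes {sorted(unknown)}; "
            f"supply axis_spec using letters from {CANONICAL_AXES!r}"
        )
    # insert missing singleton axes, then permute to canonical order
    for ax in CANONICAL_AXES:
        if ax not in file_axes:
            data = data[np.newaxis]
            file_axes = ax + file_axes
    order = [file_axes.index(ax) for ax in CANONICAL_AXES]
    data = np.transpose(data, order)

    channels = channels or meta.get("channels")
    if channels is None:
        if data.shape[2] == 2:
            raise ValueError(
                "channel names missing: supply channels=['brightfield', 'gfp'] "
                "(or the matching order for this file)"
            )
        channels = [f"ch{i}" for i in range(data.shape[2])]
    required = {"brightfield", "gfp"}
    if not required <= set(channels):
        raise ValueError(
            f"stack must contain channels {sorted(required)}; got {channels}"
        )

    pixel_size_um = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    z_step_um = z_step_um if z_step_um is not None else meta.get("z_step_um")
    frame_interval_min = (frame_interval_min if frame_interval_min is not None
                          else meta.get("frame_interval_min"))
    missing = [n for n, v in [("pixel_size_um", pixel_size_um),
                              ("z_step_um", z_step_um),
                              ("frame_interval_min", frame_interval_min)] if v is None]
    if missing:
        raise ValueError(
            f"calibration missing from file and not supplied: {missing}"
        )
    return StackSeries(
        data=data,
        channels=list(channels),
        pixel_size_um=float(pixel_size_um),
        z_step_um=float(z_step_um),
        frame_interval_min=float(frame_interval_min),
    )


def write_tables(tracks: pd.DataFrame, stats: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write the tracks table (CSV) and the stats bundle (JSON).

    The tracks CSV follows :data:`TRACK_COLUMNS` (missing columns are filled
    with NA) and is sorted by (track_id, frame).  An explicitly empty table
    produces a header-only CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = tracks.copy()
    for col in TRACK_COLUMNS:
        if col not in table.columns:
            table[col] = pd.NA
    table = table[TRACK_COLUMNS]
    if len(table):
        table = table.sort_values(["track_id", "frame"], kind="mergesort")
    tracks_path = out_dir / "tracks.csv"
    table.to_csv(tracks_path, index=False)
    stats_path = out_dir / "stats.json"
    with open(stats_path, "w") as fh:
        json.dump(_jsonable(stats), fh, indent=2, sort_keys=True)
    return {"tracks": tracks_path, "stats": stats_path}


def read_tracks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
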