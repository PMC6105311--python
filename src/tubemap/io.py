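"""Calibrated volume / track / contour I/O and shared coordinate conventions.

Conventions
-----------
* Volumes are indexed ``(z, y, x)``, zero based; after reorientation the
  slice index increases along the tube axis.
* Physical units at the I/O boundary are micrometres for positions and
  minutes for time.  Frame numbers are converted to minutes with a
  ``frame_interval`` parameter (default 2 min).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationError, ContourError, TubemapError

DEFAULT_FRAME_INTERVAL = 2.0  # minutes


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A calibrated 3D intensity grid, one timepoint of a (possibly) time-lapse.

    Parameters
    ----------
    voxels
        Non-negative intensity grid indexed ``(z, y, x)``.
    spacing
        Voxel pitch ``(dz, dy, dx)`` in micrometres.
    time_index
        Optional frame number for time-lapse data.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    time_index: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise TubemapError(f"volume must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < 8 or nx < 8:
            raise TubemapError(f"volume too small: shape {self.voxels.shape} (need >=1 slice, >=8x8 in-plane)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise CalibrationError(f"spacings must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise TubemapError("voxel intensities must be finite and >= 0")
        if self.time_index is not None and self.time_index < 0:
            raise TubemapError("time_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class SpotTrack:
    """An ordered junction-spot trajectory; gaps (missing timepoints) permitted."""

    label: str
    t: np.ndarray  # minutes, strictly increasing
    x: np.ndarray  # um
    y: np.ndarray  # um

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise TubemapError("t, x, y must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise TubemapError(f"track {self.label!r}: timepoints must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TubemapError(f"track {self.label!r}: positions must be finite")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ContourTable:
    """Manually delimited cell contours in map coordinates (um)."""

    contours: dict[object, np.ndarray]  # id -> (n, 2) vertex array, columns (x, y)
    annotations: dict[object, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, verts in self.contours.items():
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ContourError(f"cell {cid!r}: contour needs >= 3 (x, y) vertices")
            self.contours[cid] = verts


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

_OME_SIZE_RE = {
    ax: re.compile(rf'PhysicalSize{ax}="([0-9.eE+-]+)"') for ax in "XYZ"
}


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort spacing extraction: OME XML, then ImageJ metadata + resolution tags."""
    if tf.ome_metadata:
        sizes = {}
        for ax, rx in _OME_SIZE_RE.items():
            m = rx.search(tf.ome_metadata)
            if m:
                sizes[ax] = float(m.group(1))
        if {"X", "Y", "Z"} <= sizes.keys():
            return (sizes["Z"], sizes["Y"], sizes["X"])
    dz = dy = dx = None
    if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
        dz = float(tf.imagej_metadata["spacing"])
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None and yres is not None:
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr > 0 and yr > 0:
            dx, dy = 1.0 / xr, 1.0 / yr
    if dz is not None and dy is not None and dx is not None:
        return (dz, dy, dx)
    return None


def read_volume(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    channel: int | None = None,
    time_index: int | None = None,
) -> Volume:
    """Read a TIFF / OME-TIFF stack as a calibrated :class:`Volume`.

    ``spacing_override`` takes precedence over file metadata; if neither is
    available a :class:`CalibrationError` is raised.  Multi-channel stacks
    require an explicit ``channel``.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, ValueError) as exc:
        raise TubemapError(f"cannot read {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        spacing = spacing_override or _spacing_from_tiff(tf)

    # drop singleton leading axes (S/Q/T/C of size 1)
    while arr.ndim > 3 and arr.shape[0] == 1:
        arr = arr[0]
        axes = axes[1:]
    if arr.ndim == 4 and "C" in axes:
        cax = axes.index("C")
        if channel is None:
            raise TubemapError(f"multi-channel stack ({arr.shape[cax]} channels): pass channel=")
        arr = np.take(arr, channel, axis=cax)
    elif arr.ndim == 4:
        raise TubemapError(f"cannot interpret 4D stack with axes {axes!r}; split time frames first")
    if arr.ndim == 2:
        raise TubemapError("2D-only image: a volume needs >= 1 Z slice stack (3D)")

    if spacing is None:
        raise CalibrationError(
            f"{path}: no voxel calibration in metadata and no spacing_override given"
        )
    return Volume(voxels=arr, spacing=spacing, time_index=time_index)


def write_volume(path: str | Path, volume: Volume) -> None:
    """Write a :class:`Volume` as an OME-TIFF carrying its calibration."""
    dz, dy, dx = volume.spacing
    tifffile.imwrite(
        str(path),
        volume.voxels,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# track I/O
# ---------------------------------------------------------------------------

def read_tracks(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> list[SpotTrack]:
    """Read spot tracks from a CSV with columns ``track_id,t,x,y[,label]``.

    ``t`` is in minutes.  A ``frame`` column may be given instead of ``t``;
    it is converted with ``frame_interval`` (minutes per frame).  Duplicate
    ``(track_id, t)`` rows are an error.  Samples are returned time-sorted.
    """
    df = pd.read_csv(path)
    if "t" not in df.columns:
        if "frame" in df.columns:
            df["t"] = df["frame"].astype(float) * float(frame_interval)
        else:
            raise TubemapError("tracks CSV: missing required column 't' (or 'frame')")
    missing = {"track_id", "x", "y"} - set(df.columns)
    if missing:
        raise TubemapError(f"tracks CSV: missing required column(s) {sorted(missing)}")
    if df.duplicated(subset=["track_id", "t"]).any():
        dup = df[df.duplicated(subset=["track_id", "t"], keep=False)].iloc[0]
        raise TubemapError(
            f"tracks CSV: duplicated (track_id, t) = ({dup['track_id']}, {dup['t']})"
        )
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t")
        if "label" in grp.columns and grp["label"].notna().any():
            label = str(grp["label"].dropna().iloc[0])
        else:
            label = str(tid)
        tracks.append(
            SpotTrack(
                label=label,
                t=grp["t"].to_numpy(float),
                x=grp["x"].to_numpy(float),
                y=grp["y"].to_numpy(float),
            )
        )
    return tracks


def write_tracks(path: str | Path, tracks: list[SpotTrack]) -> None:
    rows = []
    for i, tr in enumerate(tracks):
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append({"track_id": i, "t": t, "x": x, "y": y, "label": tr.label})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# contour I/O
# ---------------------------------------------------------------------------

def read_contours(path: str | Path) -> ContourTable:
    """Read polygon contours from a CSV ``cell_id,vertex_index,x,y[,annotation]``."""
    df = pd.read_csv(path)
    missing = {"cell_id", "vertex_index", "x", "y"} - set(df.columns)
    if missing:
        raise TubemapError(f"contour CSV: missing required column(s) {sorted(missing)}")
    contours: dict[object, np.ndarray] = {}
    annotations: dict[object, str] = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        contours[cid] = grp[["x", "y"]].to_numpy(float)
        if "annotation" in grp.columns and grp["annotation"].notna().any():
            annotations[cid] = str(grp["annotation"].dropna().iloc[0])
    return ContourTable(contours=contours, annotations=annotations)


def write_contours(path: str | Path, table: ContourTable) -> None:
    rows = []
    for cid, verts in table.contours.items():
        ann = table.annotations.get(cid, "")
        for i, (x, y) in enumerate(verts):
            rows.append({"cell_id": cid, "vertex_index": i, "x": x, "y": y, "annotation": ann})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plain-text config
# ---------------------------------------------------------------------------

def parse_config(path: str | Path) -> dict[str, object]:
    """Parse a ``key = value`` plain-text config; numbers are coerced to float."""
    out: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise TubemapError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val
    return out
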