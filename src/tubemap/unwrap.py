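"""Cylindrical-to-planar projection of the fitted tube.

The map's X axis is circumferential position (the circle perimeter), the Y
axis is position along the tube's central axis.  Calibration is isotropic:
the circumferential pixel pitch equals the axial slice spacing ``dz`` at the
reference (median) radius.  Intensities are never interpolated — each
angular bin takes the maximum intensity over the crown pixels whose centre
falls in that angular sector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DomainError, TubemapError
from .io import Volume
from .tubefit import CrownCircle, TubeModel, _check_inplane_isotropy, fit_circle_slice, propagate_fit


@dataclass
class UnwrappedMap:
    """Planar, isotropically calibrated projection of the tube surface."""

    pixels: np.ndarray          # (height, width); X circumferential, Y axial
    pixel_size: float           # um, isotropic
    theta_origin: float = 0.0   # radians mapped to X = 0
    row_radius: np.ndarray | None = None  # per-row source radius, um
    duplicated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise TubemapError("map must be 2D")
        if self.pixel_size <= 0:
            raise TubemapError("pixel_size must be > 0")
        if self.row_radius is not None:
            self.row_radius = np.asarray(self.row_radius, dtype=float)
            if self.row_radius.shape != (self.pixels.shape[0],):
                raise TubemapError("row_radius must have one entry per map row")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def base_width(self) -> int:
        """Width of one period (half the width when duplicated)."""
        return self.width // 2 if self.duplicated else self.width


def sample_ring(
    slice_image: np.ndarray,
    circle: CrownCircle,
    n_theta: int,
    theta_origin: float = 0.0,
) -> np.ndarray:
    """Angular max-intensity profile of the crown.

    A pixel at integer coordinates ``(y, x)`` belongs to the crown when its
    Euclidean distance ``d`` to the circle centre satisfies
    ``r - w/2 <= d <= r + w/2``.  Its angular bin is
    ``round((atan2(y - cy, x - cx) - theta_origin) / dtheta) mod n_theta``
    with ``dtheta = 2*pi/n_theta`` (bins centred on ``theta_origin + k*dtheta``).
    Bin value = max intensity over its crown pixels; an empty bin is an error.
    """
    if n_theta < 8:
        raise TubemapError(f"n_theta must be >= 8, got {n_theta}")
    img = np.asarray(slice_image)
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(yy - circle.cy, xx - circle.cx)
    crown = (d >= circle.r_inner) & (d <= circle.r_outer)
    if not crown.any():
        raise DomainError("crown entirely outside the image domain")
    dtheta = 2 * math.pi / n_theta
    ang = np.arctan2(yy[crown] - circle.cy, xx[crown] - circle.cx)
    rel = np.mod(ang - theta_origin, 2 * math.pi)
    bins = np.round(rel / dtheta).astype(int) % n_theta
    profile = np.full(n_theta, -np.inf)
    np.maximum.at(profile, bins, img[crown].astype(float))
    if np.any(np.isneginf(profile)):
        empty = int(np.flatnonzero(np.isneginf(profile))[0])
        raise DomainError(
            f"angular bin {empty} holds no crown pixel (n_theta={n_theta} too fine "
            f"for radius {circle.r})"
        )
    return profile


def unwrap_volume(
    volume: Volume,
    tube: TubeModel,
    theta_origin: float = 0.0,
    reference_radius: float | None = None,
) -> UnwrappedMap:
    """Project the volume onto the plane using the fitted tube.

    Row ``y`` of the map is the ring profile of slice ``y`` sampled on its
    own circle; the common width is ``round(2*pi*r_ref / dz)`` so that the
    circumferential pitch equals the axial pitch at the reference radius.
    """
    if not tube.circles:
        raise TubemapError("empty TubeModel")
    _check_inplane_isotropy(volume.spacing)
    dz, dy, dx = volume.spacing
    r_ref = tube.reference_radius if reference_radius is None else float(reference_radius)
    n_theta = int(round(2 * math.pi * r_ref / dz))
    rows, radii = [], []
    for circ in tube.circles:
        if circ.z >= volume.n_slices:
            raise TubemapError(f"tube circle at z={circ.z} beyond volume ({volume.n_slices} slices)")
        rows.append(sample_ring(volume.voxels[circ.z], circ, n_theta, theta_origin))
        radii.append(circ.r * dx)
    return UnwrappedMap(
        pixels=np.vstack(rows),
        pixel_size=dz,
        theta_origin=theta_origin,
        row_radius=np.array(radii),
        duplicated=False,
    )


def duplicate_map(umap: UnwrappedMap) -> UnwrappedMap:
    """Tile the map twice along X so seam-crossing contours become contiguous."""
    if umap.duplicated:
        raise TubemapError("map already duplicated")
    return UnwrappedMap(
        pixels=np.concatenate([umap.pixels, umap.pixels], axis=1),
        pixel_size=umap.pixel_size,
        theta_origin=umap.theta_origin,
        row_radius=None if umap.row_radius is None else umap.row_radius.copy(),
        duplicated=True,
    )


def unwrap_timelapse(
    volumes: list[Volume],
    init: CrownCircle,
    theta_origin: float = 0.0,
    **fit_kwargs,
) -> tuple[list[UnwrappedMap], list[TubeModel]]:
    """Unwrap a time-ordered sequence of frames with a common width.

    Frame ``t`` is initialized from frame ``t - 1``'s first-slice fit; the
    median of the per-frame reference radii fixes one width for the whole
    sequence.
    """
    if not volumes:
        raise TubemapError("empty time-lapse")
    spacing0 = volumes[0].spacing
    for v in volumes[1:]:
        if v.spacing != spacing0:
            raise TubemapError("time-lapse frames must share calibration")
    tubes: list[TubeModel] = []
    seed = init
    for vol in volumes:
        tube = propagate_fit(vol, replace(seed, z=0, flagged=False), **fit_kwargs)
        tubes.append(tube)
        seed = tube.circles[0]
    r_common = float(np.median([t.reference_radius for t in tubes]))
    maps = [
        unwrap_volume(vol, tube, theta_origin=theta_origin, reference_radius=r_common)
        for vol, tube in zip(volumes, tubes)
    ]
    return maps, tubes


def write_map(path: str | Path, umap: UnwrappedMap) -> None:
    """Write a map as single-channel TIFF plus a calibration sidecar CSV."""
    path = Path(path)
    tifffile.imwrite(str(path), umap.pixels.astype(np.float32))
    sidecar = path.with_suffix(".meta.csv")
    meta = pd.DataFrame(
        {
            "row": np.arange(umap.height),
            "row_radius_um": umap.row_radius
            if umap.row_radius is not None
            else np.full(umap.height, np.nan),
        }
    )
    meta.insert(0, "pixel_size_um", umap.pixel_size)
    meta.insert(1, "theta_origin_rad", umap.theta_origin)
    meta.insert(2, "duplicated", umap.duplicated)
    meta.to_csv(sidecar, index=False)
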