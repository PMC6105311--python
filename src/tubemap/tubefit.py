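"""Slice-wise crown-constrained circle fitting and tube-axis assembly.

Each Z slice of the reoriented volume shows the vessel wall as a ring of
bright membrane signal.  The wall is located by a circle whose *crown*
(annulus of width ``w`` centred on the radius) should capture as much
signal as possible while the lumen inside the crown stays dark.  Repeating
the fit slice by slice, seeding each slice with its predecessor, yields the
tube's central axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError, FitError, TubemapError
from .io import Volume

DEFAULT_CROWN_WIDTH = 3.0      # in-plane px
DEFAULT_LAMBDA = 1.0
DEFAULT_SEARCH = 3             # px, each of +-center and +-radius
DEFAULT_MAX_RADIUS_STEP = 2.0  # px between consecutive slices


@dataclass
class CrownCircle:
    """A fitted circle on one slice, with its scoring crown.

    Coordinates and radii are in in-plane pixels; ``score`` is the crown
    objective value and ``flagged`` marks a carried-over (not re-fitted) result.
    """

    z: int
    cx: float
    cy: float
    r: float
    crown_width: float = DEFAULT_CROWN_WIDTH
    score: float = math.nan
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise DomainError(f"radius must be > 0, got {self.r}")
        if self.crown_width <= 0:
            raise DomainError(f"crown width must be > 0, got {self.crown_width}")
        if self.r - self.crown_width / 2 <= 0:
            raise DomainError(
                f"inner circle degenerate: r={self.r}, crown_width={self.crown_width}"
            )

    @property
    def r_inner(self) -> float:
        return self.r - self.crown_width / 2

    @property
    def r_outer(self) -> float:
        return self.r + self.crown_width / 2


@dataclass
class TubeModel:
    """Ordered per-slice circles plus the derived central axis (um)."""

    circles: list[CrownCircle]
    axis: np.ndarray            # (n, 3) columns (cx_um, cy_um, z_um)
    reference_radius: float     # um, median fitted radius
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.circles) < 2:
            raise TubemapError("TubeModel needs >= 2 fitted slices")
        zs = [c.z for c in self.circles]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise TubemapError("slice indices must be strictly increasing")

    def radii_px(self) -> np.ndarray:
        return np.array([c.r for c in self.circles])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": [c.z for c in self.circles],
                "cx": [c.cx for c in self.circles],
                "cy": [c.cy for c in self.circles],
                "r": [c.r for c in self.circles],
                "score": [c.score for c in self.circles],
                "flagged": [c.flagged for c in self.circles],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_inplane_isotropy(spacing: tuple[float, float, float]) -> None:
    _, dy, dx = spacing
    if not math.isclose(dy, dx, rel_tol=1e-6):
        raise CalibrationError(
            f"in-plane spacing must be isotropic for circle fitting (dy={dy}, dx={dx})"
        )


def reorient(volume: Volume, axis_spec) -> Volume:
    """Reorient a volume so its slice normal approximates the tube axis.

    ``axis_spec`` is either a permutation of ``(0, 1, 2)`` (new axis order
    in (z, y, x) index space) or a pair of small rotation angles
    ``(rot_zy_deg, rot_zx_deg)`` applied about the x and y axes; rotation
    requires isotropic spacing along the axes it mixes.
    """
    spec = tuple(axis_spec)
    if sorted(spec) == [0, 1, 2]:
        perm = tuple(int(a) for a in spec)
        vox = np.transpose(volume.voxels, perm)
        spacing = tuple(volume.spacing[a] for a in perm)
        if vox.shape[1] < 8 or vox.shape[2] < 8:
            raise DomainError("reorientation leaves no full slice of data")
        return Volume(voxels=vox.copy(), spacing=spacing, time_index=volume.time_index)
    if len(spec) == 2:
        from scipy import ndimage

        rot_zy, rot_zx = (float(a) for a in spec)
        vox = volume.voxels.astype(float)
        dz, dy, dx = volume.spacing
        if abs(rot_zy) > 1e-9 and not math.isclose(dz, dy, rel_tol=1e-6):
            raise CalibrationError("rotation about x mixes z and y: needs dz == dy")
        if abs(rot_zx) > 1e-9 and not math.isclose(dz, dx, rel_tol=1e-6):
            raise CalibrationError("rotation about y mixes z and x: needs dz == dx")
        if abs(rot_zy) > 1e-9:
            vox = ndimage.rotate(vox, rot_zy, axes=(0, 1), order=1, reshape=True)
        if abs(rot_zx) > 1e-9:
            vox = ndimage.rotate(vox, rot_zx, axes=(0, 2), order=1, reshape=True)
        vox = np.clip(vox, 0, None)
        if vox.shape[0] < 1 or vox.shape[1] < 8 or vox.shape[2] < 8:
            raise DomainError("rotation leaves no full slice of data")
        return Volume(voxels=vox, spacing=volume.spacing, time_index=volume.time_index)
    raise TubemapError(f"axis_spec must be a 3-permutation or two angles, got {axis_spec!r}")


def _crown_masks(shape: tuple[int, int], circle: CrownCircle):
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(yy - circle.cy, xx - circle.cx)
    crown = (d >= circle.r_inner) & (d <= circle.r_outer)
    inner = d < circle.r_inner
    return crown, inner


def crown_objective(
    slice_image: np.ndarray,
    circle: CrownCircle,
    lam: float = DEFAULT_LAMBDA,
    normalize: bool = True,
) -> float:
    """Crown score: bright annulus, dark lumen.

    Pixels are classified by the Euclidean distance of their integer centre
    to the circle centre: the *crown* is ``r - w/2 <= d <= r + w/2`` and the
    *inner* disk is ``d < r - w/2``.  The score is
    ``crown_term - lam * inner_term`` where, with ``normalize=True``
    (default), each term is the mean intensity of its region; with
    ``normalize=False`` the raw sums are used.
    """
    img = np.asarray(slice_image)
    crown, inner = _crown_masks(img.shape, circle)
    n_crown = int(crown.sum())
    if n_crown == 0:
        raise DomainError("crown entirely outside the image domain")
    n_inner = int(inner.sum())
    crown_sum = float(img[crown].sum())
    inner_sum = float(img[inner].sum())
    if normalize:
        crown_term = crown_sum / n_crown
        inner_term = inner_sum / n_inner if n_inner else 0.0
    else:
        crown_term, inner_term = crown_sum, inner_sum
    return crown_term - lam * inner_term


def fit_circle_slice(
    slice_image: np.ndarray,
    init: CrownCircle,
    search_center: int = DEFAULT_SEARCH,
    search_radius: int = DEFAULT_SEARCH,
    step: int = 1,
    lam: float = DEFAULT_LAMBDA,
    normalize: bool = True,
) -> CrownCircle:
    """Exhaustive local grid search maximizing :func:`crown_objective`.

    Candidates are ``init`` shifted by multiples of ``step`` within
    ``+-search_center`` px (each of cx, cy) and ``+-search_radius`` px of
    radius.  Ties are broken toward the candidate nearest the
    initialization, then lexicographically on ``(cx, cy, r)``.
    """
    img = np.asarray(slice_image)
    offsets_c = range(-search_center, search_center + 1, step)
    offsets_r = range(-search_radius, search_radius + 1, step)
    best = None  # (score, -dist2, neg lex key) style comparison done explicitly
    for dcx in offsets_c:
        for dcy in offsets_c:
            for dr in offsets_r:
                cx, cy, r = init.cx + dcx, init.cy + dcy, init.r + dr
                if r - init.crown_width / 2 <= 0:
                    continue
                cand = replace(init, cx=cx, cy=cy, r=r, flagged=False)
                try:
                    score = crown_objective(img, cand, lam=lam, normalize=normalize)
                except DomainError:
                    continue
                dist2 = dcx * dcx + dcy * dcy + dr * dr
                key = (score, -dist2, (-cx, -cy, -r))
                if best is None or key > best[0]:
                    best = (key, replace(cand, score=score))
    if best is None:
        raise FitError("empty feasible search grid")
    return best[1]


def propagate_fit(
    volume: Volume,
    init: CrownCircle,
    quality_floor: float = 0.0,
    search_center: int = DEFAULT_SEARCH,
    search_radius: int = DEFAULT_SEARCH,
    step: int = 1,
    lam: float = DEFAULT_LAMBDA,
    max_radius_step: float = DEFAULT_MAX_RADIUS_STEP,
    refit_radius: bool = True,
) -> TubeModel:
    """Fit every slice, seeding each with the previous slice's circle.

    Slices whose best score falls below ``quality_floor`` reuse the previous
    circle and are flagged.  The radius search per slice is limited to
    ``max_radius_step`` px; set ``refit_radius=False`` to hold the radius
    fixed after the first slice.
    """
    _check_inplane_isotropy(volume.spacing)
    if init.z != 0:
        raise FitError("propagate_fit expects the initialization on the first slice (z=0)")
    dz, dy, dx = volume.spacing
    dr_limit = min(search_radius, int(math.floor(max_radius_step))) if refit_radius else 0

    circles: list[CrownCircle] = []
    prev = init
    for z in range(volume.n_slices):
        fitted = fit_circle_slice(
            volume.voxels[z],
            replace(prev, z=z, flagged=False),
            search_center=search_center,
            search_radius=search_radius if z == 0 else dr_limit,
            step=step,
            lam=lam,
        )
        if fitted.score < quality_floor:
            if z == 0:
                raise FitError(
                    f"first slice below quality floor ({fitted.score:.4g} < {quality_floor:.4g})"
                )
            fitted = replace(prev, z=z, score=fitted.score, flagged=True)
        else:
            fitted = replace(fitted, z=z)
        circles.append(fitted)
        prev = fitted

    axis = np.array([(c.cx * dx, c.cy * dy, c.z * dz) for c in circles])
    reference_radius = float(np.median([c.r for c in circles])) * dx
    return TubeModel(
        circles=circles, axis=axis, reference_radius=reference_radius, spacing=volume.spacing
    )
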