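"""Ground-truthed synthetic inputs: cylindrical vessel volumes and
oscillatory spot-track pairs.

The tube phantom paints a bright membrane shell on a (possibly drifting,
radius-varying) cylinder, tessellates the surface into cells with a
wrap-around Voronoi diagram on the unrolled ``(r*theta, z)`` plane, brightens
cell borders and junction vertices, then applies blur and additive Gaussian
noise.  All randomness flows from a single seed, bit-exactly.

The track phantom integrates a contraction/plateau phase plan, superposes a
sinusoidal oscillation of known period, places the two spots symmetrically,
and degrades the result with positional noise and random dropouts.  The
analytic minima of the planted closing speed (at exact multiples of the
period) are part of the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import KDTree, Voronoi

from .errors import TubemapError
from .io import SpotTrack, Volume


# ---------------------------------------------------------------------------
# tube phantom
# ---------------------------------------------------------------------------

@dataclass
class TubePhantomSpec:
    n_slices: int = 32
    image_size: tuple[int, int] = (64, 64)       # (ny, nx) px
    spacing: tuple[float, float, float] = (0.6, 0.2, 0.2)  # (dz, dy, dx) um
    radius_profile: float | np.ndarray = 16.0    # px, scalar or per-slice
    center_profile: tuple[float, float] | np.ndarray = (32.0, 32.0)  # (cx, cy) px
    membrane_amplitude: float = 100.0
    membrane_thickness: float = 3.0              # px
    n_cells: int = 0                             # Voronoi seeds on the surface
    border_gain: float = 1.5                     # border brightness multiple
    junction_spot_gain: float = 2.0              # vertex brightness multiple
    border_halfwidth: float = 1.2                # px, half-width of border band
    seed_aspect: float = 1.0                     # > 1 elongates cells axially
    psf_sigma: float = 0.0                       # px, in-plane blur
    noise_sigma: float = 0.0
    background: float = 0.0
    seed: int = 0
    # optional painted features for geometry tests
    stripe_theta: float | None = None            # bright longitudinal stripe (rad)
    stripe_halfwidth: float = 0.15               # rad
    patch: tuple[float, float, float] | None = None  # (theta_c, z_c_idx, side_um)
    patch_gain: float = 2.5

    def resolved_radii(self) -> np.ndarray:
        r = np.broadcast_to(np.asarray(self.radius_profile, float), (self.n_slices,)).copy()
        return r

    def resolved_centers(self) -> np.ndarray:
        c = np.asarray(self.center_profile, float)
        if c.ndim == 1:
            c = np.broadcast_to(c, (self.n_slices, 2)).copy()
        return c

    def validate(self) -> None:
        if self.n_slices < 2:
            raise TubemapError("phantom needs >= 2 slices")
        ny, nx = self.image_size
        radii = self.resolved_radii()
        centers = self.resolved_centers()
        if radii.shape != (self.n_slices,) or centers.shape != (self.n_slices, 2):
            raise TubemapError("radius/center profiles must match n_slices")
        if np.any(radii - self.membrane_thickness / 2 <= 0):
            raise TubemapError("inner circle degenerate: radius <= thickness/2")
        outer = radii + self.membrane_thickness / 2
        cx, cy = centers[:, 0], centers[:, 1]
        if (
            np.any(cx - outer < 0)
            or np.any(cx + outer > nx - 1)
            or np.any(cy - outer < 0)
            or np.any(cy + outer > ny - 1)
        ):
            raise TubemapError("crown leaves the image domain for some slice")
        if self.membrane_amplitude <= 0 or self.membrane_thickness <= 0:
            raise TubemapError("membrane amplitude and thickness must be > 0")
        if self.noise_sigma < 0 or self.psf_sigma < 0 or self.background < 0:
            raise TubemapError("noise/blur/background must be >= 0")


@dataclass
class TubeGroundTruth:
    centers_px: np.ndarray          # (n_slices, 2) true (cx, cy)
    radii_px: np.ndarray            # (n_slices,)
    reference_radius_px: float      # median radius
    seeds: np.ndarray               # (n_cells, 2) as (theta, z_index)
    border_points: np.ndarray       # (M, 2) as (theta, z_index) on cell borders
    cell_arcs: list[tuple[float, float]]  # per-cell occupied theta arc (start, extent)
    spacing: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def map_position(self, theta: float, z_index: float, theta_origin: float = 0.0,
                     n_theta: int | None = None) -> tuple[float, float]:
        """Analytic (theta, z) -> (X_col, Y_row) transform for a map of
        ``n_theta`` columns (X returned modulo ``n_theta``)."""
        if n_theta is None:
            raise TubemapError("n_theta required")
        dtheta = 2 * math.pi / n_theta
        x = np.mod((theta - theta_origin) / dtheta, n_theta)
        return float(x), float(z_index)


def _circular_arc(us: np.ndarray, c: float) -> tuple[float, float]:
    u = np.sort(np.unique(np.mod(us, c)))
    if u.size == 1:
        return float(u[0]), 0.0
    gaps = np.diff(np.concatenate([u, [u[0] + c]]))
    k = int(np.argmax(gaps))
    return float(u[(k + 1) % u.size]), float(c - gaps[k])


def make_tube_phantom(spec: TubePhantomSpec) -> tuple[Volume, TubeGroundTruth]:
    """Render the phantom volume and return it with its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.image_size
    dz, dy, dx = spec.spacing
    radii = spec.resolved_radii()
    centers = spec.resolved_centers()
    r_ref = float(np.median(radii))
    circ_px = 2 * math.pi * r_ref
    zscale = dz / dx            # slice index -> px along the axis
    aspect = spec.seed_aspect
    z_extent = (spec.n_slices - 1) * zscale

    # --- surface tessellation in metric coordinates (u, w) = (r*theta, z_px/aspect)
    seeds_uw = np.empty((0, 2))
    tree = None
    if spec.n_cells > 0:
        u = rng.uniform(0, circ_px, spec.n_cells)
        w = rng.uniform(0, z_extent, spec.n_cells) / aspect
        seeds_uw = np.column_stack([u, w])
        reps = np.concatenate(
            [seeds_uw + [off, 0.0] for off in (-circ_px, 0.0, circ_px)]
        )
        tree = KDTree(reps)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    vox = np.full((spec.n_slices, ny, nx), float(spec.background))
    half_th = spec.membrane_thickness / 2
    for z in range(spec.n_slices):
        cx, cy = centers[z]
        d = np.hypot(yy - cy, xx - cx)
        shell = np.abs(d - radii[z]) <= half_th
        if not shell.any():
            continue
        phi = np.mod(np.arctan2(yy[shell] - cy, xx[shell] - cx), 2 * math.pi)
        tex = np.ones(phi.size)
        if tree is not None:
            pts = np.column_stack([phi * r_ref, np.full(phi.size, z * zscale / aspect)])
            dist, _ = tree.query(pts, k=3)
            border = dist[:, 1] - dist[:, 0] <= spec.border_halfwidth
            vertex = dist[:, 2] - dist[:, 0] <= spec.border_halfwidth * 1.5
            tex[border] = spec.border_gain
            tex[vertex] = spec.junction_spot_gain
        if spec.stripe_theta is not None:
            dphi = np.abs(np.angle(np.exp(1j * (phi - spec.stripe_theta))))
            tex = np.maximum(tex, np.where(dphi <= spec.stripe_halfwidth, spec.border_gain, 1.0))
        if spec.patch is not None:
            theta_c, z_c, side_um = spec.patch
            dphi = np.abs(np.angle(np.exp(1j * (phi - theta_c))))
            in_x = dphi * r_ref * dx <= side_um / 2
            in_y = abs(z - z_c) * dz <= side_um / 2
            if in_y:
                tex = np.maximum(tex, np.where(in_x, spec.patch_gain, 1.0))
        plane = vox[z]
        plane[shell] = spec.background + spec.membrane_amplitude * tex

    if spec.psf_sigma > 0:
        vox = ndimage.gaussian_filter(vox, sigma=(0, spec.psf_sigma, spec.psf_sigma))
    if spec.noise_sigma > 0:
        vox = vox + rng.normal(0.0, spec.noise_sigma, vox.shape)
    vox = np.clip(vox, 0, None)

    border_points = _voronoi_border_points(seeds_uw, circ_px, z_extent, aspect, zscale, r_ref)
    cell_arcs = _occupied_arcs(tree, spec.n_cells, circ_px, z_extent, aspect, r_ref)
    seeds_tz = (
        np.column_stack([seeds_uw[:, 0] / r_ref, seeds_uw[:, 1] * aspect / zscale])
        if seeds_uw.size
        else seeds_uw
    )
    truth = TubeGroundTruth(
        centers_px=centers,
        radii_px=radii,
        reference_radius_px=r_ref,
        seeds=seeds_tz,
        border_points=border_points,
        cell_arcs=cell_arcs,
        spacing=spec.spacing,
    )
    return Volume(voxels=vox, spacing=spec.spacing), truth


def _voronoi_border_points(
    seeds_uw: np.ndarray,
    circ_px: float,
    z_extent: float,
    aspect: float,
    zscale: float,
    r_ref: float,
    samples_per_ridge: int = 25,
) -> np.ndarray:
    """Sample ground-truth cell-border curves as (theta, z_index) points."""
    if seeds_uw.shape[0] < 2:
        return np.empty((0, 2))
    reps = []
    for off in (-circ_px, 0.0, circ_px):
        reps.append(seeds_uw + [off, 0.0])
    base = np.concatenate(reps)
    # guard rows close the diagram above and below the axial range
    n_guard = max(8, seeds_uw.shape[0])
    gu = np.linspace(-circ_px, 2 * circ_px, 3 * n_guard, endpoint=False)
    guards = np.concatenate(
        [
            np.column_stack([gu, np.full(gu.size, -0.6 * max(z_extent / aspect, 1.0))]),
            np.column_stack([gu, np.full(gu.size, 1.6 * max(z_extent / aspect, 1.0))]),
        ]
    )
    pts = np.concatenate([base, guards])
    n_real = base.shape[0]
    vor = Voronoi(pts)
    out = []
    frac = np.linspace(0, 1, samples_per_ridge)
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_real or q >= n_real:  # guard ridges are not cell borders
            continue
        if -1 in verts:
            continue
        a, b = vor.vertices[verts[0]], vor.vertices[verts[1]]
        seg = a[None, :] + frac[:, None] * (b - a)[None, :]
        keep = (
            (seg[:, 0] >= 0)
            & (seg[:, 0] < circ_px)
            & (seg[:, 1] >= 0)
            & (seg[:, 1] <= z_extent / aspect)
        )
        out.append(seg[keep])
    if not out:
        return np.empty((0, 2))
    uw = np.concatenate(out)
    theta = uw[:, 0] / r_ref
    z_idx = uw[:, 1] * aspect / zscale
    return np.column_stack([theta, z_idx])


def _occupied_arcs(
    tree: KDTree | None,
    n_cells: int,
    circ_px: float,
    z_extent: float,
    aspect: float,
    r_ref: float,
    n_theta: int = 360,
    n_z: int = 48,
) -> list[tuple[float, float]]:
    """Per-cell occupied circumferential arc (theta_start, theta_extent)."""
    if tree is None or n_cells == 0:
        return []
    u = np.linspace(0, circ_px, n_theta, endpoint=False)
    w = np.linspace(0, z_extent / aspect, n_z)
    uu, ww = np.meshgrid(u, w)
    _, owner = tree.query(np.column_stack([uu.ravel(), ww.ravel()]), k=1)
    owner = owner % n_cells  # collapse wrap replicas
    arcs = []
    for cell in range(n_cells):
        us = uu.ravel()[owner == cell]
        if us.size == 0:
            arcs.append((0.0, 0.0))
            continue
        start, extent = _circular_arc(us, circ_px)
        arcs.append((start / r_ref, extent / r_ref))
    return arcs


# ---------------------------------------------------------------------------
# track phantom
# ---------------------------------------------------------------------------

@dataclass
class TrackPhantomSpec:
    duration: float = 400.0                # minutes
    sampling_interval: float = 2.0         # minutes
    initial_distance: float = 25.0         # um
    phases: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("contraction", 400.0, 0.03)]
    )  # (kind, duration min, distance-shrink rate um/min)
    oscillation_amplitude: float = 0.5     # um
    period: float = 40.0                   # minutes
    dropout_probability: float = 0.0
    positional_noise_sigma: float = 0.0    # um
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_interval <= 0 or self.duration <= 0:
            raise TubemapError("duration and sampling_interval must be > 0")
        if self.period <= 2 * self.sampling_interval:
            raise TubemapError("period must exceed twice the sampling interval")
        if not 0 <= self.dropout_probability < 1:
            raise TubemapError("dropout_probability must be in [0, 1)")
        for kind, dur, _rate in self.phases:
            if kind not in ("contraction", "plateau"):
                raise TubemapError(f"unknown phase kind {kind!r}")
            if dur <= 0:
                raise TubemapError("phase durations must be > 0")


@dataclass
class TrackGroundTruth:
    t: np.ndarray
    d: np.ndarray                 # planted distance at every sample time
    minima_times: np.ndarray      # analytic closing-speed minima (multiples of T)
    period: float


def _integrated_shrink(t: np.ndarray, phases) -> np.ndarray:
    """Cumulative distance decrease from the piecewise-constant phase plan."""
    shrink = np.zeros_like(t)
    start = 0.0
    for _kind, dur, rate in phases:
        overlap = np.clip(t - start, 0, dur)
        shrink += rate * overlap
        start += dur
    return shrink


def make_track_pair(
    spec: TrackPhantomSpec,
) -> tuple[SpotTrack, SpotTrack, TrackGroundTruth]:
    """Generate an (anterior, posterior) spot-track pair with planted dynamics."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.sampling_interval / 2, spec.sampling_interval)
    d = (
        spec.initial_distance
        - _integrated_shrink(t, spec.phases)
        + spec.oscillation_amplitude * np.sin(2 * math.pi * t / spec.period)
    )
    if np.any(d < 0):
        raise TubemapError("phase plan drives the distance below 0")

    sig = spec.positional_noise_sigma
    ax = -d / 2 + rng.normal(0, sig, t.size) if sig else -d / 2
    ay = rng.normal(0, sig, t.size) if sig else np.zeros_like(t)
    px = d / 2 + rng.normal(0, sig, t.size) if sig else d / 2
    py = rng.normal(0, sig, t.size) if sig else np.zeros_like(t)

    keep_a = rng.random(t.size) >= spec.dropout_probability
    keep_p = rng.random(t.size) >= spec.dropout_probability
    if not keep_a.any() or not keep_p.any():
        raise TubemapError("dropout removed every sample")

    anterior = SpotTrack(label="anterior", t=t[keep_a], x=ax[keep_a], y=ay[keep_a])
    posterior = SpotTrack(label="posterior", t=t[keep_p], x=px[keep_p], y=py[keep_p])
    if spec.oscillation_amplitude > 0:
        minima = np.arange(spec.period, spec.duration, spec.period)
    else:
        minima = np.array([])  # flat closing speed plants no cycle
    truth = TrackGroundTruth(t=t, d=d, minima_times=minima, period=spec.period)
    return anterior, posterior, truth
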