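"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected result with naive per-element loops and
must stay independent of the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def crown_objective_bruteforce(img, cx, cy, r, w, lam=1.0, normalize=True):
    """Per-pixel classification loop version of the crown score."""
    crown_sum = inner_sum = 0.0
    n_crown = n_inner = 0
    ny, nx = img.shape
    for y in range(ny):
        for x in range(nx):
            d = math.sqrt((y - cy) ** 2 + (x - cx) ** 2)
            if r - w / 2 <= d <= r + w / 2:
                crown_sum += img[y, x]
                n_crown += 1
            elif d < r - w / 2:
                inner_sum += img[y, x]
                n_inner += 1
    if n_crown == 0:
        raise ValueError("no crown pixel")
    if normalize:
        crown_term = crown_sum / n_crown
        inner_term = inner_sum / n_inner if n_inner else 0.0
    else:
        crown_term, inner_term = crown_sum, inner_sum
    return crown_term - lam * inner_term


def fit_circle_bruteforce(img, cx0, cy0, r0, w, dc, dr, step=1, lam=1.0):
    """Exhaustive enumeration of the search grid; same tie-breaking rules."""
    best = None
    for dcx in range(-dc, dc + 1, step):
        for dcy in range(-dc, dc + 1, step):
            for drr in range(-dr, dr + 1, step):
                cx, cy, r = cx0 + dcx, cy0 + dcy, r0 + drr
                if r - w / 2 <= 0:
                    continue
                try:
                    score = crown_objective_bruteforce(img, cx, cy, r, w, lam=lam)
                except ValueError:
                    continue
                dist2 = dcx * dcx + dcy * dcy + drr * drr
                key = (score, -dist2, (-cx, -cy, -r))
                if best is None or key > best[0]:
                    best = (key, (cx, cy, r, score))
    return best[1]


def sector_max_bruteforce(img, cx, cy, r, w, n_theta, theta_origin=0.0):
    """Per-pixel loop: classify crown pixels into angular bins, take max."""
    profile = [None] * n_theta
    dtheta = 2 * math.pi / n_theta
    ny, nx = img.shape
    for y in range(ny):
        for x in range(nx):
            d = math.sqrt((y - cy) ** 2 + (x - cx) ** 2)
            if not (r - w / 2 <= d <= r + w / 2):
                continue
            ang = math.atan2(y - cy, x - cx)
            rel = (ang - theta_origin) % (2 * math.pi)
            k = int(round(rel / dtheta)) % n_theta
            val = float(img[y, x])
            if profile[k] is None or val > profile[k]:
                profile[k] = val
    return profile


def minima_with_prominence_bruteforce(v, threshold):
    """Enumerate interior minima (plateaus at their first sample) and compute
    prominence by exhaustive saddle search; keep those above threshold."""
    v = list(map(float, v))
    n = len(v)
    kept = []
    for i in range(1, n - 1):
        # plateau-aware interior minimum test, minimum reported at first sample
        if not v[i] < v[i - 1]:
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j >= n - 1 or not v[j + 1] > v[i]:
            continue
        # exhaustive prominence: highest wall on each side before a lower value
        left_candidates = []
        for a in range(i - 1, -1, -1):
            if v[a] < v[i]:
                break
            left_candidates.append(v[a])
        right_candidates = []
        for b in range(i + 1, n):
            if v[b] < v[i]:
                break
            right_candidates.append(v[b])
        left_wall = max(left_candidates) if left_candidates else v[i]
        right_wall = max(right_candidates) if right_candidates else v[i]
        prom = min(left_wall, right_wall) - v[i]
        if prom > threshold:
            kept.append(i)
    return kept


def polygon_area_montecarlo(contour, n_points=1_000_000, seed=0):
    """Monte-Carlo rasterization area estimate via even-odd ray crossing."""
    contour = np.asarray(contour, float)
    lo = contour.min(axis=0)
    hi = contour.max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    inside = np.zeros(n_points, dtype=bool)
    n = contour.shape[0]
    for i in range(n):
        x1, y1 = contour[i]
        x2, y2 = contour[(i + 1) % n]
        crosses = (y1 > pts[:, 1]) != (y2 > pts[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (pts[:, 1] - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (pts[:, 0] < xint)
    box = np.prod(hi - lo)
    return inside.mean() * box


def delaunay_neighbors_cylinder(seeds_uz, circumference, extra_points=None):
    """Delaunay adjacency of seeds on the unrolled cylinder, wrap-aware.

    ``extra_points`` (e.g. guard rows used to close Voronoi cells) join the
    triangulation but contribute no adjacency of their own.
    """
    from scipy.spatial import Delaunay

    seeds_uz = np.asarray(seeds_uz, float)
    n = seeds_uz.shape[0]
    reps = np.concatenate(
        [seeds_uz + [off, 0.0] for off in (-circumference, 0.0, circumference)]
    )
    pts = reps if extra_points is None else np.concatenate([reps, extra_points])
    tri = Delaunay(pts)
    n_real = reps.shape[0]
    central = range(n, 2 * n)  # only central copies are fully buffered
    adj = {i: set() for i in range(n)}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if b >= n_real or a not in central:
                    continue
                ia, ib = int(a) - n, int(b) % n
                if ia != ib:
                    adj[ia].add(ib)
                    adj[ib].add(ia)
    return adj
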