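"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (exhaustive loops, O(n²) scans)
and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximiser over integer levels.

    Scans every integer level t in [min, max); foreground is value > t.
    Ties resolve to the lowest level, matching an ascending argmax.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    best_t, best_v = None, -1.0
    for t in range(int(vals.min()), int(vals.max())):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)


def brute_force_inscribed_circle(mask: np.ndarray) -> tuple[float, np.ndarray]:
    """O(n²) largest inscribed circle: for every foreground pixel, the
    minimum distance to any background pixel, maximised over pixels.

    Returns (radius, array of maximising pixel coordinates).
    """
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    assert fg.size and bg.size
    d2 = ((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
    min_d = np.sqrt(d2.min(axis=1))
    r = min_d.max()
    return float(r), fg[np.isclose(min_d, r)]


def brute_force_small_object_filter(mask: np.ndarray, min_px: float) -> np.ndarray:
    """Flood-fill 8-connected labelling + size filter, no library calls."""
    out = np.zeros_like(mask, dtype=bool)
    seen = np.zeros_like(mask, dtype=bool)
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r0, c0 in np.argwhere(mask):
        if seen[r0, c0]:
            continue
        stack, comp = [(r0, c0)], []
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                    if mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        if len(comp) >= min_px:
            for r, c in comp:
                out[r, c] = True
    return out


def brute_force_3d_zspan_filter(vox: np.ndarray, min_slices: int) -> np.ndarray:
    """26-connected 3D labelling + z-extent filter via flood fill."""
    out = np.zeros_like(vox, dtype=bool)
    seen = np.zeros_like(vox, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    nz, ny, nx = vox.shape
    for z0, y0, x0 in np.argwhere(vox):
        if seen[z0, y0, x0]:
            continue
        stack, comp = [(z0, y0, x0)], []
        seen[z0, y0, x0] = True
        while stack:
            z, y, x = stack.pop()
            comp.append((z, y, x))
            for dz, dy, dx in offsets:
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    if vox[zz, yy, xx] and not seen[zz, yy, xx]:
                        seen[zz, yy, xx] = True
                        stack.append((zz, yy, xx))
        zs = [p[0] for p in comp]
        if max(zs) - min(zs) + 1 >= min_slices:
            for p in comp:
                out[p] = True
    return out


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from ordered vertices via the shoelace formula."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def monte_carlo_hull_area(points: np.ndarray, rng, n_samples: int = 200_000) -> float:
    """Monte-Carlo estimate of the convex-hull area of a 2D point set."""
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    box = np.prod(hi - lo)
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    # a sample is inside the hull iff it is a convex combination: test via
    # linear programming would be heavy; use the support-function test on
    # hull edges computed independently with a gift-wrapping scan
    hull = _gift_wrap(points)
    inside = np.ones(n_samples, dtype=bool)
    m = len(hull)
    for i in range(m):
        a, b = hull[i], hull[(i + 1) % m]
        edge = b - a
        cross = edge[0] * (samples[:, 1] - a[1]) - edge[1] * (samples[:, 0] - a[0])
        inside &= cross >= -1e-12
    return box * inside.mean()


def _gift_wrap(points: np.ndarray) -> list[np.ndarray]:
    """Jarvis-march convex hull (counter-clockwise vertex list)."""
    pts = np.unique(points.astype(float), axis=0)
    start = pts[np.lexsort((pts[:, 1], pts[:, 0]))][0]
    hull, p = [start], start
    while True:
        q = pts[0] if not np.array_equal(pts[0], p) else pts[1]
        for r in pts:
            cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
            if cross < 0 or (cross == 0 and np.linalg.norm(r - p) > np.linalg.norm(q - p)):
                q = r
        if np.array_equal(q, start):
            break
        hull.append(q)
        p = q
    return hull
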