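"""Numba kernels for orientation-averaged projected areas of disk unions.

Both estimators share the same geometry: atoms rotated into a viewing frame
become disks of radius ``element radius + probe`` in the xy-plane, and the
per-orientation quantity is the area of their union.  ``pa_areas_mc`` uses
uniform rejection sampling inside the bounding box with a cell list for the
point-in-union test; ``pa_areas_grid`` rasterises the union on square cells
and serves as the oracle.
"""

import numpy as np
from numba import njit

_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _xorshift(state):
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _union_area_mc(x, y, r, n_points, seed):
    """MC area of the union of disks (centres x,y radii r) via cell list."""
    n = x.size
    rmax = 0.0
    for i in range(n):
        if r[i] > rmax:
            rmax = r[i]
    if n == 1:
        return np.pi * r[0] * r[0]
    xmin, xmax = x[0] - r[0], x[0] + r[0]
    ymin, ymax = y[0] - r[0], y[0] + r[0]
    for i in range(1, n):
        if x[i] - r[i] < xmin:
            xmin = x[i] - r[i]
        if x[i] + r[i] > xmax:
            xmax = x[i] + r[i]
        if y[i] - r[i] < ymin:
            ymin = y[i] - r[i]
        if y[i] + r[i] > ymax:
            ymax = y[i] + r[i]
    w, h = xmax - xmin, ymax - ymin
    cell = rmax
    nx = max(1, int(np.ceil(w / cell)))
    ny = max(1, int(np.ceil(h / cell)))
    # cell list over disk centres (a disk reaches at most one cell away)
    counts = np.zeros(nx * ny + 1, dtype=np.int64)
    cix = np.empty(n, dtype=np.int64)
    ciy = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((x[i] - xmin) / cell)
        cy = int((y[i] - ymin) / cell)
        if cx >= nx:
            cx = nx - 1
        if cy >= ny:
            cy = ny - 1
        cix[i] = cx
        ciy[i] = cy
        counts[cy * nx + cx + 1] += 1
    for k in range(1, nx * ny + 1):
        counts[k] += counts[k - 1]
    fill = counts[:-1].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = ciy[i] * nx + cix[i]
        order[fill[c]] = i
        fill[c] += 1

    state = np.uint64(seed) | np.uint64(1)
    hits = 0
    for _ in range(n_points):
        state = _xorshift(state)
        px = xmin + w * (float(state >> np.uint64(11)) * _INV53)
        state = _xorshift(state)
        py = ymin + h * (float(state >> np.uint64(11)) * _INV53)
        cx = int((px - xmin) / cell)
        cy = int((py - ymin) / cell)
        if cx >= nx:
            cx = nx - 1
        if cy >= ny:
            cy = ny - 1
        inside = False
        for gy in range(max(0, cy - 1), min(ny, cy + 2)):
            if inside:
                break
            for gx in range(max(0, cx - 1), min(nx, cx + 2)):
                c = gy * nx + gx
                for k in range(counts[c], counts[c + 1]):
                    i = order[k]
                    dx = px - x[i]
                    dy = py - y[i]
                    if dx * dx + dy * dy <= r[i] * r[i]:
                        inside = True
                        break
                if inside:
                    break
        if inside:
            hits += 1
    return w * h * hits / n_points


@njit(cache=True)
def _union_area_grid(x, y, r, cell):
    """Rasterised area: cells whose centre lies inside any disk."""
    n = x.size
    if n == 1:
        return np.pi * r[0] * r[0]
    xmin, xmax = x[0] - r[0], x[0] + r[0]
    ymin, ymax = y[0] - r[0], y[0] + r[0]
    for i in range(1, n):
        if x[i] - r[i] < xmin:
            xmin = x[i] - r[i]
        if x[i] + r[i] > xmax:
            xmax = x[i] + r[i]
        if y[i] - r[i] < ymin:
            ymin = y[i] - r[i]
        if y[i] + r[i] > ymax:
            ymax = y[i] + r[i]
    nx = int(np.ceil((xmax - xmin) / cell)) + 1
    ny = int(np.ceil((ymax - ymin) / cell)) + 1
    grid = np.zeros((ny, nx), dtype=np.uint8)
    for i in range(n):
        lo_x = max(0, int((x[i] - r[i] - xmin) / cell) - 1)
        hi_x = min(nx, int((x[i] + r[i] - xmin) / cell) + 2)
        lo_y = max(0, int((y[i] - r[i] - ymin) / cell) - 1)
        hi_y = min(ny, int((y[i] + r[i] - ymin) / cell) + 2)
        r2 = r[i] * r[i]
        for gy in range(lo_y, hi_y):
            py = ymin + (gy + 0.5) * cell
            dy = py - y[i]
            dy2 = dy * dy
            if dy2 > r2:
                continue
            for gx in range(lo_x, hi_x):
                if grid[gy, gx]:
                    continue
                px = xmin + (gx + 0.5) * cell
                dx = px - x[i]
                if dx * dx + dy2 <= r2:
                    grid[gy, gx] = 1
    return float(grid.sum()) * cell * cell


@njit(cache=True)
def pa_areas_mc(coords, radii, rotmats, n_points, seeds):
    """Per-orientation MC union areas; one xorshift stream per orientation."""
    m = rotmats.shape[0]
    n = coords.shape[0]
    areas = np.empty(m)
    x = np.empty(n)
    y = np.empty(n)
    for k in range(m):
        R = rotmats[k]
        for i in range(n):
            x[i] = R[0, 0] * coords[i, 0] + R[0, 1] * coords[i, 1] + R[0, 2] * coords[i, 2]
            y[i] = R[1, 0] * coords[i, 0] + R[1, 1] * coords[i, 1] + R[1, 2] * coords[i, 2]
        areas[k] = _union_area_mc(x, y, radii, n_points, seeds[k])
    return areas


@njit(cache=True)
def pa_areas_grid(coords, radii, rotmats, cell):
    """Per-orientation rasterised union areas (oracle path)."""
    m = rotmats.shape[0]
    n = coords.shape[0]
    areas = np.empty(m)
    x = np.empty(n)
    y = np.empty(n)
    for k in range(m):
        R = rotmats[k]
        for i in range(n):
            x[i] = R[0, 0] * coords[i, 0] + R[0, 1] * coords[i, 1] + R[0, 2] * coords[i, 2]
            y[i] = R[1, 0] * coords[i, 0] + R[1, 1] * coords[i, 1] + R[1, 2] * coords[i, 2]
        areas[k] = _union_area_grid(x, y, radii, cell)
    return areas
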