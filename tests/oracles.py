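"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, breadth-first search,
all-pairs distances) and shares no code with the package internals.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[set[tuple[int, int, int]]]:
    """Connected components of a 3D boolean array by BFS flood fill."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    elif connectivity == 18:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if 0 < abs(dz) + abs(dy) + abs(dx) <= 2
        ]
    elif connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        raise ValueError(connectivity)
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
        comps.append(comp)
    return comps


def border_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Mask pixels 4-adjacent to in-frame background (frame edge counts as inside)."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx]:
                    out.append((y, x))
                    break
    return out


def min_distance_to_border_um(
    y_px: float, x_px: float, border: list[tuple[int, int]], pixel_size_um: float
) -> float:
    if not border:
        return float("inf")
    return min(np.hypot(y_px - by, x_px - bx) for by, bx in border) * pixel_size_um


def window_min_distance_um(
    y0: int, x0: int, size_px: int, border: list[tuple[int, int]], pixel_size_um: float
) -> float:
    """Minimum over all window pixels of the distance to the nearest border pixel."""
    best = float("inf")
    for y in range(y0, y0 + size_px):
        for x in range(x0, x0 + size_px):
            d = min_distance_to_border_um(y, x, border, pixel_size_um)
            if d < best:
                best = d
    return best


def polyline_curvature(points: np.ndarray) -> float:
    """Two-pass re-summation: total segment length over endpoint distance."""
    total = 0.0
    for i in range(len(points) - 1):
        total += float(np.hypot(points[i + 1][0] - points[i][0], points[i + 1][1] - points[i][1]))
    chord = float(np.hypot(points[-1][0] - points[0][0], points[-1][1] - points[0][1]))
    return total / chord


def count_points_in_box(points: np.ndarray, origin, size) -> int:
    n = 0
    for p in points:
        if all(origin[i] <= p[i] < origin[i] + size[i] for i in range(3)):
            n += 1
    return n
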