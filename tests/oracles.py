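"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (queues, loops, explicit offset
enumeration) and shares no code with the package under test.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def offsets_for(connectivity: int) -> list[tuple[int, int, int]]:
    out = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        order = sum(abs(o) for o in off)
        if connectivity == 6 and order == 1:
            out.append(off)
        elif connectivity == 18 and order <= 2:
            out.append(off)
        elif connectivity == 26:
            out.append(off)
    return out


def flood_fill(candidate: np.ndarray, seed: tuple[int, int, int], connectivity: int) -> np.ndarray:
    """BFS connected component of ``seed`` within a boolean candidate mask."""
    offs = offsets_for(connectivity)
    out = np.zeros_like(candidate, dtype=bool)
    if not candidate[seed]:
        return out
    q = deque([seed])
    out[seed] = True
    shape = candidate.shape
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offs:
            p = (z + dz, y + dy, x + dx)
            if (
                0 <= p[0] < shape[0]
                and 0 <= p[1] < shape[1]
                and 0 <= p[2] < shape[2]
                and candidate[p]
                and not out[p]
            ):
                out[p] = True
                q.append(p)
    return out


def region_grow_bf(
    vol: np.ndarray, seed: tuple[int, int, int], tolerance: float, connectivity: int
) -> np.ndarray:
    z, y, x = seed
    nb = vol[max(z - 1, 0) : z + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
    candidate = np.abs(vol.astype(float) - float(nb.mean())) <= tolerance
    candidate[seed] = True
    return flood_fill(candidate, seed, connectivity)


def label_components_bf(mask: np.ndarray, connectivity: int) -> list[np.ndarray]:
    remaining = mask.copy()
    comps = []
    while remaining.any():
        seed = tuple(np.argwhere(remaining)[0])
        comp = flood_fill(remaining, seed, connectivity)
        comps.append(comp)
        remaining &= ~comp
    return comps


def remove_islands_bf(mask: np.ndarray, min_island: int, connectivity: int) -> np.ndarray:
    out = np.zeros_like(mask)
    for comp in label_components_bf(mask, connectivity):
        if comp.sum() >= min_island:
            out |= comp
    return out


def ball_offsets(radius: float) -> list[tuple[int, int, int]]:
    r = int(np.ceil(radius))
    return [
        off
        for off in product(range(-r, r + 1), repeat=3)
        if off[0] ** 2 + off[1] ** 2 + off[2] ** 2 <= radius**2 + 1e-9
    ]


def dilate_bf(mask: np.ndarray, radius: float) -> np.ndarray:
    out = np.zeros_like(mask)
    offs = ball_offsets(radius)
    shape = mask.shape
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in offs:
            p = (z + dz, y + dy, x + dx)
            if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and 0 <= p[2] < shape[2]:
                out[p] = True
    return out


def erode_bf(mask: np.ndarray, radius: float) -> np.ndarray:
    """Minkowski erosion; out-of-volume voxels count as foreground."""
    out = np.zeros_like(mask)
    offs = ball_offsets(radius)
    shape = mask.shape
    for z, y, x in np.argwhere(mask):
        ok = True
        for dz, dy, dx in offs:
            p = (z + dz, y + dy, x + dx)
            if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and 0 <= p[2] < shape[2]:
                if not mask[p]:
                    ok = False
                    break
        if ok:
            out[z, y, x] = True
    return out


def close_bf(mask: np.ndarray, radius: float) -> np.ndarray:
    return erode_bf(dilate_bf(mask, radius), radius)


def fill_holes_bf(mask: np.ndarray, bg_connectivity: int) -> np.ndarray:
    """Foreground plus all background regions not reachable from the border."""
    bg = ~mask
    reach = np.zeros_like(bg)
    q = deque()
    shape = mask.shape
    for idx in np.argwhere(bg):
        z, y, x = idx
        if (
            z in (0, shape[0] - 1)
            or y in (0, shape[1] - 1)
            or x in (0, shape[2] - 1)
        ):
            t = (int(z), int(y), int(x))
            if not reach[t]:
                reach[t] = True
                q.append(t)
    offs = offsets_for(bg_connectivity)
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offs:
            p = (z + dz, y + dy, x + dx)
            if (
                0 <= p[0] < shape[0]
                and 0 <= p[1] < shape[1]
                and 0 <= p[2] < shape[2]
                and bg[p]
                and not reach[p]
            ):
                reach[p] = True
                q.append(p)
    return mask | (bg & ~reach)


def median_filter_bf(vol: np.ndarray, radius: int) -> np.ndarray:
    """Sort-and-pick-middle median with reflective padding."""
    pad = np.pad(vol, radius, mode="symmetric")
    out = np.empty_like(vol)
    w = 2 * radius + 1
    for z, y, x in product(*(range(n) for n in vol.shape)):
        out[z, y, x] = np.median(pad[z : z + w, y : y + w, x : x + w])
    return out


def pooled_t_bf(a, b) -> tuple[float, float]:
    """Closed-form pooled-variance t statistic and its df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(n1 + n2 - 2)
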