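"""Independent brute-force oracles used to cross-check the imaging operators.

Everything here is deliberately naive — union-find labelling, breadth-first
border reachability, exhaustive assignment search, direct kernel evaluation —
and shares no code with the implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

_NEIGH = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def union_find_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label foreground components with a plain union-find over pixel pairs."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for r in range(h):
        for c in range(w):
            if m[r, c]:
                parent[(r, c)] = (r, c)
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in _NEIGH[connectivity]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and m[rr, cc]:
                    union((r, c), (rr, cc))
    labels = np.zeros((h, w), dtype=np.int32)
    roots: dict[tuple[int, int], int] = {}
    nxt = 1
    for r in range(h):
        for c in range(w):
            if m[r, c]:
                root = find((r, c))
                if root not in roots:
                    roots[root] = nxt
                    nxt += 1
                labels[r, c] = roots[root]
    return labels


def component_areas(labels: np.ndarray) -> list[int]:
    """Sorted multiset of component areas from a label map."""
    lab = np.asarray(labels)
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    return sorted(int(c) for c in counts)


def border_reachable_fill(mask: np.ndarray, hole_connectivity: int) -> np.ndarray:
    """Hole filling via explicit BFS over background from the border."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    reach = np.zeros((h, w), dtype=bool)
    q: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not m[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not m[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in _NEIGH[hole_connectivity]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not m[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                q.append((rr, cc))
    return m | ~reach


def gaussian_kernel_2d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized discrete Gaussian kernel by direct evaluation."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    return np.outer(k1, k1)


def canny_step_oracle(image: np.ndarray, low: float, high: float) -> np.ndarray:
    """Hand-rolled Canny for axis-aligned fixtures.

    3x3 Sobel gradients, non-maximum suppression against the two
    neighbours along the quantized gradient direction (ties kept), then
    double-threshold hysteresis grown under 8-connectivity.  The 1-px
    image border is excluded, matching the implementation's mask handling.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            win = img[r - 1:r + 2, c - 1:c + 2]
            gx[r, c] = np.sum(win * np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]))
            gy[r, c] = np.sum(win * np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]]))
    mag = np.hypot(gx, gy)

    nms = np.zeros((h, w), dtype=bool)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if mag[r, c] == 0:
                continue
            ang = np.rad2deg(np.arctan2(gy[r, c], gx[r, c])) % 180.0
            if ang < 22.5 or ang >= 157.5:
                n1, n2 = mag[r, c - 1], mag[r, c + 1]
            elif ang < 67.5:
                n1, n2 = mag[r - 1, c - 1], mag[r + 1, c + 1]
            elif ang < 112.5:
                n1, n2 = mag[r - 1, c], mag[r + 1, c]
            else:
                n1, n2 = mag[r - 1, c + 1], mag[r + 1, c - 1]
            nms[r, c] = mag[r, c] >= n1 and mag[r, c] >= n2

    strong = nms & (mag >= high)
    weak = nms & (mag >= low)
    out = strong.copy()
    q = deque(zip(*np.where(strong)))
    while q:
        r, c = q.popleft()
        for dr, dc in _NEIGH[8]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and weak[rr, cc] and not out[rr, cc]:
                out[rr, cc] = True
                q.append((rr, cc))
    return out


def best_matching_bruteforce(
    truth: np.ndarray, predicted: np.ndarray, iou_min: float
) -> tuple[int, float]:
    """Exhaustive one-to-one matching maximizing total matched IoU.

    Returns (number of matched pairs, summed IoU of the best assignment),
    considering only pairs with IoU >= iou_min.  Exponential — use only on
    toy instances.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    t_ids = [int(i) for i in np.unique(t[t > 0])]
    p_ids = [int(i) for i in np.unique(p[p > 0])]
    iou = {}
    for ti in t_ids:
        tm = t == ti
        for pi in p_ids:
            pm = p == pi
            inter = int((tm & pm).sum())
            if inter:
                val = inter / int((tm | pm).sum())
                if val >= iou_min:
                    iou[(ti, pi)] = val
    best_n, best_sum = 0, 0.0
    k = min(len(t_ids), len(p_ids))
    for size in range(k, -1, -1):
        found_at_size = False
        for t_sub in itertools.combinations(t_ids, size):
            for p_perm in itertools.permutations(p_ids, size):
                pairs = list(zip(t_sub, p_perm))
                if all(pr in iou for pr in pairs):
                    s = sum(iou[pr] for pr in pairs)
                    found_at_size = True
                    if (size, s) > (best_n, best_sum):
                        best_n, best_sum = size, s
        if found_at_size:
            break
    return best_n, best_sum


def circle_area_pixel_scan(h: int, w: int, cr: float, cc: float, radius: float) -> int:
    """Exhaustive pixel-centre scan of (r-cr)^2 + (c-cc)^2 <= radius^2."""
    n = 0
    for r in range(h):
        for c in range(w):
            if (r - cr) ** 2 + (c - cc) ** 2 <= radius**2:
                n += 1
    return n


def accumulate_measurements(labels: np.ndarray, image: np.ndarray) -> dict:
    """Per-label area / centroid / mean intensity by explicit accumulation."""
    lab = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    out: dict[int, dict] = {}
    for r in range(lab.shape[0]):
        for c in range(lab.shape[1]):
            k = int(lab[r, c])
            if k == 0:
                continue
            d = out.setdefault(k, {"n": 0, "sr": 0.0, "sc": 0.0, "si": 0.0})
            d["n"] += 1
            d["sr"] += r
            d["sc"] += c
            d["si"] += img[r, c]
    return {
        k: {
            "area": d["n"],
            "centroid": (d["sr"] / d["n"], d["sc"] / d["n"]),
            "mean_intensity": d["si"] / d["n"],
        }
        for k, d in out.items()
    }
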