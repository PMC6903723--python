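"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-pixel loops, explicit offset
structuring elements with out-of-bounds treated as background, BFS component
labelling, exhaustive permutation/labelling enumeration, O(n^2) pairwise
concordance. These never call the package's own routines.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# morphology on small masks
# ---------------------------------------------------------------------------

def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def erode(mask: np.ndarray, radius: int) -> np.ndarray:
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                    ok = False
                    break
            out[y, x] = ok
    return out


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    out[yy, xx] = True
    return out


def opening(mask: np.ndarray, radius: int) -> np.ndarray:
    return dilate(erode(mask, radius), radius)


def closing(mask: np.ndarray, radius: int) -> np.ndarray:
    # padded so the image border cannot erode the dilated pattern
    pad = radius + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    out = erode(dilate(padded, radius), radius)
    return out[pad:-pad, pad:-pad]


def label8(mask: np.ndarray) -> tuple[np.ndarray, int]:
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and labels[y, x] == 0:
                current += 1
                q = deque([(y, x)])
                labels[y, x] = current
                while q:
                    cy, cx = q.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = cy + dy, cx + dx
                            if (
                                0 <= yy < h
                                and 0 <= xx < w
                                and mask[yy, xx]
                                and labels[yy, xx] == 0
                            ):
                                labels[yy, xx] = current
                                q.append((yy, xx))
    return labels, current


def remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = label8(mask)
    out = np.zeros_like(mask, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() >= min_px:
            out |= comp
    return out


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Holes = background components not connected (4-conn) to the border."""
    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    q = deque()
    for y in range(h):
        for x in (0, w - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    while q:
        cy, cx = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = cy + dy, cx + dx
            if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx] and not outside[yy, xx]:
                outside[yy, xx] = True
                q.append((yy, xx))
    return mask | ~outside


# ---------------------------------------------------------------------------
# the stage chain as plain set arithmetic
# ---------------------------------------------------------------------------

def stage_chain(slice_hu: np.ndarray, limb_body: np.ndarray, params) -> dict[str, np.ndarray]:
    """Recompute every stage mask for one limb with the naive primitives."""
    band = np.zeros_like(limb_body, dtype=bool)
    h, w = limb_body.shape
    for y in range(h):
        for x in range(w):
            band[y, x] = limb_body[y, x] and slice_hu[y, x] > params.hu_band_high
    denoised = remove_small(
        opening(band, params.opening_radius_px) if params.opening_radius_px > 0 else band,
        params.min_object_px,
    )
    skin_line = limb_body & ~erode(limb_body, params.skin_peel_px)
    peeled = denoised & ~skin_line
    closed = closing(peeled, params.closing_radius_px) if peeled.any() else peeled.copy()
    # core = component containing the limb centroid (nearest component otherwise)
    labels, n = label8(closed)
    if n <= 1:
        core = closed.copy()
    else:
        ys, xs = np.nonzero(limb_body)
        ri = int(round(ys.mean()))
        ci = int(round(xs.mean()))
        lab = labels[min(max(ri, 0), h - 1), min(max(ci, 0), w - 1)]
        if lab == 0:
            best, best_key = None, None
            for cand in range(1, n + 1):
                cy, cx = np.nonzero(labels == cand)
                d2 = (cy.mean() - ys.mean()) ** 2 + (cx.mean() - xs.mean()) ** 2
                key = (d2, -len(cy))
                if best_key is None or key < best_key:
                    best, best_key = cand, key
            lab = best
        core = labels == lab
    merged = core | skin_line
    inverted = ~merged
    donut = inverted & limb_body
    return {
        "band": band,
        "denoised": denoised,
        "peeled": peeled,
        "closed": core,
        "merged": merged,
        "inverted": inverted,
        "donut": donut,
        "reticulation": band & donut,
    }


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def average_ranks(v: np.ndarray) -> np.ndarray:
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt(float((xm**2).sum() * (ym**2).sum()))
    return float((xm * ym).sum() / denom) if denom else float("nan")


def spearman_perm_p(x, y) -> tuple[float, float]:
    """(rho, exact two-sided p) by full permutation of y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx, ry = average_ranks(x), average_ranks(y)
    rho_obs = pearson(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = pearson(rx, np.array(perm))
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / total


def mann_whitney_enum_p(a, b) -> tuple[float, float]:
    """(min-U, exact two-sided p by the doubling rule) via full enumeration."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = average_ranks(pooled)
    n, m = len(a), len(b)

    def u1(positions):
        return float(sum(ranks[i] for i in positions) - n * (n + 1) / 2)

    u_obs = u1(range(n))
    us = np.array([u1(c) for c in itertools.combinations(range(n + m), n)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(u_obs, n * m - u_obs), min(1.0, float(p))


def auc_pairwise(scores, labels) -> float:
    """O(n^2) concordance AUC, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
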