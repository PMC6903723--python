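"""Left/right limb separation on axial slices.

Both limbs are scanned simultaneously, so each slice must be split into an
image-left and an image-right region before per-limb counting. Disjoint limbs
are separated by connected components; limbs that touch (proximal thigh) are
split along the least-occupied image column between the two body-mass peaks.
The affected side is a per-patient clinical annotation, never inferred from
the images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

_CONN8 = np.ones((3, 3), dtype=bool)

SIDES = ("left", "right")


@dataclass
class LimbPair:
    """Per-slice limb regions with the affected-side label.

    Left/right are in image coordinates: the region whose centroid has the
    smaller column coordinate is ``left_region``.
    """

    left_region: np.ndarray
    right_region: np.ndarray
    affected_side: str
    slice_index: int

    def __post_init__(self) -> None:
        if self.affected_side not in SIDES:
            raise ValueError(f"affected_side must be one of {SIDES}, got {self.affected_side!r}")
        if np.logical_and(self.left_region, self.right_region).any():
            raise ValueError("left and right limb regions overlap")

    @property
    def affected_region(self) -> np.ndarray:
        return self.left_region if self.affected_side == "left" else self.right_region

    @property
    def unaffected_region(self) -> np.ndarray:
        return self.right_region if self.affected_side == "left" else self.left_region


def _centroid_col(mask: np.ndarray) -> float:
    cols = np.nonzero(mask)[1]
    return float(cols.mean())


def split_limbs(body: np.ndarray, slice_index: int, affected_side: str) -> LimbPair:
    """Split a body silhouette into left and right limb regions.

    With two or more connected components the two largest become the limbs
    (smaller specks are discarded with a log entry). A single merged
    component is split at the column minimising the body-pixel count between
    the two column-histogram mass peaks; pixels on the cut column go to the
    side with the nearer centroid (ties to the left).
    """
    body = np.asarray(body, dtype=bool)
    labels, n = ndi.label(body, structure=_CONN8)
    if n == 0:
        raise ValueError("body mask has no connected components")
    if n == 1:
        left, right = _split_single_blob(body)
    else:
        sizes = np.bincount(labels.ravel())[1:]
        order = np.argsort(sizes, kind="stable")[::-1]
        keep = order[:2] + 1
        if n > 2:
            logger.warning(
                "slice %d: discarding %d small extra component(s) when splitting limbs",
                slice_index,
                n - 2,
            )
        a = labels == keep[0]
        b = labels == keep[1]
        if _centroid_col(a) <= _centroid_col(b):
            left, right = a, b
        else:
            left, right = b, a
    return LimbPair(
        left_region=left, right_region=right, affected_side=affected_side, slice_index=slice_index
    )


def _split_single_blob(body: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split one merged body blob along the thinnest column between mass peaks."""
    hist = body.sum(axis=0)
    w = body.shape[1]
    mid = w // 2
    # The two body-mass peaks, one per image half.
    p1 = int(np.argmax(hist[:mid]))
    p2 = mid + int(np.argmax(hist[mid:]))
    if p2 <= p1 + 1:
        raise ValueError("cannot locate two body-mass peaks to split touching limbs")
    inner = hist[p1 + 1 : p2]
    min_val = inner.min()
    candidates = np.nonzero(inner == min_val)[0] + p1 + 1
    # Deterministic tie-break: the minimising column closest to the midpoint
    # between the peaks, lower index first.
    centre = (p1 + p2) / 2.0
    cut = int(min(candidates, key=lambda c: (abs(c - centre), c)))

    left = body.copy()
    left[:, cut:] = False
    right = body.copy()
    right[:, : cut + 1] = False
    cut_pixels = body[:, cut]
    if cut_pixels.any():
        # Assign the cut column to the side with the nearer centroid; tie -> left.
        cl = _centroid_col(left) if left.any() else -np.inf
        cr = _centroid_col(right) if right.any() else np.inf
        if (cut - cl) <= (cr - cut):
            left[:, cut] = cut_pixels
        else:
            right[:, cut] = cut_pixels
    return left, right
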