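"""Per-slice digital-subtraction chain for epifascial reticulation.

The chain reproduces, per limb and per axial slice, the eight image states of
the reticulation-counting algorithm:

1. original HU slice;
2. HU-band elimination — soft tissue in the band ``[hu_band_low,
   hu_band_high]`` (default [-50, 26] HU, inclusive) is blacked out; the
   remaining *nonblack* pattern is the above-band tissue (skin, muscle, bone
   and fibrotic trabeculae). Tissue darker than the band (subcutaneous fat,
   air) is radiographically black and is never part of the pattern;
3. noise removal — morphological opening plus removal of small connected
   components (a seedable surrogate for interactive cleanup);
4. skin peel — the outer shell of the body silhouette is removed and retained;
5. closing — the peeled pattern is consolidated and the connected component
   containing the limb centroid is taken as the subfascial (muscle + bone)
   core;
6. the peeled skin line is re-added around the core;
7. black-white reversion of the merged pattern;
8. restriction to the body yields the donut-shaped epifascial region between
   skin and core; the nonblack pixels of the *original* slice inside the donut
   are counted as reticulation.

All morphology is 2-D with digital-disk structuring elements
(``dx**2 + dy**2 <= r**2``); nothing operates across slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

logger = logging.getLogger(__name__)

#: 8-connectivity used for all connected-component labelling.
_CONN8 = np.ones((3, 3), dtype=bool)

#: Names of the seven stored stage masks (image states 2-8).
STAGE_NAMES = (
    "band",        # 2: band-eliminated nonblack pattern
    "denoised",    # 3: after opening + small-object removal
    "peeled",      # 4: after skin removal
    "closed",      # 5: closed subfascial core (single component per limb)
    "merged",      # 6: core with skin line re-added
    "inverted",    # 7: black-white reversion of the merged pattern
    "donut",       # 8: epifascial donut (inverted, restricted to the body)
)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the per-slice chain.

    ``hu_band_low``/``hu_band_high`` delimit the eliminated soft-tissue band in
    HU (inclusive on both ends); tissue above the band forms the working
    pattern, tissue below it is already black. ``body_mask_hu`` separates body
    from background air. Pixel radii/counts control the morphology; see module
    docstring for where each applies. ``closing_escalations`` allows doubling
    the closing radius (up to that many times) when the closed pattern stays
    fragmented; it defaults to 0 because aggressive merging can annex
    free-floating reticulations into the core.
    """

    hu_band_low: float = -50.0
    hu_band_high: float = 26.0
    body_mask_hu: float = -300.0
    opening_radius_px: int = 1
    min_object_px: int = 9
    skin_peel_px: int = 2
    closing_radius_px: int = 5
    closing_escalations: int = 0

    def __post_init__(self) -> None:
        if not self.hu_band_low < self.hu_band_high:
            raise ValueError(
                f"hu_band_low ({self.hu_band_low}) must be < hu_band_high ({self.hu_band_high})"
            )
        if not self.body_mask_hu < self.hu_band_low:
            raise ValueError(
                f"body_mask_hu ({self.body_mask_hu}) must be < hu_band_low ({self.hu_band_low})"
            )
        for name in ("opening_radius_px", "min_object_px", "closing_escalations"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        for name in ("skin_peel_px", "closing_radius_px"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SliceSegmentation:
    """Stage masks and the reticulation count for one limb on one slice."""

    stage_masks: dict[str, np.ndarray]
    skin_line: np.ndarray
    reticulation_mask: np.ndarray
    reticulation_count: int
    residual_components: int = 0
    meta: dict = field(default_factory=dict)


def _disk(radius: int) -> np.ndarray:
    return disk(int(radius)).astype(bool)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def remove_small_objects(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_px`` pixels."""
    mask = _as_bool(mask)
    if min_px <= 1 or not mask.any():
        return mask.copy()
    labels, n = ndi.label(mask, structure=_CONN8)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def body_mask(slice_hu: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary body silhouette: air excluded, interior holes filled.

    Pixels at or above ``body_mask_hu`` are body candidates; holes (e.g. fat
    darker than the threshold would be, bowel gas) are filled and components
    smaller than ``min_object_px`` are discarded as speckle.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    mask = slice_hu >= params.body_mask_hu
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, params.min_object_px)
    if not mask.any():
        raise ValueError("no body found in slice")
    return mask


def eliminate_hu_band(
    slice_hu: np.ndarray, body: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Black out the HU band and return the nonblack (above-band) pattern.

    The band ``[hu_band_low, hu_band_high]`` is eliminated with inclusive
    bounds; together with the sub-band tissue (fat, air), which is already
    black, this leaves the bright skin/muscle/bone/trabecula pattern.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    body = _as_bool(body)
    if not body.any():
        raise ValueError("body mask is empty")
    return body & (slice_hu > params.hu_band_high)


def jitter_params(params: SegmentationParams, seed: int) -> SegmentationParams:
    """Deterministically perturb the denoise parameters from a run seed.

    Surrogate for interactive noise cleanup: each processing repetition uses a
    slightly different opening radius (1 or 2 px) and small-object threshold
    (5..15 px), drawn from ``seed``.
    """
    rng = np.random.default_rng(int(seed))
    return replace(
        params,
        opening_radius_px=int(rng.integers(1, 3)),
        min_object_px=int(rng.integers(5, 16)),
    )


def denoise(
    mask: np.ndarray, params: SegmentationParams, seed: Optional[int] = None
) -> np.ndarray:
    """Opening with a digital disk, then small-object removal.

    When ``seed`` is given the denoise parameters are jittered via
    :func:`jitter_params` (the per-run variability surrogate).
    """
    if seed is not None:
        params = jitter_params(params, seed)
    mask = _as_bool(mask)
    if params.opening_radius_px > 0:
        mask = ndi.binary_opening(mask, structure=_disk(params.opening_radius_px))
    return remove_small_objects(mask, params.min_object_px)


def peel_skin(
    mask: np.ndarray, body: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the outermost skin from the pattern; keep the skin line.

    The skin line is the outer shell of the body silhouette,
    ``skin_peel_px`` thick (body minus body eroded by a disk of that radius).
    """
    body = _as_bool(body)
    if not body.any():
        raise ValueError("body mask is empty")
    eroded = ndi.binary_erosion(body, structure=_disk(params.skin_peel_px))
    skin_line = body & ~eroded
    peeled = _as_bool(mask) & ~skin_line
    return peeled, skin_line


def _closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with a digital disk, padded so the image border is inert."""
    pad = radius + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = ndi.binary_closing(padded, structure=_disk(radius))
    return closed[pad:-pad, pad:-pad]


def close_to_region(peeled: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Morphological closing aimed at one connected region per limb.

    Applies the closing at ``closing_radius_px``; if more than one component
    remains and ``closing_escalations`` allows, the radius is doubled (each
    doubling logged) and the closing rerun on the original pattern. A residual
    multi-component result is reported, not an error: downstream the component
    containing the limb centroid is taken as the subfascial core, so detached
    reticulation fragments remain in the epifascial space.
    """
    peeled = _as_bool(peeled)
    if not peeled.any():
        return peeled.copy()
    radius = params.closing_radius_px
    closed = _closing(peeled, radius)
    _, n = ndi.label(closed, structure=_CONN8)
    escalations = 0
    while n > 1 and escalations < params.closing_escalations:
        radius *= 2
        escalations += 1
        logger.info("closing left %d components; escalating radius to %d px", n, radius)
        closed = _closing(peeled, radius)
        _, n = ndi.label(closed, structure=_CONN8)
    if n > 1:
        logger.debug("closing left %d connected components", n)
    return closed


def select_core(closed: np.ndarray, region: np.ndarray) -> tuple[np.ndarray, int]:
    """Pick the subfascial core from the closed pattern.

    The core is the connected component containing the centroid of the limb
    region (the muscle+bone block sits at the centre of a limb cross-section);
    if the centroid pixel is empty, the component whose own centroid is
    nearest is used, largest first on ties. Returns the core mask and the
    number of residual (non-core) components.
    """
    closed = _as_bool(closed)
    labels, n = ndi.label(closed, structure=_CONN8)
    if n == 0:
        return closed.copy(), 0
    if n == 1:
        return closed.copy(), 0
    region = _as_bool(region)
    r, c = (np.mean(idx) for idx in np.nonzero(region if region.any() else closed))
    ri, ci = int(round(r)), int(round(c))
    ri = min(max(ri, 0), closed.shape[0] - 1)
    ci = min(max(ci, 0), closed.shape[1] - 1)
    label_at = labels[ri, ci]
    if label_at > 0:
        core_label = int(label_at)
    else:
        centroids = ndi.center_of_mass(closed, labels, index=range(1, n + 1))
        sizes = ndi.sum_labels(closed, labels, index=range(1, n + 1))
        d2 = [(cy - r) ** 2 + (cx - c) ** 2 for cy, cx in centroids]
        order = sorted(range(n), key=lambda i: (d2[i], -sizes[i]))
        core_label = order[0] + 1
    return labels == core_label, n - 1


def donut_roi(
    closed: np.ndarray, skin_line: np.ndarray, body: np.ndarray
) -> np.ndarray:
    """Donut-shaped epifascial region between the skin and the core.

    ``merged = closed | skin_line`` is black-white reverted and restricted to
    the body: ``donut = ~merged & body``. The donut is disjoint from both the
    skin line and the closed core by construction.
    """
    closed, skin_line, body = (_as_bool(m) for m in (closed, skin_line, body))
    if not (closed.shape == skin_line.shape == body.shape):
        raise ValueError("closed, skin_line and body must share shape")
    donut = ~(closed | skin_line) & body
    if not donut.any():
        logger.warning("donut region is empty; slice contributes count 0")
    return donut


def count_reticulation(
    slice_hu: np.ndarray, donut: np.ndarray, band_mask: np.ndarray
) -> tuple[int, np.ndarray]:
    """Count the nonblack pixels of the original slice inside the donut.

    ``band_mask`` is the stage-2 nonblack pattern of the original image; its
    intersection with the donut is the epifascial reticulation.
    """
    donut = _as_bool(donut)
    band_mask = _as_bool(band_mask)
    if donut.shape != band_mask.shape or donut.shape != np.shape(slice_hu):
        raise ValueError("slice, donut and band mask must share shape")
    mask = band_mask & donut
    return int(np.count_nonzero(mask)), mask


def segment_limb(
    slice_hu: np.ndarray,
    limb_body: np.ndarray,
    params: SegmentationParams,
    seed: Optional[int] = None,
) -> SliceSegmentation:
    """Run the full stage chain for one limb region of one slice."""
    band = eliminate_hu_band(slice_hu, limb_body, params)
    denoised = denoise(band, params, seed=seed)
    peeled, skin_line = peel_skin(denoised, limb_body, params)
    closed_raw = close_to_region(peeled, params)
    core, residual = select_core(closed_raw, limb_body)
    merged = core | skin_line
    inverted = ~merged
    donut = donut_roi(core, skin_line, limb_body)
    count, ret_mask = count_reticulation(slice_hu, donut, band)
    return SliceSegmentation(
        stage_masks={
            "band": band,
            "denoised": denoised,
            "peeled": peeled,
            "closed": core,
            "merged": merged,
            "inverted": inverted,
            "donut": donut,
        },
        skin_line=skin_line,
        reticulation_mask=ret_mask,
        reticulation_count=count,
        residual_components=residual,
    )
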