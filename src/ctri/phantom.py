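"""Synthetic paired-limb CT phantom with exact reticulation ground truth.

Each axial slice holds two concentric-disk limbs on an air background: a bone
core inside a muscle disk, a subcutaneous fat annulus, and a skin ring. The
honeycomb-like fibrotic reticulation is emulated by radial trabecular spokes
placed in the fat annulus (in up to two radial bands) at a requested per-side
area density, with seeded, non-overlapping slot placement so the per-slice,
per-side ground-truth pixel count is exact. Additive Gaussian HU noise is
applied *after* the truth masks are recorded, so the target is unambiguous.

Geometry is chosen so the pipeline's defaults can recover the truth: the skin
ring is drawn as the morphological outer shell of the limb disk (matching the
skin peel), and spokes keep a clearance from the muscle core larger than the
closing diameter so they are never annexed into the subfascial core.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as _disk_footprint

from .io import CTVolume, save_nifti

logger = logging.getLogger(__name__)

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic paired-limb volume.

    ``reticulation_density`` is the (left, right) fraction of each side's fat
    annulus area to cover with trabecular spokes; a scalar applies to both
    sides. Material HUs must respect the elimination band (fat below it, the
    solid tissues above it) so the ground truth is well defined.
    """

    n_slices: int = 20
    image_size: tuple[int, int] = (256, 256)
    limb_radius_px: int = 58
    skin_thickness_px: int = 2
    core_radius_px: int = 28
    bone_radius_px: int = 12
    fat_hu: float = -100.0
    skin_hu: float = 35.0
    muscle_hu: float = 45.0
    bone_hu: float = 700.0
    trabecula_hu: float = 60.0
    trabecula_width_px: int = 3
    reticulation_density: tuple[float, float] = (0.1, 0.1)
    core_clearance_px: int = 12
    skin_clearance_px: int = 4
    noise_sd: float = 5.0
    seed: int = 0
    mirror: bool = False
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if isinstance(self.reticulation_density, (int, float)):
            object.__setattr__(
                self,
                "reticulation_density",
                (float(self.reticulation_density), float(self.reticulation_density)),
            )
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.core_radius_px + self.skin_thickness_px >= self.limb_radius_px:
            raise ValueError(
                "core_radius_px + skin_thickness_px must be < limb_radius_px "
                "(a fat annulus must exist)"
            )
        if not self.fat_hu < -50:
            raise ValueError(f"fat_hu must be < -50 HU, got {self.fat_hu}")
        for name in ("trabecula_hu", "skin_hu", "muscle_hu"):
            if not getattr(self, name) > 26:
                raise ValueError(f"{name} must be > 26 HU, got {getattr(self, name)}")
        for i, d in enumerate(self.reticulation_density):
            if not 0.0 <= d <= 0.5:
                raise ValueError(
                    f"reticulation_density[{i}] must be in [0, 0.5], got {d}"
                )
        if self.trabecula_width_px < 1:
            raise ValueError("trabecula_width_px must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rows, cols = self.image_size
        c_left, c_right = cols // 4, cols - 1 - cols // 4
        if c_right - c_left <= 2 * self.limb_radius_px + 4:
            raise ValueError(
                "limb_radius_px too large for image_size: the two limbs would touch"
            )
        if rows // 2 + self.limb_radius_px >= rows or c_left - self.limb_radius_px < 0:
            raise ValueError("limb_radius_px too large for image_size")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        raw = json.loads(text)
        for key in ("image_size", "reticulation_density", "spacing"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PhantomTruth:
    """Pre-noise ground truth: per-slice per-side reticulation pixels."""

    counts_left: np.ndarray
    counts_right: np.ndarray
    masks: list[dict[str, np.ndarray]] = field(default_factory=list)

    def count(self, slice_index: int, side: str) -> int:
        arr = self.counts_left if side == "left" else self.counts_right
        return int(arr[slice_index])


def _limb_materials(spec: PhantomSpec, shape: tuple[int, int], centre: tuple[int, int]):
    """Masks for one limb: (limb, skin, muscle, bone, fat)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
    limb = d2 <= spec.limb_radius_px**2
    # Skin as the morphological outer shell of the limb disk, so a peel with
    # the same element removes it exactly.
    eroded = ndi.binary_erosion(limb, structure=_disk_footprint(spec.skin_thickness_px))
    skin = limb & ~eroded
    muscle = d2 <= spec.core_radius_px**2
    bone = d2 <= spec.bone_radius_px**2
    fat = limb & ~skin & ~muscle
    return limb, skin, muscle, bone, fat, d2


def _spoke_slots(spec: PhantomSpec) -> list[tuple[float, float, int]]:
    """Candidate spoke positions: (r_inner, r_outer, n_angular_slots) per band."""
    r_lo = spec.core_radius_px + spec.core_clearance_px
    r_hi = spec.limb_radius_px - spec.skin_thickness_px - spec.skin_clearance_px
    if r_hi - r_lo < 4:
        return []
    bands: list[tuple[float, float, int]] = []
    span = r_hi - r_lo
    if span >= 16:
        mid = r_lo + span * 0.55
        ranges = [(r_lo, mid - 1.5), (mid + 1.5, r_hi)]
    else:
        ranges = [(r_lo, r_hi)]
    for r0, r1 in ranges:
        pitch = (spec.trabecula_width_px + 2) / r0  # radians between slot centres
        n_slots = max(int(2 * math.pi / pitch), 1)
        bands.append((r0, r1, n_slots))
    return bands


def _place_spokes(
    spec: PhantomSpec,
    fat: np.ndarray,
    d2: np.ndarray,
    centre: tuple[int, int],
    target_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stamp non-overlapping radial spokes until ``target_px`` is reached."""
    shape = fat.shape
    truth = np.zeros(shape, dtype=bool)
    if target_px <= 0:
        return truth
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    rho = np.sqrt(d2.astype(float))
    phi = np.arctan2(rr - centre[0], cc - centre[1])
    half_w = spec.trabecula_width_px / 2.0

    slots: list[tuple[float, float, float]] = []  # (r0, r1, angle)
    for r0, r1, n in _spoke_slots(spec):
        offset = rng.uniform(0, 2 * math.pi)
        for k in range(n):
            slots.append((r0, r1, (offset + 2 * math.pi * k / n) % (2 * math.pi)))
    rng.shuffle(slots)

    count = 0
    for r0, r1, theta in slots:
        dphi = np.abs((phi - theta + math.pi) % (2 * math.pi) - math.pi)
        spoke = (rho >= r0) & (rho <= r1) & (rho * dphi <= half_w) & fat
        new = spoke & ~truth
        if not new.any():
            continue
        truth |= new
        count += int(np.count_nonzero(new))
        if count >= target_px:
            return truth
    raise ValueError(
        f"reticulation_density not achievable: placed {count} of {target_px} "
        "requested pixels; lower the density or enlarge the fat annulus"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate the paired-limb volume and its pre-noise ground truth.

    With ``spec.mirror`` the right limb (image and truth, including the noise
    field) is the exact horizontal mirror of the left limb, for tests that
    need pixel-identical limbs.
    """
    rows, cols = spec.image_size
    centre_row = rows // 2
    centres = {"left": (centre_row, cols // 4), "right": (centre_row, cols - 1 - cols // 4)}
    densities = {"left": spec.reticulation_density[0], "right": spec.reticulation_density[1]}

    voxels = np.full((spec.n_slices, rows, cols), AIR_HU, dtype=np.float64)
    counts = {"left": np.zeros(spec.n_slices, dtype=int), "right": np.zeros(spec.n_slices, dtype=int)}
    masks: list[dict[str, np.ndarray]] = []

    sides = ("left",) if spec.mirror else ("left", "right")
    for s in range(spec.n_slices):
        img = voxels[s]
        slice_masks: dict[str, np.ndarray] = {}
        for side_idx, side in enumerate(sides):
            limb, skin, muscle, bone, fat, d2 = _limb_materials(spec, (rows, cols), centres[side])
            img[fat] = spec.fat_hu
            img[muscle] = spec.muscle_hu
            img[bone] = spec.bone_hu
            img[skin] = spec.skin_hu
            rng = np.random.default_rng([spec.seed, s, side_idx])
            target = int(round(densities[side] * int(np.count_nonzero(fat))))
            truth = _place_spokes(spec, fat, d2, centres[side], target, rng)
            img[truth] = spec.trabecula_hu
            counts[side][s] = int(np.count_nonzero(truth))
            slice_masks[side] = truth
        if spec.mirror:
            flipped = img[:, ::-1]
            voxels[s] = np.maximum(img, flipped)
            slice_masks["right"] = slice_masks["left"][:, ::-1]
            counts["right"][s] = counts["left"][s]
        masks.append(slice_masks)

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, 0xC7])
        noise = noise_rng.normal(0.0, spec.noise_sd, size=voxels.shape)
        if spec.mirror:
            # Make the noise field flip-symmetric so the limbs stay exact mirrors.
            half = cols // 2
            noise[:, :, cols - half :] = noise[:, :, :half][:, :, ::-1]
        voxels += noise

    volume = CTVolume(
        voxels=voxels,
        spacing=spec.spacing,
        source_id=f"phantom(seed={spec.seed})",
    )
    truth = PhantomTruth(counts_left=counts["left"], counts_right=counts["right"], masks=masks)
    return volume, truth


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom volume (NIfTI), truth counts (CSV) and the spec (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, truth = generate_phantom(spec)
    paths = {
        "volume": out_dir / "phantom.nii.gz",
        "truth": out_dir / "truth_counts.csv",
        "spec": out_dir / "phantom_spec.json",
    }
    save_nifti(volume, paths["volume"])
    with open(paths["truth"], "w") as fh:
        fh.write("slice_index,left_count,right_count\n")
        for s in range(spec.n_slices):
            fh.write(f"{s},{truth.counts_left[s]},{truth.counts_right[s]}\n")
    paths["spec"].write_text(spec.to_json())
    return paths
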