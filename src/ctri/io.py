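"""Reading and writing CT volumes.

The pipeline consumes calibrated Hounsfield-unit (HU) volumes. Sources are
either a DICOM series directory (raw stored values are calibrated with the
per-file rescale slope/intercept) or a NIfTI file already expressed in HU.
A :class:`CTVolume` is the single in-memory representation used everywhere
downstream: a ``(slice, row, column)`` float array with millimetre spacing,
slices ordered proximal to distal.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pydicom

logger = logging.getLogger(__name__)

#: Conventional calibrated CT range; values outside are clipped and counted.
HU_MIN = -1024.0
HU_MAX = 3072.0


@dataclass
class CTVolume:
    """A calibrated CT volume.

    Attributes
    ----------
    voxels:
        3-D float array of HU values, indexed ``(slice, row, column)``.
    spacing:
        ``(slice_thickness_mm, row_mm, col_mm)``, all strictly positive.
    slice_order:
        Slice indices from proximal to distal (identity after loading; kept
        explicit so derived volumes can record reordering).
    source_id:
        Free-text provenance of the volume.
    n_clipped:
        Number of voxels clipped into ``[HU_MIN, HU_MAX]`` at construction.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_order: list[int] = field(default_factory=list)
    source_id: str = ""
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError(
                f"voxels must be a 3-D (slice, row, col) array with >=1 slice, "
                f"got shape {self.voxels.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be strictly positive, got {self.spacing}")
        if not self.slice_order:
            self.slice_order = list(range(self.voxels.shape[0]))
        out_of_range = int(np.count_nonzero((self.voxels < HU_MIN) | (self.voxels > HU_MAX)))
        if out_of_range:
            logger.info("clipping %d voxels outside [%g, %g] HU", out_of_range, HU_MIN, HU_MAX)
            np.clip(self.voxels, HU_MIN, HU_MAX, out=self.voxels)
        self.n_clipped += out_of_range

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def load_ct_volume(path: str | os.PathLike, format_hint: Optional[str] = None) -> CTVolume:
    """Load a CT volume from a DICOM series directory or a NIfTI file.

    ``format_hint`` may be ``"dicom_series"`` or ``"nifti"``; when omitted the
    format is inferred (directory -> DICOM series, ``.nii``/``.nii.gz`` ->
    NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CT volume path does not exist: {path}")
    if format_hint is None:
        if path.is_dir():
            format_hint = "dicom_series"
        elif path.name.endswith((".nii", ".nii.gz")):
            format_hint = "nifti"
        else:
            raise ValueError(
                f"cannot infer format of {path}; pass format_hint='dicom_series' or 'nifti'"
            )
    if format_hint == "dicom_series":
        return _load_dicom_series(path)
    if format_hint == "nifti":
        return _load_nifti(path)
    raise ValueError(f"unknown format_hint {format_hint!r}")


def _load_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file() and not p.name.startswith("."))
    if not files:
        raise FileNotFoundError(f"no files in DICOM series directory {directory}")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # unreadable file: report which one
            raise IOError(f"unreadable DICOM file {f}: {exc}") from exc
        datasets.append((f, ds))

    rows0, cols0 = int(datasets[0][1].Rows), int(datasets[0][1].Columns)
    for f, ds in datasets:
        if (int(ds.Rows), int(ds.Columns)) != (rows0, cols0):
            raise ValueError(
                f"mixed-dimension DICOM series: {f} is {int(ds.Rows)}x{int(ds.Columns)}, "
                f"expected {rows0}x{cols0}"
            )
    for f, ds in datasets:
        for attr in ("RescaleSlope", "RescaleIntercept"):
            if getattr(ds, attr, None) is None:
                raise ValueError(f"missing rescale metadata: {f} has no {attr}")

    datasets.sort(key=lambda item: _scan_axis_position(item[1]))

    slices = []
    for _, ds in datasets:
        raw = ds.pixel_array.astype(np.float64)
        slices.append(raw * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    voxels = np.stack(slices, axis=0)

    ds0 = datasets[0][1]
    row_mm, col_mm = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    if len(datasets) >= 2:
        zs = [_scan_axis_position(ds) for _, ds in datasets]
        dz = float(np.median(np.diff(zs)))
        thickness = abs(dz) if dz != 0 else float(getattr(ds0, "SliceThickness", 1.0))
    else:
        thickness = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(
        voxels=voxels,
        spacing=(thickness, row_mm, col_mm),
        source_id=str(directory),
    )


def _scan_axis_position(ds: pydicom.Dataset) -> float:
    """Position of a DICOM slice along the scan axis.

    Uses ImagePositionPatient projected on the slice normal (from
    ImageOrientationPatient) when available, else falls back to
    InstanceNumber. Sorting on this key makes slice order independent of
    on-disk file order.
    """
    ipp = getattr(ds, "ImagePositionPatient", None)
    iop = getattr(ds, "ImageOrientationPatient", None)
    if ipp is not None and iop is not None:
        row_dir = np.asarray(iop[:3], dtype=float)
        col_dir = np.asarray(iop[3:], dtype=float)
        normal = np.cross(row_dir, col_dir)
        return float(np.dot(np.asarray(ipp, dtype=float), normal))
    if ipp is not None:
        return float(ipp[2])
    return float(getattr(ds, "InstanceNumber", 0))


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D NIfTI, got shape {data.shape} in {path}")
    # On-disk axis order is (col, row, slice); in memory we use (slice, row, col).
    voxels = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing=spacing, source_id=str(path))


def save_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume to NIfTI (float64, lossless round-trip)."""
    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.float64)
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def save_mask_nifti(
    masks: Sequence[np.ndarray], spacing: tuple[float, float, float], path: str | os.PathLike
) -> None:
    """Write a stack of per-slice binary masks as a uint8 NIfTI label volume."""
    vol = np.stack([np.asarray(m, dtype=np.uint8) for m in masks], axis=0)
    data = np.transpose(vol, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))
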