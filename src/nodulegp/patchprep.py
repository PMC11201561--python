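"""Nodule ROI preparation from CT volumes.

Pipeline: resample the scan to isotropic 0.5 mm voxels with cubic B-spline
interpolation, extract a 32 mm square axial ROI centred on a marked nodule
(64x64 pixels), and map HU to [0, 1] with a fixed lung display window.

Array convention: volumes are numpy arrays indexed (z, y, x) with matching
``spacing_mm`` / ``origin_mm`` triples; nodule marks are stored in the same
(z, y, x) physical order (mark CSVs list x/y/z columns and are converted on
read). Physical coordinates map to indices by nearest-voxel rounding,
``index = round((coord - origin) / spacing)``, and the ROI spans the
half-open index range [c - 32, c + 32) so the marked centre lands on pixel
(32, 32) of the patch.

Slice selection is an input (a radiologist picks the slice that best shows
the nodule); there is no automatic slice chooser here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .simgrowth import ImagePatch

__all__ = [
    "CtVolume",
    "NoduleMark",
    "RoiOutOfBoundsError",
    "extract_roi",
    "load_volume",
    "normalize_intensity",
    "prepare_patches",
    "read_dicom_series",
    "read_marks_csv",
    "read_nifti",
    "resample_isotropic",
]

DEFAULT_HU_WINDOW = (-1000.0, 400.0)


class RoiOutOfBoundsError(ValueError):
    """ROI would extend past the volume; no silent padding is performed."""


@dataclass(frozen=True)
class CtVolume:
    """A CT volume in HU with (z, y, x) array layout."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.values.shape, self.spacing_mm))


@dataclass(frozen=True)
class NoduleMark:
    """A radiologist-marked nodule centre, physical (z, y, x) mm."""

    center_mm: tuple[float, float, float]
    slice_index: int | None = None  # axial slice after resampling
    subject_id: str = ""


# ------------------------------------------------------------- sitk bridging
def _to_sitk(volume: CtVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(volume.values)  # array (z,y,x) -> img (x,y,z)
    img.SetSpacing(tuple(reversed(volume.spacing_mm)))
    img.SetOrigin(tuple(reversed(volume.origin_mm)))
    return img


def _from_sitk(img: sitk.Image) -> CtVolume:
    return CtVolume(
        values=sitk.GetArrayFromImage(img),
        spacing_mm=tuple(reversed(img.GetSpacing())),
        origin_mm=tuple(reversed(img.GetOrigin())),
    )


# ----------------------------------------------------------------- resampling
def resample_isotropic(volume: CtVolume,
                       target_spacing_mm: float = 0.5) -> CtVolume:
    """Resample to isotropic voxels with cubic B-spline interpolation.

    The output grid covers the same physical extent (within one voxel);
    B-spline overshoot outside the input intensity range is clamped back to
    the input min/max.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    img = _to_sitk(volume)
    t = float(target_spacing_mm)
    new_size = [max(1, int(round(n * s / t)))
                for n, s in zip(img.GetSize(), img.GetSpacing())]
    resampler = sitk.ResampleImageFilter()
    resampler.SetInterpolator(sitk.sitkBSpline)
    resampler.SetOutputSpacing((t, t, t))
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetSize(new_size)
    resampler.SetDefaultPixelValue(float(volume.values.min()))
    out = _from_sitk(resampler.Execute(img))
    clamped = np.clip(out.values, volume.values.min(), volume.values.max())
    return CtVolume(clamped, out.spacing_mm, out.origin_mm)


# ------------------------------------------------------------- ROI extraction
def _nearest_index(coord: float, origin: float, spacing: float) -> int:
    return int(round((coord - origin) / spacing))


def extract_roi(volume: CtVolume, mark: NoduleMark,
                side_mm: float = 32.0) -> np.ndarray:
    """Extract the axial HU patch around a marked nodule centre.

    Returns the raw HU array (side_mm / spacing pixels square); pass it to
    :func:`normalize_intensity` to obtain a valid :class:`ImagePatch`.
    """
    sz, sy, sx = volume.spacing_mm
    if not math.isclose(sy, sx, rel_tol=1e-6):
        raise ValueError("extract_roi expects an isotropic in-plane grid")
    half_px = side_mm / sx / 2.0
    if not math.isclose(half_px, round(half_px), abs_tol=1e-9):
        raise ValueError(
            f"side_mm={side_mm} is not an even pixel count at {sx} mm spacing")
    half = int(round(half_px))

    oz, oy, ox = volume.origin_mm
    cz, cy, cx = mark.center_mm
    nz, ny, nx = volume.values.shape
    iz = mark.slice_index if mark.slice_index is not None \
        else _nearest_index(cz, oz, sz)
    iy = _nearest_index(cy, oy, sy)
    ix = _nearest_index(cx, ox, sx)
    if not (0 <= iz < nz):
        raise RoiOutOfBoundsError(f"slice index {iz} outside [0, {nz})")
    if iy - half < 0 or iy + half > ny or ix - half < 0 or ix + half > nx:
        raise RoiOutOfBoundsError(
            f"{2*half}x{2*half} ROI at (y={iy}, x={ix}) exceeds "
            f"slice shape ({ny}, {nx})")
    return volume.values[iz, iy - half:iy + half, ix - half:ix + half].copy()


def normalize_intensity(hu_patch: np.ndarray,
                        window: tuple[float, float] = DEFAULT_HU_WINDOW,
                        pixel_spacing_mm: float = 0.5) -> ImagePatch:
    """Affine map of the HU window to [0, 1], clipping outside it."""
    lower, upper = window
    if not lower < upper:
        raise ValueError(f"degenerate HU window {window}")
    arr = np.asarray(hu_patch, dtype=np.float64)
    values = np.clip((arr - lower) / (upper - lower), 0.0, 1.0)
    return ImagePatch(values=values, pixel_spacing_mm=pixel_spacing_mm,
                      side_mm=values.shape[0] * pixel_spacing_mm)


def prepare_patches(volume: CtVolume, marks: list[NoduleMark],
                    target_spacing_mm: float = 0.5, side_mm: float = 32.0,
                    window: tuple[float, float] = DEFAULT_HU_WINDOW
                    ) -> list[tuple[NoduleMark, ImagePatch]]:
    """Resample once, then extract + normalize a patch for every mark."""
    iso = resample_isotropic(volume, target_spacing_mm)
    out = []
    for mark in marks:
        hu = extract_roi(iso, mark, side_mm)
        out.append((mark, normalize_intensity(hu, window, target_spacing_mm)))
    return out


# --------------------------------------------------------------------- readers
def read_nifti(path: str | Path) -> CtVolume:
    """Read a .nii/.nii.gz volume; assumes an axis-aligned affine."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)  # (x, y, z)
    zooms = img.header.get_zooms()[:3]
    offset = img.affine[:3, 3]
    return CtVolume(
        values=np.transpose(data, (2, 1, 0)),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin_mm=(float(offset[2]), float(offset[1]), float(offset[0])),
    )


def read_dicom_series(directory: str | Path) -> CtVolume:
    """Read a DICOM series directory as one volume."""
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FileNotFoundError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    return _from_sitk(reader.Execute())


def load_volume(path: str | Path) -> CtVolume:
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return read_nifti(path)
    raise ValueError(f"unsupported volume input: {path}")


def read_marks_csv(path: str | Path) -> list[NoduleMark]:
    """Read nodule marks from CSV (subject_id, x_mm, y_mm, z_mm[, slice])."""
    df = pd.read_csv(path)
    marks = []
    for _, row in df.iterrows():
        slice_idx = int(row["slice"]) if "slice" in df.columns \
            and not pd.isna(row.get("slice")) else None
        marks.append(NoduleMark(
            center_mm=(float(row["z_mm"]), float(row["y_mm"]),
                       float(row["x_mm"])),
            slice_index=slice_idx,
            subject_id=str(row.get("subject_id", "")),
        ))
    return marks
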