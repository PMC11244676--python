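"""CT volume container, ROI/contour/result types, and NIfTI / DICOM-series I/O.

All voxel coordinates in this package are 0-based with axis order
``(slice, row, column)``; spacings are millimetres per voxel edge in the same
order.  Attenuation is always in Hounsfield units (HU): volumes read from
DICOM are mapped through the rescale slope/intercept exactly once and flagged
as calibrated so the mapping can never be applied twice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CTVolume",
    "ROISpec",
    "ROIMetrics",
    "ContourTrace",
    "FrequencySpectrum",
    "StreakResult",
    "BloomResult",
    "read_volume",
    "write_volume",
]


@dataclass
class CTVolume:
    """A 3-D attenuation grid in HU with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        Attenuation in HU.
    spacing : tuple of float
        Voxel edge lengths in mm, ordered (slice, row, column).
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    hu_calibrated : bool
        True once stored values are HU; DICOM rescale is applied on read and
        never again.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hu_calibrated: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be 3-D with each axis length >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROISpec:
    """A circular or rectangular region of interest on one slice.

    ``center`` is (row, col) in voxel units; ``size`` is the radius for a
    circle or (half_rows, half_cols) half-extents for a rectangle, both in
    voxel units.  A voxel belongs to the ROI when its centre falls inside the
    shape.
    """

    slice_index: int
    shape: Literal["circle", "rectangle"]
    center: tuple[float, float]
    size: float | tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rectangle"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")

    def mask(self, slice_shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : slice_shape[0], 0 : slice_shape[1]]
        r0, c0 = self.center
        if self.shape == "circle":
            m = (rows - r0) ** 2 + (cols - c0) ** 2 <= float(self.size) ** 2
        else:
            hr, hc = self.size  # type: ignore[misc]
            m = (np.abs(rows - r0) <= hr) & (np.abs(cols - c0) <= hc)
        return m

    def validate(self, volume: CTVolume) -> None:
        ns, nr, nc = volume.shape
        if not 0 <= self.slice_index < ns:
            raise ValueError(f"ROI slice {self.slice_index} outside volume with {ns} slices")
        r0, c0 = self.center
        if self.shape == "circle":
            er = ec = float(self.size)
        else:
            er, ec = self.size  # type: ignore[misc]
        if r0 - er < 0 or r0 + er > nr - 1 or c0 - ec < 0 or c0 + ec > nc - 1:
            raise ValueError(f"ROI {self.label or self.center} extends outside the slice")
        if int(self.mask((nr, nc)).sum()) < 2:
            raise ValueError("ROI must contain at least 2 voxels")


@dataclass(frozen=True)
class ROIMetrics:
    """Signed mean-HU difference (artifact minus reference) and artifact-ROI SD."""

    diff_hu: float
    sd_artifact: float

    def __post_init__(self) -> None:
        if self.sd_artifact < 0:
            raise ValueError("sd_artifact must be >= 0")


@dataclass
class ContourTrace:
    """Closed contour around the metal with HU sampled at each point.

    ``points`` is an (N, 2) array of (row, col) positions at sub-voxel
    precision, counter-clockwise (positive shoelace area in the (row, col)
    plane), first point not repeated at the end.
    """

    points: np.ndarray
    hu_samples: np.ndarray
    slice_index: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.hu_samples = np.asarray(self.hu_samples, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 8:
            raise ValueError("a contour needs at least 8 points")
        if len(self.hu_samples) != len(self.points):
            raise ValueError("hu_samples length must match points")
        if np.allclose(self.points[0], self.points[-1]):
            raise ValueError("first contour point must not be repeated at the end")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FrequencySpectrum:
    """Unnormalised DFT amplitudes |X_k| of HU along a contour.

    ``frequencies[k] = k / N`` in cycles per contour sample.
    """

    amplitudes: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.amplitudes) != len(self.frequencies):
            raise ValueError("amplitudes and frequencies must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class StreakResult:
    """Low-frequency streak amplitude |X_1|+|X_2| averaged over three slices.

    ``cv`` is the coefficient of variation of the three per-slice values, in
    percent, using the sample (n-1) standard deviation.
    """

    amplitude_low_freq: float
    cv: float
    per_slice: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.per_slice) != 3:
            raise ValueError("per_slice must hold exactly 3 values")
        if self.amplitude_low_freq < 0 or self.cv < 0:
            raise ValueError("amplitude_low_freq and cv must be >= 0")


@dataclass
class BloomResult:
    """Segmented metal volume from HU-band thresholding.

    The volume is the voxel count of the largest 26-connected component inside
    ``[lower_threshold, upper_threshold]`` times the voxel volume, in cm**3.
    """

    volume_cm3: float
    voxel_count: int
    lower_threshold: float
    upper_threshold: float

    def __post_init__(self) -> None:
        if self.lower_threshold >= self.upper_threshold:
            raise ValueError("lower_threshold must be < upper_threshold")
        if self.volume_cm3 < 0:
            raise ValueError("volume_cm3 must be >= 0")


# --------------------------------------------------------------------------
# I/O


def write_volume(volume: CTVolume, path: str | os.PathLike, format: str = "nifti") -> None:
    """Write a CTVolume to a NIfTI-1 file readable back by :func:`read_volume`."""
    if format != "nifti":
        raise ValueError(f"unsupported write format {format!r}")
    import nibabel as nib

    # NIfTI stores (x, y, z) = (col, row, slice); transpose accordingly.
    arr = np.asarray(volume.data, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    affine[:3, 3] = [volume.origin[2], volume.origin[1], volume.origin[0]]
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))


def read_volume(path: str | os.PathLike, format: str = "nifti") -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM pixel data are mapped through the rescale slope/intercept to HU.
    A series with mixed image orientations or missing pixel spacing raises a
    ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unsupported read format {format!r}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"NIfTI header of {path} has non-positive voxel spacing {zooms}")
    arr = np.asanyarray(img.dataobj).astype(float)
    data = arr.transpose(2, 1, 0)
    origin = tuple(float(x) for x in img.affine[:3, 3][::-1])
    return CTVolume(data=data, spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])), origin=origin)


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    if not files:
        raise ValueError(f"no files in DICOM series directory {path}")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # non-DICOM stray file
            continue
        datasets.append((f, ds))
    if not datasets:
        raise ValueError(f"no readable DICOM files in {path}")

    ref_frame = getattr(datasets[0][1], "FrameOfReferenceUID", None)
    ref_orient = [float(v) for v in datasets[0][1].ImageOrientationPatient]
    for f, ds in datasets:
        if getattr(ds, "FrameOfReferenceUID", None) != ref_frame:
            raise ValueError(f"DICOM series mixes frames of reference (offending file: {f.name})")
        orient = [float(v) for v in ds.ImageOrientationPatient]
        if not np.allclose(orient, ref_orient, atol=1e-4):
            raise ValueError(f"DICOM series mixes image orientations (offending file: {f.name})")
        if "PixelSpacing" not in ds:
            raise ValueError(f"DICOM file {f.name} has no PixelSpacing")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"DICOM file {f.name} has no rescale slope/intercept")

    row_dir = np.array(ref_orient[:3])
    col_dir = np.array(ref_orient[3:])
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda fd: float(np.dot(np.array([float(v) for v in fd[1].ImagePositionPatient]), normal)))

    slices = []
    positions = []
    for f, ds in datasets:
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(hu)
        positions.append(float(np.dot(np.array([float(v) for v in ds.ImagePositionPatient]), normal)))
    data = np.stack(slices, axis=0)

    ps = [float(v) for v in datasets[0][1].PixelSpacing]  # (row, col) mm
    if len(datasets) > 1:
        gaps = np.diff(positions)
        slice_spacing = float(np.mean(gaps))
        if slice_spacing <= 0 or not np.allclose(gaps, slice_spacing, rtol=1e-3, atol=1e-3):
            raise ValueError("DICOM series has non-uniform or non-positive slice spacing")
    else:
        slice_spacing = float(getattr(datasets[0][1], "SliceThickness", 0) or 0)
        if slice_spacing <= 0:
            raise ValueError("single-slice series without a usable SliceThickness")
    origin0 = [float(v) for v in datasets[0][1].ImagePositionPatient]
    return CTVolume(
        data=data,
        spacing=(slice_spacing, ps[0], ps[1]),
        origin=(positions[0], origin0[1], origin0[0]),
    )
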