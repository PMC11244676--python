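"""The three objective metal-artifact metrics.

* ROI analysis: signed mean-HU difference between an artifact ROI and a
  reference ROI (Diff_HU, artifact minus reference) and the sample standard
  deviation inside the artifact ROI (SD_ARTIFACT).
* Fourier streak metric: HU sampled along a closed contour a fixed offset
  outside the metal boundary, discrete Fourier transform, and the summed
  unnormalised amplitude of bins 1 and 2 (AmplitudeLowFreq), averaged over
  three sequential slices with its coefficient of variation.
* Blooming volume: the largest 26-connected component inside an HU threshold
  band, converted to cm**3 (BloomVol).

The contour is resampled by arc length to exactly N = 141 points, so bin 2
sits at 2/141 ~ 0.0142 cycles per sample regardless of implant size.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .volume import (
    BloomResult,
    ContourTrace,
    CTVolume,
    FrequencySpectrum,
    ROIMetrics,
    ROISpec,
    StreakResult,
)

__all__ = [
    "CONTOUR_SAMPLES",
    "PHANTOM_METAL_LOWER_HU",
    "PATIENT_METAL_LOWER_HU",
    "METAL_UPPER_HU",
    "compute_roi_metrics",
    "extract_metal_contour",
    "compute_spectrum",
    "compute_amplitude_low_freq",
    "compute_bloom_vol",
]

#: contour sample count; puts DFT bin 2 at 2/141 ~ 0.0142 cycles/sample
CONTOUR_SAMPLES = 141
#: default metal segmentation band (phantom-arm / patient-arm lower bound)
PHANTOM_METAL_LOWER_HU = 800.0
PATIENT_METAL_LOWER_HU = 2500.0
METAL_UPPER_HU = 32762.0


def compute_roi_metrics(
    volume: CTVolume, artifact_roi: ROISpec, reference_roi: ROISpec
) -> ROIMetrics:
    """Diff_HU = mean(artifact ROI) - mean(reference ROI); SD of artifact ROI.

    The difference is signed (artifact minus reference); the standard
    deviation uses the sample (n-1) convention.
    """
    artifact_roi.validate(volume)
    reference_roi.validate(volume)
    slice_shape = volume.shape[1:]
    art = volume.data[artifact_roi.slice_index][artifact_roi.mask(slice_shape)]
    ref = volume.data[reference_roi.slice_index][reference_roi.mask(slice_shape)]
    return ROIMetrics(
        diff_hu=float(art.mean() - ref.mean()),
        sd_artifact=float(art.std(ddof=1)),
    )


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline (first point not repeated) to n points by arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    targets = np.arange(n) * total / n
    out = np.column_stack([
        np.interp(targets, s, closed[:, 0]),
        np.interp(targets, s, closed[:, 1]),
    ])
    return out


def extract_metal_contour(
    volume: CTVolume,
    slice_index: int,
    metal_threshold: float = PHANTOM_METAL_LOWER_HU,
    offset_voxels: int = 3,
    n_points: int = CONTOUR_SAMPLES,
) -> ContourTrace:
    """Trace the outer boundary of the (dilated) largest metal region in a slice.

    The in-slice metal mask is the largest connected region above
    ``metal_threshold``, dilated by a disk of ``offset_voxels`` so the trace
    runs a fixed distance outside the metal edge.  The iso-level-0.5 boundary
    of that mask is resampled by arc length to exactly ``n_points`` points,
    oriented counter-clockwise (positive shoelace area in the (row, col)
    plane) and rotated to start at the point with minimal row, then minimal
    column.  HU is sampled at each point by bilinear interpolation.
    """
    ns = volume.shape[0]
    if not 0 <= slice_index < ns:
        raise ValueError(f"slice_index {slice_index} outside volume with {ns} slices")
    sl = volume.data[slice_index]
    metal = sl > metal_threshold
    if not metal.any():
        raise ValueError(f"no metal in slice {slice_index} above {metal_threshold} HU")
    labels = measure.label(metal, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if offset_voxels > 0:
        mask = ndimage.binary_dilation(mask, structure=morphology.disk(offset_voxels))

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError(f"no contour found in slice {slice_index}")
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        raise ValueError(f"metal contour touches the image border in slice {slice_index}")
    pts = contour[:-1]
    lo = np.array([0.5, 0.5])
    hi = np.array(sl.shape) - 1.5
    if np.any(pts < lo) or np.any(pts > hi):
        raise ValueError(f"metal contour touches the image border in slice {slice_index}")

    pts = _resample_closed(pts, n_points)
    # counter-clockwise: positive shoelace area with x = col, y = row
    x, y = pts[:, 1], pts[:, 0]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        pts = pts[::-1]
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    pts = np.roll(pts, -start, axis=0)

    hu = ndimage.map_coordinates(sl, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
    return ContourTrace(points=pts, hu_samples=hu, slice_index=slice_index)


def compute_spectrum(trace: ContourTrace) -> FrequencySpectrum:
    """Unnormalised DFT of the HU samples: X_k = sum_t h_t exp(-2*pi*i*k*t/N)."""
    h = np.asarray(trace.hu_samples, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("contour HU samples contain non-finite values")
    amplitudes = np.abs(np.fft.fft(h))
    n = len(h)
    return FrequencySpectrum(amplitudes=amplitudes, frequencies=np.arange(n) / n)


def compute_amplitude_low_freq(
    volume: CTVolume,
    center_slice: int,
    metal_threshold: float = PHANTOM_METAL_LOWER_HU,
    offset_voxels: int = 3,
    n_points: int = CONTOUR_SAMPLES,
) -> StreakResult:
    """AmplitudeLowFreq: mean over three sequential slices of |X_1| + |X_2|.

    The contour is re-delineated on each of the slices ``center_slice - 1``
    ... ``center_slice + 1``; the coefficient of variation of the three
    per-slice values is reported in percent (sample SD / mean x 100).
    """
    if not 1 <= center_slice < volume.shape[0] - 1:
        raise ValueError("center_slice must leave one valid slice on each side")
    per_slice = []
    for s in (center_slice - 1, center_slice, center_slice + 1):
        trace = extract_metal_contour(volume, s, metal_threshold, offset_voxels, n_points)
        spec = compute_spectrum(trace)
        per_slice.append(float(spec.amplitudes[1] + spec.amplitudes[2]))
    vals = np.array(per_slice)
    mean = float(vals.mean())
    cv = 0.0 if mean == 0 else float(100.0 * vals.std(ddof=1) / mean)
    return StreakResult(amplitude_low_freq=mean, cv=cv, per_slice=tuple(per_slice))


def compute_bloom_vol(
    volume: CTVolume,
    lower: float = PHANTOM_METAL_LOWER_HU,
    upper: float = METAL_UPPER_HU,
) -> BloomResult:
    """Segmented metal volume: largest 26-connected component in [lower, upper].

    Volume is the voxel count of the largest component times the voxel
    volume, in cm**3.  Ties in component size resolve to the lowest label of
    the deterministic raster-order labelling.
    """
    if lower >= upper:
        raise ValueError("lower threshold must be < upper threshold")
    band = (volume.data >= lower) & (volume.data <= upper)
    if not band.any():
        raise ValueError(f"no voxels in threshold band [{lower}, {upper}]")
    labels, n_labels = ndimage.label(band, structure=np.ones((3, 3, 3), dtype=int))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    voxel_count = int(counts.max())
    return BloomResult(
        volume_cm3=voxel_count * volume.voxel_volume_mm3 / 1000.0,
        voxel_count=voxel_count,
        lower_threshold=float(lower),
        upper_threshold=float(upper),
    )
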