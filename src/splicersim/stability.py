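"""Pixelwise temporal statistics on repeated magnitude acquisitions.

Temporal SNR — the per-pixel mean divided by the per-pixel standard
deviation over repeated acquisitions — folds physiological instability into
the noise estimate alongside thermal noise, and needs no background ROI.
Comparing the temporal-SNR maps of two protocols acquired in the same scan
time (an SNR enhancement map) quantifies how much instability one protocol
removes; because averaged SNR grows as the square root of scan time, an
enhancement ratio r is worth an r**2-fold scan-time saving.

Stacks are 4D arrays (x, y, slice, repeat) and round-trip through NIfTI-1
with the pixel geometry in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageStack",
    "RoiSpec",
    "pixel_stats",
    "enhancement_map",
    "roi_pixel_count",
    "roi_mask",
    "roi_mean",
    "snr_time_equivalence",
]


@dataclass
class ImageStack:
    """Repeated 2D multi-slice magnitude images, shape (x, y, slice, repeat)."""

    magnitudes: np.ndarray
    fov: float
    slice_thickness: float = 0.5

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 4:
            raise ValueError("magnitudes must be 4D (x, y, slice, repeat)")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.fov <= 0:
            raise ValueError("fov must be > 0")

    @property
    def matrix(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.magnitudes.shape[3]

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix

    def _affine(self) -> np.ndarray:
        return np.diag([self.pixel_spacing, self.pixel_spacing, self.slice_thickness, 1.0])

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.magnitudes.astype(np.float32), self._affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageStack":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError("expected a 4D NIfTI stack (x, y, slice, repeat)")
        zooms = img.header.get_zooms()
        return cls(
            magnitudes=data,
            fov=float(zooms[0]) * data.shape[0],
            slice_thickness=float(zooms[2]),
        )


def save_map(map3d: np.ndarray, stack: ImageStack, path: str | Path) -> None:
    """Write a 3D statistic map with the stack's geometry."""
    img = nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), stack._affine())
    nib.save(img, str(path))


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: pixel-coordinate centre plus an area (mm^2) or radius (mm)."""

    centre: tuple[float, float]
    area: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if (self.area is None) == (self.radius is None):
            raise ValueError("specify exactly one of area or radius")
        if self.area is not None and self.area <= 0:
            raise ValueError("area must be > 0")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be > 0")

    def radius_mm(self) -> float:
        if self.radius is not None:
            return self.radius
        return float(np.sqrt(self.area / np.pi))


def pixel_stats(
    stack: ImageStack,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel mean, sample SD (n-1 denominator) and SNR = mean/SD.

    Pixels with zero temporal SD get a non-finite SNR (NaN) so that
    downstream ROI statistics can mask them instead of reporting an
    artificial infinity.
    """
    if stack.n_repeats < 2:
        raise ValueError("at least 2 repeats are required for a temporal SD")
    mean = stack.magnitudes.mean(axis=3)
    sd = stack.magnitudes.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    return mean, sd, snr


def enhancement_map(snr_num: np.ndarray, snr_den: np.ndarray) -> np.ndarray:
    """Elementwise SNR ratio; non-finite wherever either input is."""
    a = np.asarray(snr_num, dtype=float)
    b = np.asarray(snr_den, dtype=float)
    if a.shape != b.shape:
        raise ValueError("SNR maps must have identical shapes")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = a / b
    out[~np.isfinite(a) | ~np.isfinite(b) | (b == 0)] = np.nan
    return out


def roi_pixel_count(roi: RoiSpec, fov: float, matrix: int) -> int:
    """Pixels in the ROI.

    Area-specified ROIs return ``round(area / pixel_area)`` (the convention
    used when quoting an ROI as "128 mm^2 = 2048 pixels"); radius-specified
    ROIs return the rasterised count with the pixel-centre inclusion rule.
    """
    pixel_area = (fov / matrix) ** 2
    if roi.radius_mm() * 2 > fov:
        raise ValueError("ROI diameter exceeds the field of view")
    if roi.area is not None:
        return int(round(roi.area / pixel_area))
    return int(roi_mask(roi, fov, matrix).sum())


def roi_mask(roi: RoiSpec, fov: float, matrix: int) -> np.ndarray:
    """Boolean mask of pixels whose centres fall within the ROI circle."""
    r_pix = roi.radius_mm() / (fov / matrix)
    cy, cx = roi.centre
    if not (0 <= cy < matrix and 0 <= cx < matrix):
        raise ValueError("ROI centre outside the image")
    yy, xx = np.mgrid[0:matrix, 0:matrix]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_pix**2


def roi_mean(
    map2d: np.ndarray,
    roi: RoiSpec,
    fov: float,
    nonfinite: str = "exclude",
) -> tuple[float, int]:
    """Mean of a statistic map over a circular ROI.

    ``nonfinite="exclude"`` averages finite pixels only; ``"unity"`` counts
    non-finite pixels as 1.0, the convention under which signal voids in an
    enhancement map register as no change.  Returns (mean, n_nonfinite).
    """
    m = np.asarray(map2d, dtype=float)
    if m.ndim != 2:
        raise ValueError("roi_mean expects a single 2D map")
    mask = roi_mask(roi, fov, m.shape[0])
    vals = m[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no pixels")
    finite = np.isfinite(vals)
    n_bad = int((~finite).sum())
    if nonfinite == "exclude":
        if not finite.any():
            raise ValueError("ROI contains no finite pixels")
        return float(vals[finite].mean()), n_bad
    if nonfinite == "unity":
        patched = np.where(finite, vals, 1.0)
        return float(patched.mean()), n_bad
    raise ValueError("nonfinite must be 'exclude' or 'unity'")


def snr_time_equivalence(snr_ratio: float) -> float:
    """Scan-time factor equivalent to an SNR ratio under signal averaging.

    Averaged SNR grows as sqrt(scan time), so matching an SNR advantage of
    ``r`` by averaging alone takes ``r**2`` times as long.
    """
    if snr_ratio <= 0:
        raise ValueError("snr_ratio must be > 0")
    return float(snr_ratio) ** 2
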