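"""Hot-spot detection on the FCH image.

In the animal protocol the tumor ROI is drawn by hand on the choline scan,
where tumor-to-brain contrast is high. Here that step is automated with a
robust two-pass rule: estimate the normal-brain background, threshold at
``mean + k_sigma * sd``, keep 26-connected suprathreshold components of at
least ``min_voxels`` voxels, then re-estimate the background with those
components (dilated) excluded and threshold once more. The re-estimation
step keeps a large hot lesion from inflating the background and masking
itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .simulate import ScanVolume

__all__ = [
    "RoiMask",
    "BackgroundEstimate",
    "estimate_background",
    "detect_hotspots",
    "CONNECTIVITY_26",
]

# full 3x3x3 neighbourhood: 26-connected components
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RoiMask:
    """One detected hot spot: a connected voxel set on the source grid."""

    mask: np.ndarray
    centroid_mm: tuple[float, float, float]
    n_voxels: int
    mean_counts: float

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("ROI must be non-empty")


@dataclass(frozen=True)
class BackgroundEstimate:
    """Counts-per-voxel statistics of the normal-brain background."""

    mean_counts_per_voxel: float
    sd_counts_per_voxel: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("background region is empty")
        if self.sd_counts_per_voxel < 0:
            raise ValueError("sd must be >= 0")


def estimate_background(
    scan: ScanVolume,
    brain_mask: np.ndarray,
    exclude: Sequence[RoiMask] = (),
    dilate_voxels: int = 2,
) -> BackgroundEstimate:
    """Mean/SD counts per voxel over brain outside all excluded ROIs.

    Excluded ROIs are dilated by ``dilate_voxels`` (26-connectivity) so the
    blur skirt around a hot spot does not contaminate the background.
    """
    region = np.asarray(brain_mask, dtype=bool).copy()
    for roi in exclude:
        grown = ndimage.binary_dilation(
            roi.mask, structure=CONNECTIVITY_26, iterations=dilate_voxels
        )
        region &= ~grown
    if not region.any():
        raise ValueError("no brain voxels remain after ROI exclusion")
    values = scan.counts[region]
    return BackgroundEstimate(
        mean_counts_per_voxel=float(values.mean()),
        sd_counts_per_voxel=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n_voxels=int(values.size),
    )


def _components(
    scan: ScanVolume,
    brain_mask: np.ndarray,
    bg: BackgroundEstimate,
    k_sigma: float,
    min_voxels: int,
) -> list[RoiMask]:
    threshold = bg.mean_counts_per_voxel + k_sigma * bg.sd_counts_per_voxel
    above = (scan.counts > threshold) & brain_mask
    labeled, n = ndimage.label(above, structure=CONNECTIVITY_26)
    rois: list[RoiMask] = []
    spacing = np.asarray(scan.spacing_mm)
    for comp_id in range(1, n + 1):
        mask = labeled == comp_id
        n_vox = int(mask.sum())
        if n_vox < min_voxels:
            continue
        idx = np.argwhere(mask)
        centroid = tuple((idx.mean(axis=0) * spacing).tolist())
        rois.append(
            RoiMask(
                mask=mask,
                centroid_mm=centroid,  # type: ignore[arg-type]
                n_voxels=n_vox,
                mean_counts=float(scan.counts[mask].mean()),
            )
        )
    # brightest first; ties broken by size, then by centroid order
    rois.sort(key=lambda r: (-r.mean_counts, -r.n_voxels, r.centroid_mm))
    return rois


def detect_hotspots(
    scan: ScanVolume,
    brain_mask: np.ndarray,
    k_sigma: float = 3.0,
    min_voxels: int = 5,
    background_mask: np.ndarray | None = None,
) -> list[RoiMask]:
    """Detect candidate tumor ROIs on one tracer image.

    Returns connected suprathreshold components sorted by descending mean
    counts; an empty list means no hot spot (a negative scan).
    ``background_mask`` restricts the background statistics to a reference
    region (typically brain eroded away from the edge-falloff zone of the
    PSF); detection itself always searches the full ``brain_mask``.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be > 0")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    bg_region = brain_mask if background_mask is None else np.asarray(background_mask, bool)
    bg0 = estimate_background(scan, bg_region)
    first_pass = _components(scan, brain_mask, bg0, k_sigma, min_voxels)
    if not first_pass:
        return []
    bg1 = estimate_background(scan, bg_region, exclude=first_pass)
    return _components(scan, brain_mask, bg1, k_sigma, min_voxels)
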