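"""Forward simulation of reconstructed dual-tracer micro-PET images.

Tomographic reconstruction is not modelled. A reconstructed-image surrogate
is produced directly: the phantom's relative-uptake map is scaled to an
expected count level, blurred with an isotropic Gaussian point-spread
function, and Poisson noise is drawn voxel-wise. This is sufficient because
every downstream quantity is a count *ratio* on the reconstructed image;
absolute count scales are package choices (no raw count levels exist to
match), and only ratios carry scientific meaning here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .phantom import LabelVolume, Region, RegionSpec

__all__ = [
    "TracerSpec",
    "AcquisitionSpec",
    "ScanVolume",
    "activity_map",
    "simulate_scan",
    "read_scan",
    "write_scan",
    "read_labels",
    "write_labels",
    "REFERENCE_DOSE_MBQ",
    "FWHM_TO_SIGMA",
]

REFERENCE_DOSE_MBQ = 5.5  # nominal injected activity per scan
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TracerSpec:
    """One tracer administration: identity, dose, uptake period, contrast."""

    tracer_name: str  # "FCH" | "FDG"
    region_uptakes: dict[Region, RegionSpec]
    injected_dose_MBq: float = REFERENCE_DOSE_MBQ
    uptake_time_min: float = 30.0

    def __post_init__(self) -> None:
        if self.tracer_name not in ("FCH", "FDG"):
            raise ValueError("tracer_name must be 'FCH' or 'FDG'")
        if self.injected_dose_MBq <= 0:
            raise ValueError("injected dose must be > 0")
        if self.uptake_time_min <= 0:
            raise ValueError("uptake time must be > 0")

    def uptake_of(self, region: Region) -> float:
        spec = self.region_uptakes[region]
        return (
            spec.relative_uptake_fch
            if self.tracer_name == "FCH"
            else spec.relative_uptake_fdg
        )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan-level parameters of the reconstructed-image surrogate.

    ``psf_fwhm_mm`` is the scanner resolution (default 2.0 mm, typical for
    rodent PET); ``counts_per_voxel_background`` sets the expected
    reconstructed count level in normal brain at the reference dose.
    """

    scan_duration_min: float = 10.0
    psf_fwhm_mm: float = 2.0
    counts_per_voxel_background: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_duration_min <= 0 or self.psf_fwhm_mm <= 0:
            raise ValueError("scan duration and PSF FWHM must be > 0")
        if not np.isfinite(self.counts_per_voxel_background) or (
            self.counts_per_voxel_background <= 0
        ):
            raise ValueError("counts_per_voxel_background must be positive and finite")


@dataclass(frozen=True)
class ScanVolume:
    """A reconstructed 3-D count image for one tracer."""

    counts: np.ndarray
    spacing_mm: tuple[float, float, float]
    tracer_name: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def activity_map(phantom: LabelVolume, tracer: TracerSpec) -> np.ndarray:
    """Relative-activity field: each voxel carries its region's uptake ratio.

    Outside-head voxels are 0; normal brain is 1, so in-head values are
    directly interpretable as contrast versus normal brain.
    """
    present = set(np.unique(phantom.labels)) - {int(Region.OUTSIDE)}
    missing = present - {int(r) for r in tracer.region_uptakes}
    if missing:
        raise ValueError(
            f"region_uptakes missing labels {sorted(missing)} present in phantom"
        )
    out = np.zeros(phantom.shape, dtype=float)
    for region_id in present:
        region = Region(region_id)
        out[phantom.labels == region_id] = tracer.uptake_of(region)
    return out


def _blur(mean_field: np.ndarray, fwhm_mm: float, spacing_mm) -> np.ndarray:
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(spacing_mm, dtype=float)
    return ndimage.gaussian_filter(mean_field, sigma=sigma_vox, mode="constant")


def simulate_scan(
    phantom: LabelVolume,
    tracer: TracerSpec,
    acq: AcquisitionSpec,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> ScanVolume:
    """Simulate one reconstructed scan.

    Expected counts are ``activity_map * counts_per_voxel_background *
    (dose / 5.5 MBq)`` convolved with the Gaussian PSF; counts are then a
    Poisson draw (skipped when ``noise=False``, which returns the blurred
    mean field itself — useful for resolution and bias checks).
    """
    mean = (
        activity_map(phantom, tracer)
        * acq.counts_per_voxel_background
        * (tracer.injected_dose_MBq / REFERENCE_DOSE_MBQ)
    )
    blurred = _blur(mean, acq.psf_fwhm_mm, phantom.spacing_mm)
    if noise:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        counts = rng.poisson(blurred).astype(float)
    else:
        counts = blurred
    meta = {
        "tracer_name": tracer.tracer_name,
        "injected_dose_MBq": tracer.injected_dose_MBq,
        "uptake_time_min": tracer.uptake_time_min,
        "scan_duration_min": acq.scan_duration_min,
        "psf_fwhm_mm": acq.psf_fwhm_mm,
        "counts_per_voxel_background": acq.counts_per_voxel_background,
        "noise": noise,
    }
    return ScanVolume(
        counts=counts,
        spacing_mm=phantom.spacing_mm,
        tracer_name=tracer.tracer_name,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# NIfTI round trip. Counts go in the NIfTI payload with voxel spacing in the
# affine/zooms; tracer and acquisition metadata travel in a JSON sidecar.


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")


def write_scan(scan: ScanVolume, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(scan.spacing_mm) + [1.0])
    img = nib.Nifti1Image(scan.counts.astype(np.float64), affine)
    img.header.set_zooms(scan.spacing_mm)
    nib.save(img, path)
    sidecar = dict(scan.metadata)
    sidecar["tracer_name"] = scan.tracer_name
    _sidecar(path).write_text(json.dumps(sidecar, indent=2))


def read_scan(path: str | Path) -> ScanVolume:
    path = Path(path)
    try:
        img = nib.load(path)
        counts = np.asarray(img.get_fdata())
    except Exception as exc:  # malformed / truncated file
        raise ValueError(f"cannot read scan volume from {path}: {exc}") from exc
    if counts.ndim != 3:
        raise ValueError(f"{path} does not contain a 3-D volume")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    tracer = meta.pop("tracer_name", "FCH")
    return ScanVolume(
        counts=counts, spacing_mm=spacing, tracer_name=tracer, metadata=meta
    )


def write_labels(vol: LabelVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, Path(path))


def read_labels(path: str | Path) -> LabelVolume:
    try:
        img = nib.load(Path(path))
        labels = np.asarray(img.dataobj).astype(np.uint8)
    except Exception as exc:
        raise ValueError(f"cannot read label volume from {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=labels, spacing_mm=spacing)
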