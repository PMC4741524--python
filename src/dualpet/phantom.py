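"""Digital mouse-head phantoms and synthetic cohorts.

The phantom is a labelled voxel grid standing in for a reconstructed
micro-PET field of view: background, an ellipsoidal brain, optionally a
spherical tumor at the lateral xenograft inoculation site, and optionally a
small ventral-midline focus of physiologic choline uptake (a surrogate for
pituitary / choroid plexus). Cohort sampling draws per-mouse geometry and
tracer uptake ratios so that a simulated study reproduces the statistical
structure of a real dual-tracer experiment: tumors with strong FCH contrast
but near-background FDG contrast, and a fraction of tumor-free controls
carrying an FCH-avid physiologic hot spot (the false-positive mechanism).

Axis convention: 0-based indices, axis order (x = left-right,
y = dorsal-ventral with y increasing ventrally, z = rostral-caudal).
Voxel membership is by center-point inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "Region",
    "RegionSpec",
    "LabelVolume",
    "CohortSpec",
    "CohortMember",
    "make_brain_phantom",
    "insert_tumor",
    "insert_physiologic_hotspot",
    "sample_cohort",
    "BRAIN_SEMI_AXES_MM",
    "DEFAULT_TUMOR_OFFSET_MM",
    "HOTSPOT_OFFSET_MM",
    "HOTSPOT_DIAMETER_MM",
]


class Region(IntEnum):
    """Tissue labels of the phantom."""

    OUTSIDE = 0
    BRAIN = 1
    TUMOR = 2
    HOTSPOT = 3


# Brain modelled as a 10 x 8 x 6 mm ellipsoid (approximate adult mouse brain
# envelope). The longest axis is placed left-right so the laterally offset
# tumor site remains wholly inside the ellipsoid at the largest tumor size.
BRAIN_SEMI_AXES_MM = (5.0, 3.0, 4.0)

# Xenograft site: 2 mm lateral of midline, 2.5 mm deep from the dorsal
# surface (y increases ventrally; dorsal surface at -3 mm from center).
DEFAULT_TUMOR_OFFSET_MM = (2.0, -0.5, 0.0)

# Physiologic hot-spot surrogate: fixed ventral-midline site, smaller than
# any tumor so size alone cannot separate the two; kept ~1 FWHM clear of
# the brain boundary so boundary spill-out does not dominate its signal.
HOTSPOT_OFFSET_MM = (0.0, 1.5, 0.0)
HOTSPOT_DIAMETER_MM = 1.5


@dataclass(frozen=True)
class RegionSpec:
    """Relative tracer uptake of one tissue region.

    Uptake ratios are dimensionless activity concentrations relative to
    normal brain; by convention normal brain has both ratios equal to 1.
    """

    region_id: Region
    relative_uptake_fch: float
    relative_uptake_fdg: float

    def __post_init__(self) -> None:
        if self.relative_uptake_fch < 0 or self.relative_uptake_fdg < 0:
            raise ValueError("relative uptakes must be >= 0")
        if self.region_id == Region.BRAIN and (
            self.relative_uptake_fch != 1.0 or self.relative_uptake_fdg != 1.0
        ):
            raise ValueError("normal brain uptake is 1 by convention")


@dataclass(frozen=True)
class LabelVolume:
    """Integer label grid with voxel spacing.

    ``labels`` assigns every voxel one :class:`Region`; ``spacing_mm`` is
    the per-axis voxel edge length.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def center_mm(self) -> np.ndarray:
        """Physical coordinate of the grid center (voxel-center convention)."""
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing_mm)

    def brain_mask(self) -> np.ndarray:
        """Boolean mask of every in-brain voxel (brain, tumor, hot spot)."""
        return self.labels != Region.OUTSIDE

    def region_mask(self, region: Region) -> np.ndarray:
        return self.labels == region

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        grids = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(self.shape, self.spacing_mm)),
            indexing="ij",
        )
        return grids[0], grids[1], grids[2]


def _as_spacing(spacing_mm: float | Sequence[float]) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError("spacing must be scalar or length-3")
    return tuple(arr)  # type: ignore[return-value]


def make_brain_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing_mm: float | Sequence[float] = 0.4,
) -> LabelVolume:
    """Create a background + brain phantom.

    The brain is a single connected ellipsoid of semi-axes
    ``BRAIN_SEMI_AXES_MM`` centered in the grid. Raises ``ValueError`` if
    the grid cannot contain it.
    """
    spacing = _as_spacing(spacing_mm)
    extent = np.asarray(shape) * np.asarray(spacing)
    needed = 2 * np.asarray(BRAIN_SEMI_AXES_MM)
    if np.any(extent < needed):
        raise ValueError(
            f"grid extent {tuple(extent)} mm cannot contain the "
            f"{tuple(needed)} mm brain ellipsoid"
        )
    labels = np.zeros(shape, dtype=np.uint8)
    vol = LabelVolume(labels=labels, spacing_mm=spacing)
    cx, cy, cz = vol.center_mm
    x, y, z = vol.voxel_centers_mm()
    a, b, c = BRAIN_SEMI_AXES_MM
    inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    labels[inside] = Region.BRAIN
    return vol


def _insert_sphere(
    phantom: LabelVolume,
    diameter_mm: float,
    center_offset_mm: Sequence[float],
    label: Region,
) -> LabelVolume:
    if diameter_mm < 0:
        raise ValueError("diameter must be >= 0")
    if diameter_mm == 0:
        return phantom
    center = phantom.center_mm + np.asarray(center_offset_mm, dtype=float)
    x, y, z = phantom.voxel_centers_mm()
    r = diameter_mm / 2.0
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= r**2
    # the sphere must carve brain tissue only: any voxel falling on
    # background (or outside the grid by construction) is a placement error
    if not inside.any():
        raise ValueError("sphere contains no voxel centers; grid too coarse")
    if np.any(phantom.labels[inside] == Region.OUTSIDE):
        raise ValueError(f"{label.name.lower()} extends outside the brain")
    labels = phantom.labels.copy()
    labels[inside] = label
    return replace(phantom, labels=labels)


def insert_tumor(
    phantom: LabelVolume,
    diameter_mm: float,
    center_offset_mm: Sequence[float] = DEFAULT_TUMOR_OFFSET_MM,
) -> LabelVolume:
    """Insert a spherical tumor; offset is in mm relative to the brain center.

    The default offset is the orthotopic inoculation site: 2 mm lateral of
    midline, 2.5 mm deep from the dorsal surface.
    """
    return _insert_sphere(phantom, diameter_mm, center_offset_mm, Region.TUMOR)


def insert_physiologic_hotspot(
    phantom: LabelVolume,
    diameter_mm: float = HOTSPOT_DIAMETER_MM,
) -> LabelVolume:
    """Insert the physiologic FCH hot spot at the fixed ventral-midline site."""
    return _insert_sphere(phantom, diameter_mm, HOTSPOT_OFFSET_MM, Region.HOTSPOT)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated two-group study.

    Defaults mirror a 10 tumor-bearing / 14 control design in which
    controls carry a physiologic FCH hot spot with probability 4/14, tumor
    FCH uptake ratios span 1.1-4.2, and tumor diameters span 2.8-4.2 mm.
    Uptake ranges are *true tissue contrasts* (pre-blur): the tumor FDG
    band (1.2, 1.6) and the hot-spot FCH band (4.0, 12.0) are calibrated
    so that, after dilution by the default 2 mm PSF, the *measured*
    ratios reproduce the observed study — fused-image tumor TBRs of
    roughly 1.0-1.2 despite tumors remaining hard to see on the FDG scan
    alone, and control hot-spot FCH TBRs of roughly 1.4-1.8 on foci much
    smaller than the scanner resolution.
    """

    n_tumor: int = 10
    n_control: int = 14
    p_physiologic_hotspot: float = 4.0 / 14.0
    tumor_fch_uptake_range: tuple[float, float] = (1.1, 4.2)
    tumor_fdg_uptake_range: tuple[float, float] = (1.2, 1.6)
    hotspot_fch_uptake_range: tuple[float, float] = (4.0, 12.0)
    tumor_diameter_range_mm: tuple[float, float] = (2.8, 4.2)
    tumor_fch_uptake_choices: tuple[float, ...] | None = None
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.p_physiologic_hotspot <= 1.0:
            raise ValueError("p_physiologic_hotspot must be in [0, 1]")
        for lo, hi in (
            self.tumor_fch_uptake_range,
            self.tumor_fdg_uptake_range,
            self.hotspot_fch_uptake_range,
            self.tumor_diameter_range_mm,
        ):
            if lo > hi:
                raise ValueError("interval lower bound exceeds upper bound")


@dataclass
class CohortMember:
    """One simulated animal: group, geometry and per-region tracer uptakes.

    The label volume is built lazily via :meth:`build_phantom` so that large
    design-level cohorts (e.g. 1000 controls for rate calibration) carry no
    voxel data until imaging is actually simulated.
    """

    mouse_id: str
    group: str  # "tumor_bearing" | "control"
    tumor_diameter_mm: float | None
    has_hotspot: bool
    region_uptakes: dict[Region, RegionSpec]
    shape: tuple[int, int, int]
    spacing_mm: float
    _phantom: LabelVolume | None = field(default=None, repr=False, compare=False)

    def build_phantom(self) -> LabelVolume:
        if self._phantom is None:
            vol = make_brain_phantom(self.shape, self.spacing_mm)
            if self.tumor_diameter_mm is not None:
                vol = insert_tumor(vol, self.tumor_diameter_mm)
            if self.has_hotspot:
                vol = insert_physiologic_hotspot(vol)
            self._phantom = vol
        return self._phantom

    @property
    def phantom(self) -> LabelVolume:
        return self.build_phantom()


def _uniform(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def sample_cohort(spec: CohortSpec) -> list[CohortMember]:
    """Draw a reproducible cohort from a :class:`CohortSpec`.

    Tumor-bearing mice get a tumor with FCH uptake uniform over
    ``tumor_fch_uptake_range`` (or resampled from
    ``tumor_fch_uptake_choices`` when given) and FDG uptake uniform over
    the narrow near-1 band; controls get a physiologic FCH hot spot with
    probability ``p_physiologic_hotspot`` (hot-spot FDG uptake is 1).
    """
    rng = np.random.default_rng(spec.seed)
    members: list[CohortMember] = []
    brain = RegionSpec(Region.BRAIN, 1.0, 1.0)
    for i in range(spec.n_tumor):
        if spec.tumor_fch_uptake_choices is not None:
            fch = float(rng.choice(np.asarray(spec.tumor_fch_uptake_choices)))
        else:
            fch = _uniform(rng, spec.tumor_fch_uptake_range)
        fdg = _uniform(rng, spec.tumor_fdg_uptake_range)
        diameter = _uniform(rng, spec.tumor_diameter_range_mm)
        members.append(
            CohortMember(
                mouse_id=f"tumor_{i + 1:02d}",
                group="tumor_bearing",
                tumor_diameter_mm=diameter,
                has_hotspot=False,
                region_uptakes={
                    Region.BRAIN: brain,
                    Region.TUMOR: RegionSpec(Region.TUMOR, fch, fdg),
                },
                shape=spec.shape,
                spacing_mm=spec.spacing_mm,
            )
        )
    for i in range(spec.n_control):
        has_hotspot = bool(rng.random() < spec.p_physiologic_hotspot)
        uptakes = {Region.BRAIN: brain}
        if has_hotspot:
            fch = _uniform(rng, spec.hotspot_fch_uptake_range)
            uptakes[Region.HOTSPOT] = RegionSpec(Region.HOTSPOT, fch, 1.0)
        members.append(
            CohortMember(
                mouse_id=f"control_{i + 1:02d}",
                group="control",
                tumor_diameter_mm=None,
                has_hotspot=has_hotspot,
                region_uptakes=uptakes,
                shape=spec.shape,
                spacing_mm=spec.spacing_mm,
            )
        )
    return members
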