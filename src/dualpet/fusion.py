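"""Dual-tracer fusion and subtraction.

The two scans come from separate sessions with independent doses and decay
histories, so raw counts are not on a common scale. Each image is first
normalized by its own normal-brain background mean, which puts normal brain
at 1 in both tracers. "Merging" is then the voxel-wise sum of the two
normalized images, and subtracting the FCH counts from the merged image
recovers exactly the FDG component — the quantity on which a true tumor
(elevated residual) separates from a physiologic choline focus (residual at
background). Registration between the sessions is an integer-voxel
translation chosen by normalized cross-correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .detect import BackgroundEstimate
from .simulate import ScanVolume

__all__ = [
    "NormalizedVolume",
    "FusedResult",
    "normalize_to_background",
    "register_translation",
    "fuse_and_subtract",
]


@dataclass(frozen=True)
class NormalizedVolume:
    """A scan divided by its normal-brain background mean (dimensionless)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    tracer_name: str
    background_used: BackgroundEstimate


@dataclass(frozen=True)
class FusedResult:
    """Merged dual-tracer image and its FDG component after FCH subtraction.

    ``valid_mask`` marks voxels covered by both volumes after the shift;
    out-of-field voxels are excluded from downstream statistics.
    """

    merged: np.ndarray
    fdg_component: np.ndarray
    shift_voxels: tuple[int, int, int]
    valid_mask: np.ndarray


def normalize_to_background(
    scan: ScanVolume, bg: BackgroundEstimate
) -> NormalizedVolume:
    """Divide every voxel by the background mean counts per voxel."""
    if bg.mean_counts_per_voxel <= 0:
        raise ValueError("background mean must be > 0 to normalize")
    return NormalizedVolume(
        values=scan.counts / bg.mean_counts_per_voxel,
        spacing_mm=scan.spacing_mm,
        tracer_name=scan.tracer_name,
        background_used=bg,
    )


def _shift_with_mask(
    values: np.ndarray, shift: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Translate by whole voxels; returns shifted array and coverage mask."""
    out = np.zeros_like(values)
    valid = np.zeros(values.shape, dtype=bool)
    src = []
    dst = []
    for n, s in zip(values.shape, shift):
        if abs(s) >= n:
            return out, valid
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = values[tuple(src)]
    valid[tuple(dst)] = True
    return out, valid


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_translation(
    moving: NormalizedVolume,
    fixed: NormalizedVolume,
    max_shift_mm: float = 2.0,
) -> tuple[int, int, int]:
    """Integer-voxel shift of ``moving`` maximizing NCC against ``fixed``.

    The search is exhaustive within ``max_shift_mm`` per axis; ties are
    broken toward the zero shift (candidates are visited in order of
    increasing shift magnitude and only a strictly better correlation
    replaces the incumbent). For speed the correlation is evaluated on the
    bounding box of the fixed volume's support, padded by the search
    radius — outside it both volumes are flat background.
    """
    if moving.values.shape != fixed.values.shape or not np.allclose(
        moving.spacing_mm, fixed.spacing_mm
    ):
        raise ValueError("volumes must share grid shape and spacing")
    max_vox = [int(np.floor(max_shift_mm / s)) for s in fixed.spacing_mm]
    support = np.argwhere(np.abs(fixed.values) > 0.05 * np.abs(fixed.values).max())
    if support.size:
        lo = np.maximum(support.min(axis=0) - np.asarray(max_vox) - 1, 0)
        hi = np.minimum(
            support.max(axis=0) + np.asarray(max_vox) + 2, fixed.values.shape
        )
    else:
        lo, hi = np.zeros(3, dtype=int), np.asarray(fixed.values.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    fixed_box = fixed.values[box]
    moving_box = moving.values[box]
    candidates = sorted(
        itertools.product(*(range(-m, m + 1) for m in max_vox)),
        key=lambda s: (sum(c * c for c in s), s),
    )
    best_shift = (0, 0, 0)
    best_score = -np.inf
    for shift in candidates:
        shifted, valid = _shift_with_mask(moving_box, shift)
        if not valid.any():
            continue
        score = _ncc(shifted[valid], fixed_box[valid])
        if score > best_score:
            best_score = score
            best_shift = shift
    return best_shift  # type: ignore[return-value]


def fuse_and_subtract(
    fdg: NormalizedVolume,
    fch: NormalizedVolume,
    shift: tuple[int, int, int] = (0, 0, 0),
) -> FusedResult:
    """Merge the two normalized images and subtract the FCH component.

    ``merged = fdg + shift(fch)`` and ``fdg_component = merged - shift(fch)``
    hold element-wise exactly on the valid region, so the subtraction
    identity is available as a hard invariant downstream.
    """
    if fdg.values.shape != fch.values.shape:
        raise ValueError("volumes must share grid shape")
    shifted_fch, valid = _shift_with_mask(fch.values, tuple(int(s) for s in shift))
    merged = np.where(valid, fdg.values + shifted_fch, 0.0)
    fdg_component = merged - np.where(valid, shifted_fch, 0.0)
    return FusedResult(
        merged=merged,
        fdg_component=fdg_component,
        shift_voxels=tuple(int(s) for s in shift),  # type: ignore[arg-type]
        valid_mask=valid,
    )
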