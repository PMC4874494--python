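"""Spherical ROI definition, ROI statistics and repeatability metrics.

The NEMA NU-2 standard wants ROI diameters "as close as possible" to the
physical inner sphere diameters; here each ROI is the Binary-Center-
Inclusion filled sphere at the accurately localized (sub-voxel) PET
center.  Repeatability across repeated acquisitions is summarized by
per-axis standard deviations of the centers, pairwise sphere-distance
discrepancies between labeled positions sets, and coefficients of
variation of the ROI statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import EmptyROIError, ROIClippedWarning
from .pet_coarse import NEMA_INNER_DIAMETERS_MM
from .volume_io import ImageVolume

__all__ = [
    "ROIStats",
    "ReproStats",
    "sphere_rois",
    "roi_stats",
    "pairwise_distances",
    "distance_discrepancies",
    "repro_stats",
]


@dataclass
class ROIStats:
    """Per-sphere and six-sphere-union ROI statistics."""

    per_sphere: dict          # sphere index -> {"mean", "max", "count"}
    union_mean: float
    union_max: float
    union_count: int
    warnings: list = field(default_factory=list)


@dataclass
class ReproStats:
    """Repeatability metrics over repeated center localizations / ROI runs."""

    center_sd_mm: dict | None = None       # sphere index -> (sd_x, sd_y, sd_z)
    distances_mm: dict | None = None       # label -> {(i, j): mm}
    discrepancies_mm: dict | None = None   # (label_x, label_y) -> {(i, j): mm}
    cov: dict | None = None                # series name -> SD / mean


def sphere_rois(
    pet: ImageVolume,
    centers_world,
    diameters_mm=NEMA_INNER_DIAMETERS_MM,
) -> dict:
    """Binary-Center-Inclusion filled-sphere masks at the accurate PET
    centers, one boolean mask per sphere (dict keyed 1..6)."""
    centers = np.asarray(centers_world, dtype=float).reshape(-1, 3)
    shape = np.array(pet.shape)
    masks: dict = {}
    for i, (c, d) in enumerate(zip(centers, diameters_mm), start=1):
        r = d / 2.0
        cidx = pet.world_to_voxel(c)
        half = r / pet.spacing
        lo = np.floor(cidx - half).astype(int) - 1
        hi = np.ceil(cidx + half).astype(int) + 1
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape - 1)
        if np.any(lo_c != lo) or np.any(hi_c != hi):
            warnings.warn(
                f"ROI for sphere {i} is clipped by the volume boundary",
                ROIClippedWarning,
                stacklevel=2,
            )
        mask = np.zeros(pet.shape, dtype=bool)
        if np.all(hi_c >= lo_c):
            axes = [np.arange(l, h + 1) for l, h in zip(lo_c, hi_c)]
            grids = np.meshgrid(
                *[(ax - ci) * s for ax, ci, s in zip(axes, cidx, pet.spacing)],
                indexing="ij",
            )
            d2 = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2
            sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo_c, hi_c))
            mask[sl] = d2 <= r * r
        if not mask.any():
            raise EmptyROIError(f"ROI for sphere {i} covers no voxels")
        masks[i] = mask
    return masks


def roi_stats(pet: ImageVolume, masks: dict) -> ROIStats:
    """Mean, max and voxel count per ROI and over the union of all ROIs."""
    per: dict = {}
    union = np.zeros(pet.shape, dtype=bool)
    for i, mask in sorted(masks.items()):
        vals = pet.voxels[mask]
        if vals.size == 0:
            raise EmptyROIError(f"ROI for sphere {i} covers no voxels")
        per[i] = {
            "mean": float(vals.mean()),
            "max": float(vals.max()),
            "count": int(vals.size),
        }
        union |= mask
    uvals = pet.voxels[union]
    return ROIStats(
        per_sphere=per,
        union_mean=float(uvals.mean()),
        union_max=float(uvals.max()),
        union_count=int(uvals.size),
    )


def pairwise_distances(centers) -> dict:
    """All 15 pairwise distances between six sphere centers (mm)."""
    pts = np.asarray(centers, dtype=float).reshape(-1, 3)
    return {
        (i + 1, j + 1): float(np.linalg.norm(pts[i] - pts[j]))
        for i, j in combinations(range(len(pts)), 2)
    }


def distance_discrepancies(centers_x, centers_y) -> dict:
    """``|D_X;i,j - D_Y;i,j|`` for every sphere pair: how far from an exact
    isometry the two position sets are.  Exactly zero whenever one set is a
    rigid transform of the other."""
    dx = pairwise_distances(centers_x)
    dy = pairwise_distances(centers_y)
    return {k: abs(dx[k] - dy[k]) for k in dx}


def repro_stats(
    center_sets=None,
    stat_series=None,
    ddof: int = 1,
) -> ReproStats:
    """Repeatability statistics.

    ``center_sets``: array-like (n_realizations, n_spheres, 3) in mm ->
    per-sphere, per-axis SDs.  ``stat_series``: dict name -> sequence of a
    scalar ROI statistic across realizations -> COV = SD / mean.  SDs use
    the sample (n-1) denominator by default (``ddof`` configurable).
    """
    out = ReproStats()
    if center_sets is not None:
        arr = np.asarray(center_sets, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError("center_sets must be (n>=2, n_spheres, 3)")
        sds = arr.std(axis=0, ddof=ddof)
        out.center_sd_mm = {i + 1: sds[i] for i in range(arr.shape[1])}
    if stat_series is not None:
        cov = {}
        for name, series in stat_series.items():
            s = np.asarray(series, dtype=float)
            if s.size < 2:
                raise ValueError(f"series {name!r} needs >= 2 realizations")
            mean = s.mean()
            cov[name] = float(s.std(ddof=ddof) / mean) if mean != 0 else float("nan")
        out.cov = cov
    return out
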