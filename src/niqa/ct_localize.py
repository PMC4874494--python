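"""Accurate sub-voxel localization of all six spheres in the CT volume.

The three largest spheres are found directly with hollow-shell matched
filters.  Their wall voxels teach the algorithm the CT value of the plastic
sphere wall (``mu_psw``); the three smallest spheres are then predicted by
reflecting the large-sphere centers through the hexagon center, and located
on an integer-up-sampled subvolume whose values are rescaled to
``-|V - mu_psw|`` so that the shell filter matches *wall-likeness* rather
than raw intensity (which would be dominated by noise for so few wall
voxels).

Air bubbles — common after filling the phantom — are detected per
subvolume with a histogram-mode test and excluded from every matched
filter statistic, because their extreme CT values would otherwise drag the
peak away from the true center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ClippedBoxWarning,
    DegenerateArrangementError,
    NoConcaveNeighborhoodError,
    NoConcaveNeighborhoodWarning,
    WallModelError,
)
from .templates import (
    MatchedValueSpace,
    build_template,
    concave_subset,
    fit_quadratic_vertex,
    matched_scan,
)
from .volume_io import ImageVolume

__all__ = [
    "SubvolumeBox",
    "AirClassification",
    "WallModel",
    "LocalizationResult",
    "extract_box",
    "detect_air",
    "localize_large",
    "learn_wall",
    "hexagon_extrapolate",
    "upsample_integer",
    "rescale_to_wall",
    "localize_small",
    "localize_spheres",
]


@dataclass(frozen=True)
class SubvolumeBox:
    """Half-open index box ``[lo, hi)`` in the parent CT grid."""

    lo: np.ndarray
    hi: np.ndarray
    spacing: np.ndarray
    clipped: bool = False

    @property
    def slices(self) -> tuple:
        return tuple(slice(int(l), int(h)) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple:
        return tuple(int(h - l) for l, h in zip(self.lo, self.hi))


@dataclass
class AirClassification:
    """Result of the histogram-mode air test on one CT subvolume."""

    air_mask: np.ndarray
    detected: bool
    mean: float
    sd: float


@dataclass
class WallModel:
    """Mean CT value of plastic-sphere-wall voxels, pooled over spheres 4-6."""

    mu_psw: float
    n_wall_voxels: int


@dataclass
class LocalizationResult:
    center: np.ndarray  # fractional index in the parent CT grid
    wall_values: np.ndarray | None
    air: AirClassification | None
    warnings: list = field(default_factory=list)


def _min_voxels(extent_mm: float, spacing: float) -> int:
    """Minimal voxel count whose physical span covers ``extent_mm``."""
    n = int(np.ceil(extent_mm / spacing - 1e-9))
    while n * spacing < extent_mm - 1e-9:
        n += 1
    return max(n, 1)


def extract_box(
    ct: ImageVolume,
    center_estimate,
    diameter_mm: float,
    k_diameters: int,
) -> SubvolumeBox:
    """Bounding box around a center estimate spanning ``k`` sphere diameters
    per axis (k=2 for the large spheres, k=3 for the small ones, which keeps
    the subvolume mostly water while excluding neighboring spheres)."""
    c = np.rint(np.asarray(center_estimate, dtype=float)).astype(int)
    shape = np.array(ct.shape)
    ext = np.array([_min_voxels(k_diameters * diameter_mm, s) for s in ct.spacing])
    lo = c - ext // 2
    hi = lo + ext
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, shape)
    clipped = bool(np.any(lo_c != lo) or np.any(hi_c != hi))
    if clipped:
        warnings.warn(
            "bounding box clipped at the volume edge; localization proceeds on the clipped box",
            ClippedBoxWarning,
            stacklevel=2,
        )
    return SubvolumeBox(lo=lo_c, hi=hi_c, spacing=ct.spacing.copy(), clipped=clipped)


def detect_air(sub_values: np.ndarray) -> AirClassification:
    """Histogram-mode air test with the 2 SD labeling rule.

    The subvolume values are histogrammed into 10 equal-width bins spanning
    [min, max].  If the most-populated bin is in the upper half (bins 6-10,
    1-based) most voxels are water sitting *above* the middle of the value
    range, meaning something far below water — air — must be present; every
    voxel at or below ``mean - 2*SD`` is then labeled air.
    """
    vals = np.asarray(sub_values, dtype=float)
    vmin, vmax = float(vals.min()), float(vals.max())
    mean = float(vals.mean())
    sd = float(vals.std())  # population SD of the whole subvolume
    if vmax <= vmin:
        return AirClassification(np.zeros(vals.shape, dtype=bool), False, mean, sd)
    counts, _ = np.histogram(vals, bins=10, range=(vmin, vmax))
    mode_bin = int(np.argmax(counts)) + 1  # 1-based; first bin wins ties
    detected = mode_bin >= 6
    if detected:
        air_mask = vals <= mean - 2.0 * sd
    else:
        air_mask = np.zeros(vals.shape, dtype=bool)
    return AirClassification(air_mask, detected, mean, sd)


def upsample_integer(sub_values: np.ndarray, spacing) -> tuple:
    """Integer nearest-neighbor up-sampling to sub-millimeter voxels.

    Per axis the replication factor is the smallest integer ``f`` with
    ``spacing/f < 1`` mm (``f = 1`` if the spacing is already < 1 mm); no
    interpolation, the value multiset is preserved up to multiplicity.
    Returns ``(upsampled, factors)``.
    """
    s = np.asarray(spacing, dtype=float).reshape(3)
    factors = np.array([1 if sp < 1.0 else int(np.floor(sp)) + 1 for sp in s])
    out = np.asarray(sub_values)
    for axis, f in enumerate(factors):
        if f > 1:
            out = np.repeat(out, f, axis=axis)
    return out, factors


def rescale_to_wall(values: np.ndarray, mu_psw: float) -> np.ndarray:
    """Wall-likeness rescaling ``V -> -|V - mu_psw|``: the maximum value 0
    is attained exactly at the learned plastic-wall CT value, and air is
    maximally penalized."""
    return -np.abs(np.asarray(values, dtype=float) - mu_psw)


def _subvoxel_center(space: MatchedValueSpace) -> tuple:
    """Concave-subset + quadratic-vertex refinement of the argmax.

    Returns ``(center, warnings)`` with the center as a fractional index in
    the grid the value space was computed over."""
    warns: list[str] = []
    try:
        lo, hi = concave_subset(space)
    except NoConcaveNeighborhoodError:
        warnings.warn(
            "no concave neighborhood at the argmax; falling back to a 3x3x3 box",
            NoConcaveNeighborhoodWarning,
            stacklevel=3,
        )
        warns.append("NoConcaveNeighborhood")
        m = np.array(space.argmax_index)
        lo = np.maximum(m - 1, 0)
        hi = np.minimum(m + 1, np.array(space.values.shape) - 1)
    box_sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo, hi))
    box_vals = space.values[box_sl]
    box_valid = space.valid[box_sl]
    valid_arg = None if box_valid.all() else box_valid
    vertex, info = fit_quadratic_vertex(box_vals, valid=valid_arg)
    warns.extend(info["warnings"])
    center = vertex + lo + space.anchor
    return center, warns


def localize_large(
    ct: ImageVolume,
    box: SubvolumeBox,
    inner_diameter_mm: float,
    wall_mm: float = 1.0,
    air_detection: bool = True,
) -> LocalizationResult:
    """Accurate CT localization of one of the three largest spheres.

    A hollow-shell template is matched over the subvolume (mean of non-air
    voxels when air was detected, sum otherwise); the shell voxels at the
    argmax, minus air, are labeled 'plastic sphere wall' and their values
    recorded; the sub-voxel center comes from the quadratic vertex over the
    concave neighborhood of the peak.
    """
    sub = np.asarray(ct.voxels[box.slices], dtype=float)
    warns: list[str] = []
    air = detect_air(sub) if air_detection else AirClassification(
        np.zeros(sub.shape, dtype=bool), False, float(sub.mean()), float(sub.std())
    )
    template = build_template("SHELL", inner_diameter_mm, wall_mm, spacing=box.spacing)
    if air.detected:
        space = matched_scan(sub, template, statistic="MEAN", exclude=air.air_mask)
    else:
        space = matched_scan(sub, template, statistic="SUM")
    warns.extend(space.warnings)

    # label wall voxels: the shell at the argmax, minus air
    lo_t = np.array(space.argmax_index)
    sl = tuple(slice(int(l), int(l) + n) for l, n in zip(lo_t, template.mask.shape))
    covered = template.mask & ~air.air_mask[sl]
    wall_values = sub[sl][covered]

    center_sub, w2 = _subvoxel_center(space)
    warns.extend(w2)
    return LocalizationResult(
        center=center_sub + box.lo,
        wall_values=wall_values,
        air=air,
        warnings=warns,
    )


def learn_wall(wall_value_sets) -> WallModel:
    """Pool the wall-voxel values of the three largest spheres into the
    plastic-wall model ``mu_psw`` (plain mean over the union of voxels)."""
    arrays = [np.asarray(w, dtype=float).ravel() for w in wall_value_sets if w is not None]
    pooled = np.concatenate(arrays) if arrays else np.array([])
    if pooled.size == 0:
        raise WallModelError("no voxels labeled as plastic sphere wall")
    mu = float(pooled.mean())
    if not np.isfinite(mu):
        raise WallModelError("non-finite plastic wall mean")
    return WallModel(mu_psw=mu, n_wall_voxels=int(pooled.size))


def hexagon_extrapolate(c4, c5, c6, collinearity_tol: float = 1e-6) -> tuple:
    """Predict the three smallest sphere centers from the three largest.

    The spheres sit at consecutive vertices of a (roughly regular) hexagon
    in descending diameter order; for consecutive vertices the hexagon
    center is ``C_H = C4 + C6 - C5``, and each small sphere is the
    reflection of its large partner through it:
    ``C_i = 2*C_H - C_{i+3}`` for i in {1, 2, 3}.

    The formula is affine, so it may be applied in voxel or mm coordinates
    alike and is exactly equivariant under rigid motions.
    """
    p4 = np.asarray(c4, dtype=float)
    p5 = np.asarray(c5, dtype=float)
    p6 = np.asarray(c6, dtype=float)
    u = p5 - p6
    v = p4 - p6
    cross = np.cross(u, v)
    scale = max(np.linalg.norm(u) * np.linalg.norm(v), 1e-300)
    if np.linalg.norm(cross) / scale <= collinearity_tol:
        raise DegenerateArrangementError("the three large-sphere centers are collinear")
    center_h = p4 + p6 - p5
    c1 = 2.0 * center_h - p4
    c2 = 2.0 * center_h - p5
    c3 = 2.0 * center_h - p6
    return c1, c2, c3


def localize_small(
    ct: ImageVolume,
    box: SubvolumeBox,
    inner_diameter_mm: float,
    wall_model: WallModel,
    wall_mm: float = 1.0,
    air_detection: bool = True,
) -> LocalizationResult:
    """Accurate CT localization of one of the three smallest spheres.

    Pipeline: integer up-sampling to sub-millimeter voxels (the 1 mm walls
    are barely representable at typical CT spacing) -> air test on the
    up-sampled values -> wall-likeness rescaling with ``mu_psw`` -> shell
    matched filter (mean over non-air) -> quadratic sub-voxel vertex,
    mapped back to parent-grid fractional indices.
    """
    sub = np.asarray(ct.voxels[box.slices], dtype=float)
    warns: list[str] = []
    up, factors = upsample_integer(sub, box.spacing)
    up_spacing = box.spacing / factors
    air = detect_air(up) if air_detection else AirClassification(
        np.zeros(up.shape, dtype=bool), False, float(up.mean()), float(up.std())
    )
    rescaled = rescale_to_wall(up, wall_model.mu_psw)
    template = build_template("SHELL", inner_diameter_mm, wall_mm, spacing=up_spacing)
    if air.detected:
        space = matched_scan(rescaled, template, statistic="MEAN", exclude=air.air_mask)
    else:
        space = matched_scan(rescaled, template, statistic="SUM")
    warns.extend(space.warnings)
    center_up, w2 = _subvoxel_center(space)
    warns.extend(w2)
    # center-aligned replication: up-sampled index u -> parent (u + 0.5)/f - 0.5
    center_parent = (center_up + 0.5) / factors - 0.5
    return LocalizationResult(
        center=center_parent + box.lo,
        wall_values=None,
        air=air,
        warnings=warns,
    )


def localize_spheres(
    ct: ImageVolume,
    large_estimates: dict,
    diameters_mm=(10.0, 13.0, 17.0, 22.0, 28.0, 37.0),
    wall_mm: float = 1.0,
    air_detection: bool = True,
) -> tuple:
    """Run the full CT localization for all six spheres.

    ``large_estimates`` maps sphere indices {4, 5, 6} to (fractional) CT
    voxel index estimates.  Returns ``(centers, wall_model, results)`` with
    ``centers`` a dict sphere-index -> fractional CT voxel index.
    """
    results: dict = {}
    centers: dict = {}
    for i in (6, 5, 4):
        d = float(diameters_mm[i - 1])
        box = extract_box(ct, large_estimates[i], d, k_diameters=2)
        res = localize_large(ct, box, d, wall_mm=wall_mm, air_detection=air_detection)
        results[i] = res
        centers[i] = res.center
    wall_model = learn_wall([results[i].wall_values for i in (6, 5, 4)])
    small_est = hexagon_extrapolate(centers[4], centers[5], centers[6])
    for i, est in zip((1, 2, 3), small_est):
        d = float(diameters_mm[i - 1])
        box = extract_box(ct, est, d, k_diameters=3)
        res = localize_small(
            ct, box, d, wall_model, wall_mm=wall_mm, air_detection=air_detection
        )
        results[i] = res
        centers[i] = res.center
    return centers, wall_model, results
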