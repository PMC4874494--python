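"""Binary matched-filter templates and sub-grid quadratic peak fitting.

The object detector used throughout the pipeline is a *binary matched
filter*: a voxel mask of the expected object (a filled sphere in PET, a
hollow plastic shell in CT) that is slid across the volume; the sum or mean
of the covered voxels populates a "matched value space" whose peak marks
the object.  Masks are rasterized with the Binary Center Inclusion rule:
a voxel belongs to the template iff its CENTER lies within or on the
analytic sphere boundary (``<=`` comparisons, no tolerance).

Sub-voxel peak positions come from fitting a full N-variate quadratic
(constant + linear + all pure and cross second-order terms) to the matched
values around the peak and solving for its vertex analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve

from .errors import (
    DegenerateFitError,
    DegenerateTemplateError,
    MultipleMaximaWarning,
    NoConcaveNeighborhoodError,
    NonConcaveFitWarning,
    TemplateTooLargeError,
)

__all__ = [
    "BinaryTemplate",
    "MatchedValueSpace",
    "build_template",
    "matched_scan",
    "concave_subset",
    "fit_quadratic_vertex",
]


@dataclass(frozen=True)
class BinaryTemplate:
    """A binary matched-filter mask with its geometric anchor.

    ``anchor`` is the (possibly fractional) index of the analytic sphere
    center within the mask grid, in array order.
    """

    mask: np.ndarray
    anchor: np.ndarray
    kind: str  # FILLED or SHELL
    inner_diameter_mm: float
    wall_mm: float = 0.0
    spacing: np.ndarray | None = None

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class MatchedValueSpace:
    """Matched-filter values over all template placements that fit.

    ``values[m]`` is the statistic with the template anchor at volume index
    ``m + anchor`` (so the value space is smaller than the volume: edges
    where the template would overhang are not populated).
    """

    values: np.ndarray
    valid: np.ndarray
    argmax_index: tuple
    anchor: np.ndarray
    warnings: list = field(default_factory=list)

    def center_in_volume(self, index=None) -> np.ndarray:
        """Volume-grid (fractional) position of the sphere center for a
        value-space index (default: the argmax)."""
        idx = np.asarray(self.argmax_index if index is None else index, dtype=float)
        return idx + self.anchor


def build_template(
    kind: str,
    inner_diameter_mm: float,
    wall_mm: float = 0.0,
    spacing=(1.0, 1.0, 1.0),
    center_offset=(0.0, 0.0, 0.0),
) -> BinaryTemplate:
    """Rasterize a filled sphere or hollow shell by Binary Center Inclusion.

    ``center_offset`` (voxels, array order) shifts the analytic sphere
    center away from the central voxel center, which is needed when mapped
    sphere centers do not coincide with the voxel lattice.
    """
    kind = kind.upper()
    if kind not in ("FILLED", "SHELL"):
        raise ValueError(f"unknown template kind {kind!r}")
    if inner_diameter_mm <= 0:
        raise ValueError("inner_diameter_mm must be positive")
    if kind == "SHELL" and wall_mm <= 0:
        raise ValueError("SHELL template requires wall_mm > 0")
    s = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(s <= 0):
        raise ValueError("spacing must be positive")
    off = np.asarray(center_offset, dtype=float).reshape(3)

    r_in = inner_diameter_mm / 2.0
    r_out = r_in + (wall_mm if kind == "SHELL" else 0.0)
    half = np.ceil(r_out / s + np.abs(off)).astype(int) + 1
    anchor = half.astype(float) + off
    grids = np.meshgrid(
        *[(np.arange(2 * h + 1) - a) * sp for h, a, sp in zip(half, anchor, s)],
        indexing="ij",
    )
    d2 = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2
    if kind == "FILLED":
        mask = d2 <= r_in**2
    else:
        mask = (d2 > r_in**2) & (d2 <= r_out**2)
    if not mask.any():
        raise DegenerateTemplateError(
            f"{kind} template of diameter {inner_diameter_mm} mm is empty at spacing {s.tolist()}"
        )
    return BinaryTemplate(
        mask=mask,
        anchor=anchor,
        kind=kind,
        inner_diameter_mm=float(inner_diameter_mm),
        wall_mm=float(wall_mm),
        spacing=s,
    )


def _correlate_valid(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    flipped = kernel[::-1, ::-1, ::-1]
    return fftconvolve(volume, flipped, mode="valid")


_TIE_RTOL = 1e-9


def _first_argmax(values: np.ndarray, valid: np.ndarray):
    """First (lexicographic array-order) global maximum among valid
    positions, with a warning when the maximum is not unique."""
    masked = np.where(valid, values, -np.inf)
    vmax = masked.max()
    tol = _TIE_RTOL * max(1.0, abs(vmax))
    ties = np.flatnonzero((masked >= vmax - tol).ravel())
    idx = np.unravel_index(ties[0], values.shape)
    multiple = len(ties) > 1
    return idx, multiple, vmax


def matched_scan(
    volume: np.ndarray,
    template: BinaryTemplate,
    statistic: str = "SUM",
    exclude: np.ndarray | None = None,
) -> MatchedValueSpace:
    """Slide the template across a volume and record the SUM or MEAN of the
    covered voxels at every placement where the template fits.

    ``exclude`` marks voxels (e.g. CT air) that are left out of the MEAN;
    placements whose covered voxels are all excluded are invalid.  When
    several placements share the maximum value, the first in lexicographic
    array order is chosen and a :class:`MultipleMaximaWarning` is issued.
    """
    statistic = statistic.upper()
    if statistic not in ("SUM", "MEAN"):
        raise ValueError(f"unknown statistic {statistic!r}")
    vol = np.asarray(volume, dtype=float)
    tshape = np.array(template.mask.shape)
    vshape = np.array(vol.shape)
    if np.any(vshape < tshape):
        raise TemplateTooLargeError(
            f"template of shape {tuple(tshape)} does not fit in volume of shape {tuple(vshape)}"
        )
    kernel = template.mask.astype(float)
    count = template.count
    warns: list[str] = []

    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        num = _correlate_valid(vol * keep, kernel)
        den = np.rint(_correlate_valid(keep.astype(float), kernel))
        valid = den >= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            means = num / den
        values = means if statistic == "MEAN" else num
        values = np.where(valid, values, -np.inf)
    else:
        sums = _correlate_valid(vol, kernel)
        values = sums if statistic == "SUM" else sums / count
        valid = np.ones(values.shape, dtype=bool)

    if not valid.any():
        raise TemplateTooLargeError("no valid template placement (all covered voxels excluded)")

    idx, multiple, _ = _first_argmax(values, valid)
    if multiple:
        warnings.warn(
            "multiple maxima in matched value space; first one (array order) used",
            MultipleMaximaWarning,
            stacklevel=2,
        )
        warns.append("MultipleMaxima")
    return MatchedValueSpace(
        values=values,
        valid=valid,
        argmax_index=tuple(int(i) for i in idx),
        anchor=template.anchor.copy(),
        warnings=warns,
    )


def _valid_run(valid_line: np.ndarray, m: int) -> tuple:
    """Extent of the contiguous valid run containing index ``m``."""
    lo = m
    while lo - 1 >= 0 and valid_line[lo - 1]:
        lo -= 1
    hi = m
    while hi + 1 < len(valid_line) and valid_line[hi + 1]:
        hi += 1
    return lo, hi


def concave_subset(space: MatchedValueSpace) -> tuple:
    """Largest box around the argmax whose axis profiles through the peak
    are strictly concave down (negative discrete second difference at every
    interior profile point).

    Returns ``(lo, hi)`` inclusive index bounds into ``space.values``.
    Raises :class:`NoConcaveNeighborhoodError` when a profile fails the
    concavity test immediately at the argmax (callers fall back to a 3x3x3
    box with a warning).
    """
    values = space.values
    if values.ndim != 3:
        raise ValueError("concave_subset expects a 3D matched value space")
    m = np.array(space.argmax_index)
    lo = np.empty(3, dtype=int)
    hi = np.empty(3, dtype=int)
    for a in range(3):
        sl = [slice(None)] * 3
        for b in range(3):
            if b != a:
                sl[b] = m[b]
        profile = values[tuple(sl)]
        vline = space.valid[tuple(sl)]
        vlo, vhi = _valid_run(vline, m[a])
        if m[a] - 1 < vlo or m[a] + 1 > vhi:
            raise NoConcaveNeighborhoodError(
                f"argmax at the edge of the valid region along axis {a}"
            )

        def d2(t):
            return profile[t + 1] - 2.0 * profile[t] + profile[t - 1]

        if not d2(m[a]) < 0:
            raise NoConcaveNeighborhoodError(
                f"non-negative curvature at the argmax along axis {a}"
            )
        h = m[a] + 1
        while h <= vhi - 1 and d2(h) < 0:
            h += 1
        l = m[a] - 1
        while l >= vlo + 1 and d2(l) < 0:
            l -= 1
        lo[a], hi[a] = l, h
    return lo, hi


@lru_cache(maxsize=8)
def _quadratic_design(shape: tuple):
    """Design matrix (and its pseudo-inverse) for a full N-variate quadratic
    sampled on an integer grid of the given shape, coordinates centered on
    the grid center.  Cached: the 7^6 perturbation grid reuses it."""
    ndim = len(shape)
    center = (np.array(shape) - 1) / 2.0
    axes = [np.arange(n) - c for n, c in zip(shape, center)]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = [np.ones(int(np.prod(shape)))]
    for a in range(ndim):
        cols.append(grids[a].ravel())
    for a in range(ndim):
        for b in range(a, ndim):
            cols.append((grids[a] * grids[b]).ravel())
    A = np.column_stack(cols)
    pinv = np.linalg.pinv(A)
    return A, pinv, center


def _coeffs_to_gradient_hessian(coeffs: np.ndarray, ndim: int):
    g = coeffs[1 : 1 + ndim]
    H = np.zeros((ndim, ndim))
    k = 1 + ndim
    for a in range(ndim):
        for b in range(a, ndim):
            if a == b:
                H[a, a] = 2.0 * coeffs[k]
            else:
                H[a, b] = H[b, a] = coeffs[k]
            k += 1
    return g, H


def fit_quadratic_vertex(values: np.ndarray, valid: np.ndarray | None = None):
    """Least-squares fit of a full N-variate quadratic to a sampled box and
    its analytic vertex (solving gradient = 0).

    Returns ``(vertex, info)`` with the vertex in the box's own index
    coordinates.  If the fitted Hessian is not negative definite the grid
    argmax is returned instead, with a :class:`NonConcaveFitWarning`
    (``info["warnings"]`` carries the same flags for reporting).
    """
    v = np.asarray(values, dtype=float)
    ndim = v.ndim
    n_terms = 1 + ndim + ndim * (ndim + 1) // 2
    shape = v.shape
    A, pinv, center = _quadratic_design(shape)
    y = v.ravel()

    if valid is not None:
        sel = np.asarray(valid, dtype=bool).ravel()
        if sel.sum() < n_terms:
            raise DegenerateFitError(
                f"{int(sel.sum())} valid samples for {n_terms} quadratic coefficients"
            )
        Asel = A[sel]
        if np.linalg.matrix_rank(Asel) < n_terms:
            raise DegenerateFitError("singular normal equations in quadratic fit")
        coeffs, *_ = np.linalg.lstsq(Asel, y[sel], rcond=None)
    else:
        if y.size < n_terms:
            raise DegenerateFitError(
                f"{y.size} samples for {n_terms} quadratic coefficients"
            )
        if min(shape) < 2:
            raise DegenerateFitError("box must span at least 2 samples per axis")
        coeffs = pinv @ y

    g, H = _coeffs_to_gradient_hessian(coeffs, ndim)
    eigs = np.linalg.eigvalsh(H)
    info = {"coeffs": coeffs, "hessian": H, "eigenvalues": eigs, "warnings": []}
    neg_definite = bool(np.all(eigs < 0))
    info["negative_definite"] = neg_definite
    if not neg_definite:
        warnings.warn(
            "quadratic fit Hessian is not negative definite; using grid argmax",
            NonConcaveFitWarning,
            stacklevel=2,
        )
        info["warnings"].append("NonConcaveFit")
        masked = v if valid is None else np.where(valid, v, -np.inf)
        vertex = np.array(np.unravel_index(np.argmax(masked), shape), dtype=float)
        return vertex, info
    try:
        vertex_centered = np.linalg.solve(H, -g)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - negdef H is invertible
        raise DegenerateFitError("singular Hessian in quadratic fit") from exc
    return vertex_centered + center, info
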