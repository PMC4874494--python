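"""Coarse PET detection of the three largest phantom spheres.

The three largest spheres (37/28/22 mm) are bright enough in any usable
PET reconstruction to be found with a plain filled-sphere matched filter.
Each detection zeroes out exactly the voxels covered by the template at
its argmax before the next scan, so a sphere cannot be found twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TemplateTooLargeError
from .templates import build_template, matched_scan
from .volume_io import ImageVolume

__all__ = ["SphereCenterSet", "estimate_three_largest"]

NEMA_INNER_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
"""Inner diameters of spheres 1..6 of the NEMA NU-2 IQ phantom."""


@dataclass
class SphereCenterSet:
    """Per-sphere center estimates in a named coordinate frame.

    ``centers`` maps sphere index (1..6, 6 = largest) to a fractional voxel
    index or mm world point, depending on ``frame``; ``quality`` records
    whether each center is a coarse ESTIMATE or an ACCURATE localization.
    """

    centers: dict
    frame: str  # PET_VOXEL / CT_VOXEL / PET_WORLD / CT_WORLD
    quality: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def as_array(self, indices=None) -> np.ndarray:
        idx = sorted(self.centers) if indices is None else list(indices)
        return np.array([self.centers[i] for i in idx], dtype=float)


def estimate_three_largest(
    pet: ImageVolume,
    diameters_mm=NEMA_INNER_DIAMETERS_MM,
) -> SphereCenterSet:
    """Estimate PET centers of spheres 6, 5 and 4 by iterated matched
    filtering with zero-out suppression.

    For each sphere (largest first) a filled binary template at the PET
    spacing is scanned over the whole volume with the SUM statistic; the
    argmax voxel is the estimate, the covered voxels are set to zero, and
    the next sphere is sought.  The input volume is not mutated.
    """
    work = pet.voxels.astype(float, copy=True)
    centers: dict = {}
    quality: dict = {}
    warns: list = []
    for sphere_index in (6, 5, 4):
        d = float(diameters_mm[sphere_index - 1])
        template = build_template("FILLED", d, spacing=pet.spacing)
        try:
            space = matched_scan(work, template, statistic="SUM")
        except TemplateTooLargeError as exc:
            raise TemplateTooLargeError(
                f"volume too small for the {d:g} mm sphere template"
            ) from exc
        center = space.center_in_volume()
        centers[sphere_index] = np.asarray(center)
        quality[sphere_index] = "ESTIMATE"
        warns.extend(f"sphere {sphere_index}: {w}" for w in space.warnings)
        # suppress: zero exactly the voxels of the detected template
        lo = np.array(space.argmax_index)
        sl = tuple(slice(l, l + n) for l, n in zip(lo, template.mask.shape))
        region = work[sl]
        region[template.mask] = 0.0
    return SphereCenterSet(centers=centers, frame="PET_VOXEL", quality=quality, warnings=warns)
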