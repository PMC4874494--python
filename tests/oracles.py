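"""Independent brute-force oracles used to pin down expected values.

These are deliberately naive (triple loops, direct enumeration) and share
no code with the implementation they check.
"""

import numpy as np


def enumerate_sphere_voxels(radius_mm, spacing, half_extent, offset=(0.0, 0.0, 0.0)):
    """Count voxel centers within ``radius_mm`` of an anchor by explicit
    triple-loop enumeration.  ``half_extent`` is in voxels per axis."""
    count = 0
    included = []
    for i in range(-half_extent[0], half_extent[0] + 1):
        for j in range(-half_extent[1], half_extent[1] + 1):
            for k in range(-half_extent[2], half_extent[2] + 1):
                d2 = (
                    ((i - offset[0]) * spacing[0]) ** 2
                    + ((j - offset[1]) * spacing[1]) ** 2
                    + ((k - offset[2]) * spacing[2]) ** 2
                )
                if d2 <= radius_mm**2:
                    count += 1
                    included.append((i, j, k))
    return count, included


def enumerate_shell_voxels(r_in_mm, wall_mm, spacing, half_extent):
    """Triple-loop enumeration of the hollow-shell inclusion rule."""
    count = 0
    included = []
    r_out = r_in_mm + wall_mm
    for i in range(-half_extent[0], half_extent[0] + 1):
        for j in range(-half_extent[1], half_extent[1] + 1):
            for k in range(-half_extent[2], half_extent[2] + 1):
                d2 = (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
                if r_in_mm**2 < d2 <= r_out**2:
                    count += 1
                    included.append((i, j, k))
    return count, included


def sliding_window_scan(volume, mask, statistic="SUM", exclude=None):
    """Direct sliding-window matched filter over all placements where the
    mask fits, via explicit loops."""
    vs = volume.shape
    ts = mask.shape
    out_shape = tuple(v - t + 1 for v, t in zip(vs, ts))
    out = np.full(out_shape, -np.inf)
    valid = np.zeros(out_shape, dtype=bool)
    for a in range(out_shape[0]):
        for b in range(out_shape[1]):
            for c in range(out_shape[2]):
                sub = volume[a : a + ts[0], b : b + ts[1], c : c + ts[2]]
                if exclude is not None:
                    keep = mask & ~exclude[a : a + ts[0], b : b + ts[1], c : c + ts[2]]
                    n = keep.sum()
                    if n == 0:
                        continue
                    total = sub[keep].sum()
                    out[a, b, c] = total if statistic == "SUM" else total / n
                else:
                    total = sub[mask].sum()
                    out[a, b, c] = total if statistic == "SUM" else total / mask.sum()
                valid[a, b, c] = True
    return out, valid
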