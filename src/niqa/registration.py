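"""Rigid CT -> PET registration driven by the six-sphere template.

The three coarse PET detections and the three accurate large-sphere CT
centers determine an initial isometry ``Phi_E`` (point-line-plane
construction with branch selection by total distance).  ``Phi_E`` is then
perturbed on a 7^6 grid over six degrees of freedom — three rotations about
the centroid of the mapped centers and three translations, each spanning
+/-3 mm in 1 mm steps (rotation increments are expressed as 1 mm of arc for
the sphere center farthest from the rotation axis).  A six-sphere filled
template is evaluated against the PET volume at every node, a full 6D
quadratic is fitted to the matched values, and its vertex defines the
optimal isometry ``Phi_O``.  Comparing ``Phi_O`` with the header isometry
``Phi_DICOM`` yields the per-sphere misalignment vectors ``D_i`` and their
maximum pairwise angle ``theta_D``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BoundaryMaxWarning,
    BoundaryWarning,
    DegenerateArrangementError,
    DegenerateFitError,
    MappingOutOfBoundsError,
    VertexFarFromMaxWarning,
)
from .pet_coarse import NEMA_INNER_DIAMETERS_MM, SphereCenterSet
from .templates import fit_quadratic_vertex
from .volume_io import ImageVolume, RigidTransform

__all__ = [
    "PerturbationGrid",
    "MisalignmentReport",
    "initial_isometry",
    "build_six_sphere_template",
    "perturbation_search",
    "optimal_isometry",
    "final_pet_centers",
    "misalignment_report",
]

N_STEPS = 3          # grid runs -3..+3 per axis (7 nodes)
TRANS_STEP_MM = 1.0  # translation increment
ARC_STEP_MM = 1.0    # arc length per rotation increment for the farthest sphere


def _frame_from_points(p_origin, p_line, p_plane, tol: float = 1e-6):
    """Right-handed orthonormal frame: axis 1 along origin->line point,
    axis 2 the in-plane perpendicular toward the plane point."""
    u = np.asarray(p_line, dtype=float) - p_origin
    v = np.asarray(p_plane, dtype=float) - p_origin
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= 0 or nv <= 0 or np.linalg.norm(np.cross(u, v)) / (nu * nv) <= tol:
        raise DegenerateArrangementError("sphere centers are collinear or coincident")
    e1 = u / nu
    w = v - (v @ e1) * e1
    e2 = w / np.linalg.norm(w)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _branch_transform(E, F, s1, s2, c6, p6):
    f1 = s1 * F[:, 0]
    f2 = s2 * F[:, 1]
    f3 = np.cross(f1, f2)
    Fb = np.column_stack([f1, f2, f3])
    R = Fb @ E.T
    t = p6 - R @ c6
    return RigidTransform(R, t, label="ESTIMATE")


def initial_isometry(ct_points, pet_points) -> RigidTransform:
    """Initial CT-world -> PET-world isometry ``Phi_E`` from three
    corresponding sphere centers (order: spheres 6, 5, 4).

    The transform (i) maps CT sphere 6 exactly onto the PET estimate of
    sphere 6, (ii) maps the 6-5 line onto the 6-5 line, and (iii) maps the
    6-5-4 plane onto the 6-5-4 plane.  Each of the last two conditions has
    a two-fold symmetry; at each step the branch minimizing the Euclidean
    distance of the mapped point to its PET counterpart is kept.  The
    result is always a proper isometry (no reflection).
    """
    c6, c5, c4 = [np.asarray(p, dtype=float) for p in ct_points]
    p6, p5, p4 = [np.asarray(p, dtype=float) for p in pet_points]
    E = _frame_from_points(c6, c5, c4)
    F = _frame_from_points(p6, p5, p4)
    # step 2: choose the line direction branch by the distance of mapped C5
    cands = {s1: _branch_transform(E, F, s1, +1, c6, p6) for s1 in (+1, -1)}
    s1 = min(cands, key=lambda s: np.linalg.norm(cands[s](c5) - p5))
    # step 3: choose the plane-side branch by the distance of mapped C4
    cands = {s2: _branch_transform(E, F, s1, s2, c6, p6) for s2 in (+1, -1)}
    s2 = min(cands, key=lambda s: np.linalg.norm(cands[s](c4) - p4))
    return _branch_transform(E, F, s1, s2, c6, p6)


def build_six_sphere_template(
    pet: ImageVolume,
    centers_world,
    diameters_mm=NEMA_INNER_DIAMETERS_MM,
) -> np.ndarray:
    """Union of six Binary-Center-Inclusion filled spheres on the PET grid.

    ``centers_world`` are six PET-world points in sphere order 1..6; the
    anchors are in general sub-voxel.  Overlapping spheres are counted
    once.  A sphere entirely outside the volume raises
    :class:`MappingOutOfBoundsError`; a center outside the grid only warns.
    """
    centers = np.asarray(centers_world, dtype=float).reshape(-1, 3)
    shape = np.array(pet.shape)
    mask = np.zeros(pet.shape, dtype=bool)
    for c, d in zip(centers, diameters_mm):
        r = d / 2.0
        cidx = pet.world_to_voxel(c)
        half = r / pet.spacing
        lo = np.floor(cidx - half).astype(int) - 1
        hi = np.ceil(cidx + half).astype(int) + 1
        if np.any(hi < 0) or np.any(lo > shape - 1):
            raise MappingOutOfBoundsError(
                f"sphere of diameter {d} mm mapped entirely outside the PET volume"
            )
        if not pet.contains_index(cidx):
            warnings.warn(
                "mapped sphere center lies outside the PET volume",
                BoundaryWarning,
                stacklevel=2,
            )
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape - 1)
        axes = [np.arange(l, h + 1) for l, h in zip(lo_c, hi_c)]
        grids = np.meshgrid(*[(ax - ci) * s for ax, ci, s in zip(axes, cidx, pet.spacing)], indexing="ij")
        d2 = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2
        sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo_c, hi_c))
        mask[sl] |= d2 <= r * r
    return mask


def _rotation_matrix(theta):
    tx, ty, tz = theta
    cx, sx = np.cos(tx), np.sin(tx)
    cy, sy = np.cos(ty), np.sin(ty)
    cz, sz = np.cos(tz), np.sin(tz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


@dataclass
class PerturbationGrid:
    """6D matched-value space over (theta_x, theta_y, theta_z, dx, dy, dz).

    Node ``n`` along each axis spans -N_STEPS..+N_STEPS; rotations are about
    the centroid of the ``Phi_E``-mapped sphere centers, in world axes.
    """

    values: np.ndarray          # shape (7,)*6
    valid: np.ndarray
    argmax_index: tuple
    theta_steps: np.ndarray     # radians per increment, per rotation axis
    trans_step: float           # mm per translation increment
    centroid: np.ndarray        # rotation origin, PET world mm
    phi_e: RigidTransform
    warnings: list = field(default_factory=list)

    def node_transform(self, node) -> RigidTransform:
        """Rigid transform ``Phi_E`` composed with the perturbation at a
        (possibly fractional) 6D grid node."""
        node = np.asarray(node, dtype=float)
        theta = (node[:3] - N_STEPS) * self.theta_steps
        delta = (node[3:] - N_STEPS) * self.trans_step
        Rv = _rotation_matrix(theta)
        rot = Rv @ self.phi_e.rotation
        trans = Rv @ (self.phi_e.translation - self.centroid) + self.centroid + delta
        return RigidTransform(rot, trans, label="OPTIMAL")


def _gather_neighborhood(pet: ImageVolume, center_world, radius_mm):
    """In-grid voxel center offsets (mm, relative to ``center_world``) and
    values within ``radius_mm`` of the center."""
    cidx = pet.world_to_voxel(center_world)
    shape = np.array(pet.shape)
    half = radius_mm / pet.spacing
    lo = np.maximum(np.floor(cidx - half).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(cidx + half).astype(int) + 1, shape - 1)
    if np.any(hi < lo):
        return np.empty((0, 3)), np.empty(0)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grids = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    world = pet.voxel_to_world(idx)
    P = world - np.asarray(center_world, dtype=float)
    keep = np.einsum("ij,ij->i", P, P) <= radius_mm * radius_mm
    sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo, hi))
    vals = pet.voxels[sl].astype(float).ravel()
    return P[keep], vals[keep]


def perturbation_search(
    phi_e: RigidTransform,
    ct_centers_world,
    pet: ImageVolume,
    diameters_mm=NEMA_INNER_DIAMETERS_MM,
    step_mm: float = TRANS_STEP_MM,
) -> PerturbationGrid:
    """Evaluate the six-sphere matched filter at all 7^6 perturbations of
    ``Phi_E`` and record the template sums.

    The implementation reuses per-sphere voxel neighborhoods: for every
    sphere the PET voxels that could possibly be covered under any
    perturbation are gathered once, split into an always-covered core and
    an uncertain shell, and only the shell is re-tested per node.  The
    resulting values are identical (to floating-point round-off) to
    rebuilding the full six-sphere template at every node and summing.

    Nodes at which any sphere's analytic ball extends past the voxel-center
    grid are flagged invalid (their sums cover only in-grid voxels) and are
    excluded from the quadratic fit.
    """
    ct_centers = np.asarray(ct_centers_world, dtype=float).reshape(-1, 3)
    n_spheres = len(ct_centers)
    radii = np.asarray(diameters_mm, dtype=float)[:n_spheres] / 2.0
    mapped0 = phi_e(ct_centers)
    centroid = mapped0.mean(axis=0)
    rel = mapped0 - centroid

    # rotation increment: 1 mm of arc for the sphere farthest from each axis
    theta_steps = np.empty(3)
    for a in range(3):
        others = [b for b in range(3) if b != a]
        r_perp = np.sqrt((rel[:, others] ** 2).sum(axis=1)).max()
        if r_perp <= 0:
            raise DegenerateArrangementError("mapped sphere centers coincide with their centroid")
        theta_steps[a] = step_mm * (ARC_STEP_MM / TRANS_STEP_MM) / r_perp

    nodes = np.arange(-N_STEPS, N_STEPS + 1)
    rot_nodes = np.array(list(itertools.product(nodes, nodes, nodes)))  # 343 x 3
    trans_nodes = rot_nodes.astype(float) * step_mm                     # 343 x 3
    n_rot = len(rot_nodes)

    # rotated-center offsets u[rot, sphere, 3]
    rots = np.stack([_rotation_matrix(n * theta_steps) for n in rot_nodes])
    u = np.einsum("rab,sb->rsa", rots, rel) + centroid - mapped0[None, :, :]

    t_norm2 = np.einsum("kj,kj->k", trans_nodes, trans_nodes)
    values = np.zeros((n_rot, n_rot))
    valid = np.ones((n_rot, n_rot), dtype=bool)
    shape = np.array(pet.shape)

    # pairwise overlap is geometrically impossible for the NEMA layout; the
    # per-sphere sum decomposition below relies on it
    d_max_all = np.abs(u).max() + np.sqrt(t_norm2.max())
    dists = np.linalg.norm(ct_centers[:, None] - ct_centers[None, :], axis=2)
    rsum = radii[:, None] + radii[None, :] + 2 * d_max_all
    np.fill_diagonal(rsum, 0.0)
    if np.any(dists < rsum):
        raise DegenerateArrangementError(
            "spheres may overlap under perturbation; layout is not NEMA-like"
        )

    for i in range(n_spheres):
        r = radii[i]
        ui = u[:, i, :]                        # 343 x 3
        d_max = np.linalg.norm(ui, axis=1).max() + np.sqrt(t_norm2.max())
        P, v = _gather_neighborhood(pet, mapped0[i], r + d_max)
        if P.shape[0] == 0:
            raise MappingOutOfBoundsError(
                f"sphere {i + 1} mapped entirely outside the PET volume"
            )
        pn2 = np.einsum("ij,ij->i", P, P)
        pd = np.sqrt(pn2)
        core = pd <= r - d_max
        shell = ~core & (pd <= r + d_max)
        base = float(v[core].sum())
        Ps, vs = P[shell], v[shell]
        a_s = pn2[shell]
        C = -2.0 * (Ps @ trans_nodes.T)        # Nshell x 343

        # node validity: analytic ball must stay inside the voxel-center grid
        cidx0 = pet.world_to_voxel(mapped0[i])
        M = (pet.orientation / pet.spacing[None, :]).T  # world delta -> index delta
        half = r / pet.spacing
        for rj in range(n_rot):
            didx = (u[rj, i] + trans_nodes) @ M.T + cidx0   # 343 x 3
            ok = np.all(didx - half >= 0.0, axis=1) & np.all(didx + half <= shape - 1, axis=1)
            valid[rj] &= ok

        for rj in range(n_rot):
            urj = ui[rj]
            w = a_s - 2.0 * (Ps @ urj) + urj @ urj          # |P - u|^2
            thr = r * r - (t_norm2 + 2.0 * (trans_nodes @ urj))
            inside = (w[:, None] + C) <= thr[None, :]
            values[rj] += vs @ inside
        values += base

    values = values.reshape((7, 7, 7) + (7, 7, 7))
    valid = valid.reshape((7, 7, 7) + (7, 7, 7))
    if not valid.any():
        raise MappingOutOfBoundsError("no valid perturbation node")
    warns: list[str] = []
    if not valid.all():
        warnings.warn(
            "some perturbation nodes map spheres out of bounds; excluded from the fit",
            BoundaryWarning,
            stacklevel=2,
        )
        warns.append("InvalidNodes")
    masked = np.where(valid, values, -np.inf)
    argmax = tuple(int(k) for k in np.unravel_index(np.argmax(masked), masked.shape))
    return PerturbationGrid(
        values=values,
        valid=valid,
        argmax_index=argmax,
        theta_steps=theta_steps,
        trans_step=step_mm,
        centroid=centroid,
        phi_e=phi_e,
        warnings=warns,
    )


FIT_HALF_WIDTH = 2  # 6D quadratic is fitted over argmax +/- 2 nodes


def optimal_isometry(grid: PerturbationGrid) -> tuple:
    """Fit a 6D quadratic to the perturbation values around the peak and
    compose its vertex with ``Phi_E`` to obtain the optimal isometry
    ``Phi_O``.

    The quadratic is fitted over the box of +/-2 grid indices around the
    argmax (clipped to the grid): the matched-value surface is close to
    quadratic only near its peak, and fitting the full +/-3-increment range
    measurably biases the vertex.  Two indices is also the scale at which a
    vertex is deemed untrustworthy (``VertexFarFromMax``).

    Returns ``(phi_o, warns)``.  Warnings: ``BoundaryMax`` when the grid
    argmax sits on a face of the search range (the true optimum may lie
    beyond +/-3 mm), ``VertexFarFromMax`` when the fitted vertex strays
    more than two indices from the argmax, and ``NonConcaveFit`` /
    ``DegenerateFit`` fallbacks to the argmax node.
    """
    warns = list(grid.warnings)
    argmax = np.array(grid.argmax_index)
    if np.any(argmax == 0) or np.any(argmax == 2 * N_STEPS):
        warnings.warn(
            "matched-value maximum lies on the boundary of the search space",
            BoundaryMaxWarning,
            stacklevel=2,
        )
        warns.append("BoundaryMax")
    lo = np.maximum(argmax - FIT_HALF_WIDTH, 0)
    hi = np.minimum(argmax + FIT_HALF_WIDTH, 2 * N_STEPS)
    sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo, hi))
    box_valid = grid.valid[sl]
    valid_arg = None if box_valid.all() else box_valid
    try:
        vertex, info = fit_quadratic_vertex(grid.values[sl], valid=valid_arg)
        vertex = vertex + lo
        warns.extend(info["warnings"])
    except DegenerateFitError:
        warns.append("DegenerateFit")
        vertex = argmax.astype(float)
    if np.any(np.abs(vertex - argmax) > 2.0):
        warnings.warn(
            "quadratic vertex is more than two indices from the grid maximum",
            VertexFarFromMaxWarning,
            stacklevel=2,
        )
        warns.append("VertexFarFromMax")
    phi_o = grid.node_transform(vertex)
    return phi_o, warns


def refine_isometry(
    phi_e: RigidTransform,
    ct_centers_world,
    pet: ImageVolume,
    diameters_mm=NEMA_INNER_DIAMETERS_MM,
    max_passes: int = 4,
    converged_mm: float = 0.25,
) -> tuple:
    """Perturbation search with re-centering until the peak is central.

    The integer-voxel coarse PET estimates can tilt the initial isometry
    enough that spheres on the far side of the ring start more than the
    +/-3 mm search range away from their true positions, and a peak near
    the edge of the fit box biases the quadratic vertex.  The search is
    therefore re-run centered on the current optimum until the grid argmax
    is the central node (peak symmetric in the fit box) or consecutive
    optima agree within ``converged_mm`` at every sphere, up to
    ``max_passes`` times; each pass is the same 7^6 search and quadratic
    fit.  Warnings of the final pass are reported, plus
    ``RecenteredSearch`` when more than one pass was needed.

    Returns ``(phi_o, warns, grid)`` with ``grid`` from the final pass.
    """
    centers = np.asarray(ct_centers_world, dtype=float).reshape(-1, 3)
    phi = phi_e
    passes = 0
    prev_mapped = None
    for _ in range(max_passes):
        grid = perturbation_search(phi, centers, pet, diameters_mm)
        phi, warns = optimal_isometry(grid)
        passes += 1
        mapped = phi(centers)
        if grid.argmax_index == (N_STEPS,) * 6:
            break
        if prev_mapped is not None and np.linalg.norm(mapped - prev_mapped, axis=1).max() < converged_mm:
            break
        prev_mapped = mapped
    if passes > 1:
        warns = warns + ["RecenteredSearch"]
    return phi, warns, grid


def final_pet_centers(
    phi_o: RigidTransform,
    ct_centers_world,
    pet: ImageVolume | None = None,
) -> SphereCenterSet:
    """Accurate PET sphere centers ``C_P,i,A = Phi_O(C_C,i,A)`` (PET world
    mm; deterministic for identical inputs)."""
    ct_centers = np.asarray(ct_centers_world, dtype=float).reshape(-1, 3)
    mapped = phi_o(ct_centers)
    centers = {i + 1: mapped[i] for i in range(len(mapped))}
    quality = {i: "ACCURATE" for i in centers}
    return SphereCenterSet(centers=centers, frame="PET_WORLD", quality=quality)


@dataclass
class MisalignmentReport:
    """Per-sphere displacement between the optimal and header isometries.

    Carries raw values only — deciding whether a misalignment is
    significant is left to the reader of the report.  A coherent direction
    (small ``theta_d``) with large norms suggests a rigid PET/CT offset;
    large norms with a wide angular spread would point at scaling issues
    instead.
    """

    d_vectors: np.ndarray   # 6 x 3 mm, PET world frame
    norms: np.ndarray
    theta_d_deg: float
    notes: list = field(default_factory=list)


def misalignment_report(
    phi_o: RigidTransform,
    phi_dicom: RigidTransform,
    ct_centers_world,
) -> MisalignmentReport:
    """``D_i = Phi_O(C_C,i,A) - Phi_DICOM(C_C,i,A)`` and the maximum
    pairwise angle ``theta_D`` between the six displacement vectors."""
    ct_centers = np.asarray(ct_centers_world, dtype=float).reshape(-1, 3)
    d = phi_o(ct_centers) - phi_dicom(ct_centers)
    norms = np.linalg.norm(d, axis=1)
    notes: list[str] = []
    nonzero = d[norms > 1e-9]
    if len(nonzero) < len(d):
        notes.append("zero displacement vectors excluded from the angle computation")
    if len(nonzero) < 2:
        notes.append("fewer than two nonzero displacement vectors; theta_D reported as 0")
        theta = 0.0
    else:
        unit = nonzero / np.linalg.norm(nonzero, axis=1, keepdims=True)
        cosines = np.clip(unit @ unit.T, -1.0, 1.0)
        iu = np.triu_indices(len(unit), k=1)
        theta = float(np.degrees(np.arccos(cosines[iu]).max()))
    return MisalignmentReport(d_vectors=d, norms=norms, theta_d_deg=theta, notes=notes)
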