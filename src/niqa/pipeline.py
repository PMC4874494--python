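"""End-to-end phantom analysis: PET coarse detection through ROI report.

The ten steps: (1) coarse PET detection of the three largest spheres,
(2) header mapping of those estimates into CT, (3-4) accurate CT
localization of the large spheres with air handling and wall learning,
(5-6) hexagonal extrapolation and small-sphere CT localization, (7) the
initial three-point isometry, (8-9) the six-degree-of-freedom template
search for the optimal isometry and the final PET centers, and (10) the
sphere ROIs and their statistics.  The whole chain is analytic and
deterministic: identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ct_localize, pet_coarse, registration, roi_report
from .pet_coarse import NEMA_INNER_DIAMETERS_MM
from .volume_io import ImageVolume, check_orthogonal, dicom_isometry, load_series

logger = logging.getLogger("niqa")

__all__ = ["PipelineConfig", "PipelineResult", "run", "run_volumes", "render_report"]


@dataclass
class PipelineConfig:
    """Inputs and toggles for one analysis run.

    Exactly one of ``ct_path`` / ``ct_geometry_path`` drives the CT stage:
    either a CT series is localized automatically, or six known CT sphere
    centers (mm, CT world frame; e.g. from a one-off manual segmentation of
    a sealed long-lived phantom) are loaded and CT localization is skipped.
    ``air_detection=False`` disables bubble compensation, which exists to
    quantify what the compensation buys.
    """

    pet_path: str | Path | None = None
    ct_path: str | Path | None = None
    ct_geometry_path: str | Path | None = None
    out_dir: str | Path | None = None
    diameters_mm: tuple = NEMA_INNER_DIAMETERS_MM
    wall_mm: float = 1.0
    air_detection: bool = True
    sd_ddof: int = 1


@dataclass
class PipelineResult:
    centers_ct_world: np.ndarray        # 6 x 3 mm
    centers_pet_world: np.ndarray       # 6 x 3 mm
    centers_pet_voxel: np.ndarray       # 6 x 3 fractional indices
    phi_e: registration.RigidTransform
    phi_o: registration.RigidTransform
    phi_dicom: registration.RigidTransform
    roi: roi_report.ROIStats
    misalignment: registration.MisalignmentReport
    wall_model: ct_localize.WallModel | None
    warnings: list = field(default_factory=list)


def _load_fixed_geometry(path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    centers = np.asarray(data["centers_ct_world_mm"] if isinstance(data, dict) else data, dtype=float)
    if centers.shape != (6, 3):
        raise ValueError("fixed CT geometry must contain six (x, y, z) centers in mm")
    return centers


def run_volumes(
    pet: ImageVolume,
    ct: ImageVolume | None = None,
    ct_centers_world: np.ndarray | None = None,
    diameters_mm: tuple = NEMA_INNER_DIAMETERS_MM,
    wall_mm: float = 1.0,
    air_detection: bool = True,
) -> PipelineResult:
    """Run the analysis on in-memory volumes.

    Supply either a CT volume (automatic localization) or six known CT
    sphere centers in mm (fixed-geometry mode).
    """
    if (ct is None) == (ct_centers_world is None):
        raise ValueError("provide exactly one of ct / ct_centers_world")
    warns: list[str] = []

    # slice orthogonality is verified for every loaded volume before any
    # analysis step runs
    check_orthogonal(pet)
    if ct is not None:
        check_orthogonal(ct)

    logger.info("step 1: coarse PET detection of spheres 6, 5, 4")
    coarse = pet_coarse.estimate_three_largest(pet, diameters_mm)
    warns.extend(coarse.warnings)
    pet_est_world = {i: pet.voxel_to_world(coarse.centers[i]) for i in (6, 5, 4)}

    if ct is not None:
        phi_dicom = dicom_isometry(ct, pet)
        logger.info("step 2: mapping PET estimates into the CT volume")
        inv = phi_dicom.inverse()
        ct_est = {i: ct.world_to_voxel(inv(pet_est_world[i])) for i in (6, 5, 4)}
        logger.info("steps 3-6: accurate CT localization of all six spheres")
        centers_vox, wall_model, results = ct_localize.localize_spheres(
            ct, ct_est, diameters_mm, wall_mm=wall_mm, air_detection=air_detection
        )
        for i in sorted(results):
            warns.extend(f"CT sphere {i}: {w}" for w in results[i].warnings)
        centers_ct_world = np.array([ct.voxel_to_world(centers_vox[i]) for i in range(1, 7)])
    else:
        phi_dicom = dicom_isometry(pet, pet)
        wall_model = None
        logger.info("steps 2-6 skipped: fixed CT geometry supplied")
        centers_ct_world = np.asarray(ct_centers_world, dtype=float).reshape(6, 3)

    logger.info("step 7: initial three-point isometry")
    phi_e = registration.initial_isometry(
        [centers_ct_world[5], centers_ct_world[4], centers_ct_world[3]],
        [pet_est_world[6], pet_est_world[5], pet_est_world[4]],
    )
    logger.info("steps 8-9: six-degree-of-freedom perturbation search")
    phi_o, reg_warns, _ = registration.refine_isometry(
        phi_e, centers_ct_world, pet, diameters_mm
    )
    warns.extend(reg_warns)
    final = registration.final_pet_centers(phi_o, centers_ct_world)
    centers_pet_world = final.as_array(range(1, 7))
    centers_pet_voxel = np.array([pet.world_to_voxel(c) for c in centers_pet_world])

    logger.info("step 10: sphere ROIs and statistics")
    masks = roi_report.sphere_rois(pet, centers_pet_world, diameters_mm)
    roi = roi_report.roi_stats(pet, masks)
    mis = registration.misalignment_report(phi_o, phi_dicom, centers_ct_world)

    return PipelineResult(
        centers_ct_world=centers_ct_world,
        centers_pet_world=centers_pet_world,
        centers_pet_voxel=centers_pet_voxel,
        phi_e=phi_e,
        phi_o=phi_o,
        phi_dicom=phi_dicom,
        roi=roi,
        misalignment=mis,
        wall_model=wall_model,
        warnings=warns,
    )


def run(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load series, analyze, write reports."""
    if (config.ct_path is None) == (config.ct_geometry_path is None):
        raise ValueError("exactly one of ct_path / ct_geometry_path is required")
    if config.pet_path is None:
        raise ValueError("pet_path is required")
    pet = load_series(config.pet_path)
    ct = load_series(config.ct_path) if config.ct_path is not None else None
    centers = (
        _load_fixed_geometry(config.ct_geometry_path)
        if config.ct_geometry_path is not None
        else None
    )
    result = run_volumes(
        pet,
        ct=ct,
        ct_centers_world=centers,
        diameters_mm=config.diameters_mm,
        wall_mm=config.wall_mm,
        air_detection=config.air_detection,
    )
    if config.out_dir is not None:
        write_reports(result, config.out_dir, pet)
    return result


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def render_report(result: PipelineResult, pet: ImageVolume | None = None) -> str:
    """Human-readable analysis report (stable formatting)."""
    lines = ["NEMA NU-2 IQ phantom automated sphere analysis", ""]
    lines.append("Sphere centers (PET world frame, mm):")
    for i in range(6):
        c = result.centers_pet_world[i]
        v = result.centers_pet_voxel[i]
        lines.append(
            f"  sphere {i + 1}: ({_fmt(c[0])}, {_fmt(c[1])}, {_fmt(c[2])})"
            f"  voxel ({_fmt(v[0])}, {_fmt(v[1])}, {_fmt(v[2])})"
        )
    lines.append("")
    lines.append("ROI statistics (diameters = physical inner diameters):")
    for i, st in sorted(result.roi.per_sphere.items()):
        lines.append(
            f"  sphere {i}: mean {_fmt(st['mean'])}  max {_fmt(st['max'])}  voxels {st['count']}"
        )
    lines.append(
        f"  six-sphere union: mean {_fmt(result.roi.union_mean)}"
        f"  max {_fmt(result.roi.union_max)}  voxels {result.roi.union_count}"
    )
    lines.append("")
    lines.append("Misalignment vs DICOM header (D_i = Phi_O(C_i) - Phi_DICOM(C_i), mm):")
    for i in range(6):
        d = result.misalignment.d_vectors[i]
        lines.append(
            f"  sphere {i + 1}: ({_fmt(d[0])}, {_fmt(d[1])}, {_fmt(d[2])})"
            f"  |D| = {_fmt(result.misalignment.norms[i])}"
        )
    lines.append(f"  theta_D (max pairwise angle) = {_fmt(result.misalignment.theta_d_deg)} deg")
    for note in result.misalignment.notes:
        lines.append(f"  note: {note}")
    lines.append("")
    if result.wall_model is not None:
        lines.append(
            f"Plastic wall model: mu_PSW = {_fmt(result.wall_model.mu_psw)} HU"
            f" over {result.wall_model.n_wall_voxels} voxels"
        )
    if result.warnings:
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in result.warnings)
    else:
        lines.append("Warnings: none")
    return "\n".join(lines) + "\n"


def _result_payload(result: PipelineResult) -> dict:
    return {
        "centers_ct_world_mm": result.centers_ct_world.tolist(),
        "centers_pet_world_mm": result.centers_pet_world.tolist(),
        "centers_pet_voxel": result.centers_pet_voxel.tolist(),
        "roi": {
            "per_sphere": {str(k): v for k, v in sorted(result.roi.per_sphere.items())},
            "union_mean": result.roi.union_mean,
            "union_max": result.roi.union_max,
            "union_count": result.roi.union_count,
        },
        "misalignment": {
            "d_vectors_mm": result.misalignment.d_vectors.tolist(),
            "norms_mm": result.misalignment.norms.tolist(),
            "theta_d_deg": result.misalignment.theta_d_deg,
            "notes": result.misalignment.notes,
        },
        "phi_o": {
            "rotation": result.phi_o.rotation.tolist(),
            "translation_mm": result.phi_o.translation.tolist(),
        },
        "mu_psw_hu": None if result.wall_model is None else result.wall_model.mu_psw,
        "warnings": result.warnings,
    }


def write_reports(result: PipelineResult, out_dir, pet: ImageVolume | None = None) -> dict:
    """Write report.txt, report.tsv and report.json; byte-identical for
    identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    txt = out / "report.txt"
    txt.write_text(render_report(result, pet))

    rows = ["sphere\tcx_mm\tcy_mm\tcz_mm\troi_mean\troi_max\troi_voxels\tDx_mm\tDy_mm\tDz_mm\tDnorm_mm"]
    for i in range(6):
        c = result.centers_pet_world[i]
        st = result.roi.per_sphere[i + 1]
        d = result.misalignment.d_vectors[i]
        rows.append(
            "\t".join(
                [str(i + 1)]
                + [_fmt(v) for v in c]
                + [_fmt(st["mean"]), _fmt(st["max"]), str(st["count"])]
                + [_fmt(v) for v in d]
                + [_fmt(result.misalignment.norms[i])]
            )
        )
    (out / "report.tsv").write_text("\n".join(rows) + "\n")

    payload = _result_payload(result)
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
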