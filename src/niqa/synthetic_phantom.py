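"""Synthetic NEMA NU-2-like PET/CT phantom pairs with exact ground truth.

The generator emulates the image-quality phantom as the localization
pipeline sees it: six hollow plastic spheres (inner diameters 10-37 mm,
1 mm walls) at the vertices of a hexagon in descending-diameter order,
inside a water-filled cylindrical body; CT shows water/plastic/air in
Hounsfield units, PET shows hot spheres over a warm background.  Optional
air bubbles sit against the top of a sphere's interior, and an optional
rigid misalignment displaces the physical PET content relative to what the
headers claim — exactly the anomaly the misalignment report is meant to
expose.

Rendering is geometric: voxels are supersampled and box-averaged so that
the 1 mm walls and sphere boundaries get correct partial-volume fractions,
then blurred with a Gaussian (standing in for reconstruction smoothing)
and optionally degraded with additive Gaussian noise.  Output volumes are
quantized to the integer storage grid a scanner would use (1 HU for CT, a
fixed activity step for PET), which also makes the DICOM round trip exact.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import gaussian_filter

from .volume_io import ImageVolume, RigidTransform

__all__ = [
    "Bubble",
    "PhantomConfig",
    "PhantomTruth",
    "render_noiseless",
    "generate",
    "add_noise",
    "write_series",
    "write_truth",
    "load_truth",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# axial stack with identity in-plane orientation: axis0 = +z, axis1 = +y,
# axis2 = +x
_AXIAL_ORIENTATION = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])

_TOP_DIRECTION = np.array([0.0, -1.0, 0.0])  # anterior: where bubbles float


@dataclass(frozen=True)
class Bubble:
    """An air bubble resting against the top of a sphere's interior."""

    sphere_index: int
    diameter_mm: float
    offset_mm: float | None = None  # distance of bubble center from sphere
    # center along the top direction; default: touching the inner wall


@dataclass
class PhantomConfig:
    """Geometry, contrast, noise and acquisition settings for one phantom.

    Defaults reproduce the standard NEMA NU-2 layout imaged at typical
    clinical PET/CT settings: CT 1.37 x 1.37 mm in-plane / 2.5 mm slices,
    PET 2.73 x 2.73 x 3.27 mm voxels with 6 mm FWHM post-smoothing, hot
    spheres at 4:1 over background.  Spacings and shapes are in array order
    (slice, row, column) = (z, y, x).
    """

    inner_diameters_mm: tuple = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    wall_mm: float = 1.0
    hexagon_radius_mm: float = 57.2
    hexagon_angle0_deg: float = 97.0  # polar angle of sphere 6 in the x-y
    # plane; deliberately off-axis — real phantoms land on the bed at an
    # arbitrary rotation, and an exactly axis-aligned ring would create
    # unphysical mirror-symmetric ties in the matched value spaces
    winding: str = "standard"         # standard: clockwise descending; mirrored: counter-clockwise
    center_mm: tuple = (1.1, -0.7, 0.6)  # slightly off-grid, like a real
    # phantom on the bed; an exactly grid-centered ring would tie mirror
    # placements across the sphere plane
    body_radius_mm: float = 112.0  # large enough that the k=2 search box of
    # the 37 mm sphere stays inside the water body, as in the torso phantom
    body_half_height_mm: float = 40.0
    hu_water: float = 0.0
    hu_plastic: float = 120.0
    hu_air: float = -1000.0
    pet_background: float = 1.0
    sphere_ratio: float = 4.0         # sphere : background activity
    ct_spacing: tuple = (2.5, 1.37, 1.37)
    ct_shape: tuple = (36, 170, 170)
    pet_spacing: tuple = (3.27, 2.73, 2.73)
    pet_shape: tuple = (32, 88, 88)
    ct_blur_fwhm_mm: float = 0.7
    pet_blur_fwhm_mm: float = 6.0
    ct_noise_sd_hu: float = 15.0
    pet_noise_sd: float = 0.1         # absolute, in activity units (10% of background)
    noise_order: str = "before_blur"  # noise enters before the smoothing
    # kernel, giving the spatially correlated texture of post-filtered
    # reconstructions; "after_blur" adds white noise to the smoothed image
    bubbles: tuple = ()
    misalignment: RigidTransform | None = None
    supersample_ct: int = 4
    supersample_pet: int = 3
    seed: int = 0

    @property
    def ct_quant(self) -> float:
        return 1.0

    @property
    def pet_quant(self) -> float:
        return self.pet_background / 5000.0


@dataclass
class PhantomTruth:
    """Exact ground truth emitted with every generated pair."""

    centers_ct_world: np.ndarray   # 6 x 3 mm, sphere order 1..6
    centers_pet_world: np.ndarray  # 6 x 3 mm (misalignment applied)
    misalignment: RigidTransform
    bubble_masks: dict             # sphere index -> CT boolean mask
    ct_noiseless: ImageVolume
    pet_noiseless: ImageVolume
    config: PhantomConfig


def sphere_centers(config: PhantomConfig) -> np.ndarray:
    """True sphere centers 1..6 (mm, phantom/CT world frame)."""
    step = -60.0 if config.winding == "standard" else 60.0
    c = np.asarray(config.center_mm, dtype=float)
    centers = np.empty((6, 3))
    for i in range(6):  # sphere 6 at angle0, then 5, 4, ... around the ring
        sphere = 6 - i
        ang = np.radians(config.hexagon_angle0_deg + i * step)
        centers[sphere - 1] = c + config.hexagon_radius_mm * np.array(
            [np.cos(ang), np.sin(ang), 0.0]
        )
    return centers


def _validate(config: PhantomConfig):
    centers = sphere_centers(config)
    radii = np.asarray(config.inner_diameters_mm) / 2.0 + config.wall_mm
    ring = [6, 5, 4, 3, 2, 1, 6]
    for a, b in zip(ring[:-1], ring[1:]):
        gap = np.linalg.norm(centers[a - 1] - centers[b - 1]) - radii[a - 1] - radii[b - 1]
        if gap <= 0:
            raise ValueError(
                f"invalid geometry: spheres {a} and {b} overlap at hexagon radius "
                f"{config.hexagon_radius_mm} mm"
            )
    for bub in config.bubbles:
        r_in = config.inner_diameters_mm[bub.sphere_index - 1] / 2.0
        rb = bub.diameter_mm / 2.0
        off = bub.offset_mm if bub.offset_mm is not None else r_in - rb
        if rb + abs(off) > r_in + 1e-9:
            raise ValueError(
                f"invalid geometry: bubble does not fit inside sphere {bub.sphere_index}"
            )


def _grid(shape, spacing, center) -> tuple:
    """Origin and orientation of an axial grid centered on ``center``."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    half = (shape - 1) / 2.0 * spacing
    origin = np.asarray(center, dtype=float) - _AXIAL_ORIENTATION @ half
    return origin, _AXIAL_ORIENTATION.copy()


def _sub_offsets(ss: int, spacing) -> np.ndarray:
    """Supersampling offsets (mm, world x/y/z) within one voxel."""
    frac = (np.arange(ss) + 0.5) / ss - 0.5
    oz, oy, ox = np.meshgrid(frac * spacing[0], frac * spacing[1], frac * spacing[2], indexing="ij")
    return np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)


def _body_fraction(volume_shape, origin, spacing, config: PhantomConfig, transform: RigidTransform, ss: int) -> np.ndarray:
    """Per-voxel coverage fraction of the (possibly rigidly moved) body
    cylinder, supersampled, computed slice by slice to bound memory."""
    nz, ny, nx = volume_shape
    axis_dir = transform.rotation @ np.array([0.0, 0.0, 1.0])
    body_center = transform(np.asarray(config.center_mm, dtype=float))
    offs = _sub_offsets(ss, spacing)
    ys = origin[1] + np.arange(ny) * spacing[1]
    xs = origin[0] + np.arange(nx) * spacing[2]
    # note: with the axial orientation, axis1 steps along world y and axis2
    # along world x; origin is the world position of voxel (0, 0, 0)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    frac = np.empty(volume_shape)
    for k in range(nz):
        z = origin[2] + k * spacing[0]
        base = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)], axis=1)
        acc = np.zeros(gx.size)
        for o in offs:
            p = base + o - body_center
            ax = p @ axis_dir
            rad2 = np.einsum("ij,ij->i", p, p) - ax**2
            inside = (rad2 <= config.body_radius_mm**2) & (
                np.abs(ax) <= config.body_half_height_mm
            )
            acc += inside
        frac[k] = (acc / len(offs)).reshape(ny, nx)
    return frac


def _paint_spheres(
    volume: np.ndarray,
    grid_vol: ImageVolume,
    config: PhantomConfig,
    transform: RigidTransform,
    ss: int,
    inner_value,
    shell_value,
    bubble_value,
    background_value,
):
    """Overwrite voxels near each (transformed) sphere with the partial-
    volume mixture of interior / wall / bubble / surrounding material."""
    centers = transform(sphere_centers(config))
    bubbles = {b.sphere_index: b for b in config.bubbles}
    top = transform.rotation @ _TOP_DIRECTION
    offs = _sub_offsets(ss, grid_vol.spacing)
    shape = np.array(grid_vol.shape)
    for i in range(1, 7):
        r_in = config.inner_diameters_mm[i - 1] / 2.0
        r_out = r_in + config.wall_mm
        c = centers[i - 1]
        cidx = grid_vol.world_to_voxel(c)
        half = (r_out + 1.0) / grid_vol.spacing
        lo = np.maximum(np.floor(cidx - half).astype(int), 0)
        hi = np.minimum(np.ceil(cidx + half).astype(int), shape - 1)
        axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
        gz, gy, gx = np.meshgrid(*axes, indexing="ij")
        idx = np.stack([gz.ravel(), gy.ravel(), gx.ravel()], axis=1).astype(float)
        world = grid_vol.voxel_to_world(idx)
        bub = bubbles.get(i)
        if bub is not None:
            rb = bub.diameter_mm / 2.0
            off = bub.offset_mm if bub.offset_mm is not None else r_in - rb
            bc = c + off * top
        f_inner = np.zeros(len(world))
        f_shell = np.zeros(len(world))
        f_bub = np.zeros(len(world))
        for o in offs:
            p = world + o - c
            d2 = np.einsum("ij,ij->i", p, p)
            in_outer = d2 <= r_out**2
            in_inner = d2 <= r_in**2
            if bub is not None:
                q = world + o - bc
                in_bub = (np.einsum("ij,ij->i", q, q) <= rb**2) & in_inner
            else:
                in_bub = np.zeros(len(world), dtype=bool)
            f_bub += in_bub
            f_inner += in_inner & ~in_bub
            f_shell += in_outer & ~in_inner
        n = len(offs)
        f_inner /= n
        f_shell /= n
        f_bub /= n
        mix = (
            f_inner * inner_value
            + f_shell * shell_value
            + f_bub * bubble_value
            + (1.0 - f_inner - f_shell - f_bub) * background_value
        )
        sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo, hi))
        volume[sl] = mix.reshape(volume[sl].shape)


def _bubble_masks(config: PhantomConfig, ct: ImageVolume) -> dict:
    masks: dict = {}
    centers = sphere_centers(config)
    for b in config.bubbles:
        r_in = config.inner_diameters_mm[b.sphere_index - 1] / 2.0
        rb = b.diameter_mm / 2.0
        off = b.offset_mm if b.offset_mm is not None else r_in - rb
        bc = centers[b.sphere_index - 1] + off * _TOP_DIRECTION
        shape = np.array(ct.shape)
        axes = [np.arange(n) for n in shape]
        cidx = ct.world_to_voxel(bc)
        half = rb / ct.spacing
        lo = np.maximum(np.floor(cidx - half).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(cidx + half).astype(int) + 1, shape - 1)
        mask = np.zeros(ct.shape, dtype=bool)
        axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
        grids = np.meshgrid(*[(ax - ci) * s for ax, ci, s in zip(axes, cidx, ct.spacing)], indexing="ij")
        d2 = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2
        sl = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo, hi))
        mask[sl] = d2 <= rb * rb
        masks[b.sphere_index] = mask
    return masks


def _blur(volume: np.ndarray, fwhm_mm: float, spacing, mode: str) -> np.ndarray:
    if fwhm_mm <= 0:
        return volume
    sigma = fwhm_mm * _FWHM_TO_SIGMA / np.asarray(spacing, dtype=float)
    return gaussian_filter(volume, sigma=sigma, mode=mode)


def render_noiseless(config: PhantomConfig) -> PhantomTruth:
    """Render the blurred, noise-free CT and PET volumes plus ground truth.

    This is the expensive geometric step; noisy realizations are produced
    cheaply on top of it with :func:`add_noise`.
    """
    _validate(config)
    identity = RigidTransform.identity(label="TRUTH")
    misalign = config.misalignment if config.misalignment is not None else identity

    # ---- CT (phantom frame; headers and physics agree for CT) ----
    # grids are centered on the world origin; the phantom sits wherever
    # config.center_mm puts it (off-grid by default, like a real scan)
    ct_origin, orient = _grid(config.ct_shape, config.ct_spacing, (0.0, 0.0, 0.0))
    ct_vol = ImageVolume(
        voxels=np.zeros(config.ct_shape),
        spacing=config.ct_spacing,
        origin=ct_origin,
        orientation=orient,
        modality="CT",
    )
    frac = _body_fraction(
        config.ct_shape, ct_origin, np.asarray(config.ct_spacing, dtype=float),
        config, identity, config.supersample_ct,
    )
    ct = config.hu_air + (config.hu_water - config.hu_air) * frac
    ct_vol.voxels = ct
    _paint_spheres(
        ct_vol.voxels, ct_vol, config, identity, config.supersample_ct,
        inner_value=config.hu_water, shell_value=config.hu_plastic,
        bubble_value=config.hu_air, background_value=config.hu_water,
    )
    bubble_masks = _bubble_masks(config, ct_vol)
    ct_vol.voxels = _blur(ct_vol.voxels, config.ct_blur_fwhm_mm, ct_vol.spacing, mode="nearest")

    # ---- PET (physical content displaced by the misalignment; the header
    # geometry below claims perfect alignment) ----
    pet_origin, _ = _grid(config.pet_shape, config.pet_spacing, (0.0, 0.0, 0.0))
    pet_vol = ImageVolume(
        voxels=np.zeros(config.pet_shape),
        spacing=config.pet_spacing,
        origin=pet_origin,
        orientation=orient,
        modality="PET",
    )
    frac = _body_fraction(
        config.pet_shape, pet_origin, np.asarray(config.pet_spacing, dtype=float),
        config, misalign, config.supersample_pet,
    )
    bg = config.pet_background
    hot = config.sphere_ratio * bg
    pet = bg * frac
    pet_vol.voxels = pet
    _paint_spheres(
        pet_vol.voxels, pet_vol, config, misalign, config.supersample_pet,
        inner_value=hot, shell_value=0.0, bubble_value=0.0, background_value=bg,
    )
    pet_vol.voxels = _blur(pet_vol.voxels, config.pet_blur_fwhm_mm, pet_vol.spacing, mode="constant")

    centers_ct = sphere_centers(config)
    return PhantomTruth(
        centers_ct_world=centers_ct,
        centers_pet_world=misalign(centers_ct),
        misalignment=misalign,
        bubble_masks=bubble_masks,
        ct_noiseless=ct_vol,
        pet_noiseless=pet_vol,
        config=config,
    )


def add_noise(
    truth: PhantomTruth,
    rng: np.random.Generator,
) -> tuple:
    """One seeded noisy (and quantized) realization of a rendered phantom.

    Returns ``(ct, pet)`` :class:`ImageVolume` pairs.  Additive Gaussian
    noise enters before the smoothing kernel by default (the blur is
    linear, so this equals blurring the noisy unsmoothed image), giving
    the spatially correlated texture of post-filtered reconstructions;
    ``noise_order='after_blur'`` adds white noise to the smoothed image.
    """
    cfg = truth.config

    def realize(vol: ImageVolume, sd: float, fwhm: float, quant: float, mode: str) -> ImageVolume:
        data = vol.voxels
        if sd > 0:
            noise = rng.normal(0.0, sd, size=data.shape)
            if cfg.noise_order == "before_blur":
                data = data + _blur(noise, fwhm, vol.spacing, mode=mode)
            else:
                data = data + noise
        data = np.rint(data / quant) * quant
        return ImageVolume(
            voxels=data, spacing=vol.spacing, origin=vol.origin,
            orientation=vol.orientation, modality=vol.modality,
        )

    ct = realize(truth.ct_noiseless, cfg.ct_noise_sd_hu, cfg.ct_blur_fwhm_mm, cfg.ct_quant, "nearest")
    pet = realize(truth.pet_noiseless, cfg.pet_noise_sd, cfg.pet_blur_fwhm_mm, cfg.pet_quant, "constant")
    return ct, pet


def generate(config: PhantomConfig) -> tuple:
    """Render a phantom and return ``(ct, pet, truth)`` with seeded noise.

    The same seed always yields bit-identical volumes.
    """
    truth = render_noiseless(config)
    rng = np.random.default_rng(config.seed)
    ct, pet = add_noise(truth, rng)
    return ct, pet, truth


_SOP_CLASS = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "PET": "1.2.840.10008.5.1.4.1.1.128",
}


def write_series(
    volume: ImageVolume,
    path,
    rescale_slope: float = 1.0,
    rescale_intercept: float = 0.0,
) -> list:
    """Write a volume as a one-file-per-slice DICOM series.

    Pixel data are stored as signed 16-bit with the given rescale
    slope/intercept; pass the generator's quantization step as the slope so
    the write -> load round trip reproduces the voxel array exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    frame_uid = generate_uid()
    study_uid = generate_uid()
    stored = np.rint((volume.voxels - rescale_intercept) / rescale_slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise ValueError("rescale slope/intercept do not fit the data into int16")
    stored = stored.astype(np.int16)
    files = []
    row_dir = volume.orientation[:, 2]
    col_dir = volume.orientation[:, 1]
    for k in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _SOP_CLASS.get(volume.modality, _SOP_CLASS["CT"])
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "PT" if volume.modality == "PET" else volume.modality
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [float(v) for v in np.concatenate([row_dir, col_dir])]
        ds.ImagePositionPatient = [float(v) for v in volume.voxel_to_world((k, 0, 0))]
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[2])]
        ds.SliceThickness = float(volume.spacing[0])
        ds.Rows, ds.Columns = int(volume.shape[1]), int(volume.shape[2])
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = float(rescale_slope)
        ds.RescaleIntercept = float(rescale_intercept)
        ds.PixelData = stored[k].tobytes()
        fname = path / f"slice_{k:04d}.dcm"
        ds.save_as(str(fname), enforce_file_format=True)
        files.append(fname)
    return files


def write_truth(truth: PhantomTruth, path) -> Path:
    """JSON ground-truth sidecar for a written phantom pair."""
    path = Path(path)
    payload = {
        "centers_ct_world_mm": truth.centers_ct_world.tolist(),
        "centers_pet_world_mm": truth.centers_pet_world.tolist(),
        "misalignment": {
            "rotation": truth.misalignment.rotation.tolist(),
            "translation": truth.misalignment.translation.tolist(),
        },
        "inner_diameters_mm": list(truth.config.inner_diameters_mm),
        "wall_mm": truth.config.wall_mm,
        "bubbles": [
            {"sphere_index": b.sphere_index, "diameter_mm": b.diameter_mm, "offset_mm": b.offset_mm}
            for b in truth.config.bubbles
        ],
        "seed": truth.config.seed,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_truth(path) -> dict:
    data = json.loads(Path(path).read_text())
    data["centers_ct_world_mm"] = np.asarray(data["centers_ct_world_mm"])
    data["centers_pet_world_mm"] = np.asarray(data["centers_pet_world_mm"])
    data["misalignment"] = RigidTransform(
        np.asarray(data["misalignment"]["rotation"]),
        np.asarray(data["misalignment"]["translation"]),
        label="TRUTH",
    )
    return data
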