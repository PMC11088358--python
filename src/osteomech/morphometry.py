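"""μCT-style voxel morphometry of tensile specimens.

Pipeline: Gaussian filtering (sigma = 1 voxel, kernel radius 1), single-level
TMD threshold segmentation at 550 mgHA/cm^3, largest-connected-component
cleanup (26-connectivity for bone), and derivation of bone volume, mean
cross-sectional area (bone volume over axial specimen length), TMD mean/SD
over bone voxels, and internal porosity (enclosed pore space, 6-connected).
A phantom generator provides specimens with planted ground truth.

Images are plain 3-D arrays of TMD in mgHA/cm^3 with isotropic voxel
spacing in μm; the specimen long axis is the last array axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelImage",
    "MorphometryResult",
    "PhantomSpec",
    "preprocess",
    "segment",
    "porosity_of_mask",
    "morphometry",
    "engineering_stress",
    "generate_phantom",
    "read_image",
    "write_image",
]

DEFAULT_THRESHOLD = 550.0  # mgHA/cm^3


@dataclass(frozen=True)
class VoxelImage:
    """3-D TMD image (mgHA/cm^3) with isotropic voxel spacing (μm)."""

    values: np.ndarray
    spacing: float = 4.9

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.spacing <= 0.0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class MorphometryResult:
    bv: float          # bone volume, mm^3
    mean_area: float   # mm^2 (= bv / axial specimen length)
    length: float      # axial extent of the bone mask, mm
    tmd_mean: float    # mgHA/cm^3 over bone voxels
    tmd_std: float
    porosity: float    # enclosed-pore fraction of the solid body


class NoBoneFoundError(ValueError):
    """Raised when thresholding produces an empty mask."""


def preprocess(image: VoxelImage) -> VoxelImage:
    """Gaussian smoothing with sigma = 1 voxel, kernel truncated at radius 1."""
    filtered = ndimage.gaussian_filter(image.values, sigma=1.0, radius=1)
    return VoxelImage(filtered, image.spacing)


def segment(image: VoxelImage, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold at ``threshold`` and keep the largest 26-connected component."""
    mask = image.values >= threshold
    if not mask.any():
        raise NoBoneFoundError(f"no voxel reaches the {threshold} mgHA/cm^3 threshold")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return mask


def porosity_of_mask(mask: np.ndarray) -> float:
    """Enclosed-pore fraction: cavity volume / (bone + cavity volume).

    Pore space is 6-connected background; components reaching the image
    border are exterior, not pores.
    """
    filled = ndimage.binary_fill_holes(mask)
    pores = int(filled.sum() - mask.sum())
    solid = int(filled.sum())
    return pores / solid if solid else 0.0


def morphometry(mask: np.ndarray, image: VoxelImage,
                spacing: float | None = None) -> MorphometryResult:
    """Bone volume, mean cross-sectional area, TMD statistics, porosity."""
    if not mask.any():
        raise NoBoneFoundError("empty bone mask")
    spacing = spacing or image.spacing
    voxel_mm = spacing * 1e-3
    bv = float(mask.sum()) * voxel_mm**3
    axial = np.flatnonzero(mask.any(axis=(0, 1)))
    length = (axial[-1] - axial[0] + 1) * voxel_mm
    tmd = image.values[mask]
    return MorphometryResult(
        bv=bv,
        mean_area=bv / length,
        length=length,
        tmd_mean=float(tmd.mean()),
        tmd_std=float(tmd.std(ddof=1)) if tmd.size > 1 else 0.0,
        porosity=porosity_of_mask(mask),
    )


def engineering_stress(force_n, mean_area_mm2: float):
    """Engineering stress (MPa) = force (N) / mean cross-sectional area (mm^2)."""
    if mean_area_mm2 <= 0.0:
        raise ValueError("mean_area must be positive")
    return np.asarray(force_n, dtype=float) / mean_area_mm2


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic rod specimen with planted pores and a correlated TMD field."""

    shape: tuple = (40, 40, 120)     # voxels; long axis last
    spacing: float = 4.9             # μm
    margin: int = 4                  # empty border around the solid body, voxels
    n_pores: int = 0
    pore_radius: tuple = (2.0, 4.0)  # voxel radius range, uniform
    tmd_mean: float = 1045.0         # mgHA/cm^3
    tmd_sd: float = 152.0            # voxel-level TMD SD after spatial correlation
    corr_sigma: float = 2.0          # spatial correlation length of the TMD field, voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) <= 2 * self.margin:
            raise ValueError("margin too large for the requested shape")
        if self.n_pores < 0 or self.tmd_sd < 0:
            raise ValueError("n_pores and tmd_sd must be >= 0")


def generate_phantom(spec: PhantomSpec):
    """Build a phantom image; returns ``(VoxelImage, truth)``.

    ``truth`` records the planted porosity (pore voxels over solid-body
    voxels) and the realized TMD mean/SD of the bone voxels.  Pores are
    spheres placed fully inside the body so they remain enclosed cavities.
    Raises if the requested pore volume exceeds the solid volume.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    m = spec.margin
    body = np.zeros(spec.shape, dtype=bool)
    body[m:nx - m, m:ny - m, m:nz - m] = True

    pores = np.zeros_like(body)
    if spec.n_pores:
        xs, ys, zs = np.indices(spec.shape)
        r_max = spec.pore_radius[1]
        expected_pore_vol = spec.n_pores * 4.0 / 3.0 * np.pi * np.mean(spec.pore_radius) ** 3
        if expected_pore_vol >= body.sum():
            raise ValueError("requested pore volume exceeds the solid volume")
        for _ in range(spec.n_pores):
            r = rng.uniform(*spec.pore_radius)
            pad = int(np.ceil(r)) + 1
            cx = rng.uniform(m + pad, nx - m - pad)
            cy = rng.uniform(m + pad, ny - m - pad)
            cz = rng.uniform(m + pad, nz - m - pad)
            pores |= (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= r * r

    bone = body & ~pores
    values = np.zeros(spec.shape)
    if spec.tmd_sd > 0.0:
        noise = rng.standard_normal(spec.shape)
        noise = ndimage.gaussian_filter(noise, sigma=spec.corr_sigma)
        noise *= spec.tmd_sd / noise.std()
    else:
        noise = np.zeros(spec.shape)
    values[bone] = spec.tmd_mean + noise[bone]

    truth = {
        "porosity": float(pores[body].sum() / body.sum()),
        "tmd_mean": float(values[bone].mean()) if bone.any() else float("nan"),
        "tmd_std": float(values[bone].std(ddof=1)) if bone.sum() > 1 else 0.0,
        "bv_mm3": float(bone.sum()) * (spec.spacing * 1e-3) ** 3,
    }
    return VoxelImage(values, spec.spacing), truth


def read_image(path) -> VoxelImage:
    """Read a MetaImage/NRRD volume (TMD in mgHA/cm^3) via SimpleITK."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing_mm = img.GetSpacing()[0]
    # SimpleITK arrays come back (z, y, x); put the long axis last
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelImage(np.asarray(values, dtype=float), spacing_mm * 1e3)


def write_image(image: VoxelImage, path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(image.values.transpose(2, 1, 0))
    s = image.spacing * 1e-3
    img.SetSpacing((s, s, s))
    sitk.WriteImage(img, str(path))
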