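"""3D volume containers and I/O.

Volumes are isotropic 3D scalar grids indexed (z, y, x) with the voxel edge
length carried in millimetres.  Readers exist for NIfTI, MetaImage and TIFF
stacks; writers mirror them so round-trips are exact.  A binary mask on the
same lattice delineates the volume of interest (VOI) — here the trabecular
compartment after cortical bone has been masked out upstream.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "extract_voi",
    "downsample_block",
]

#: Relative tolerance used when deciding whether stored spacings are isotropic.
_ISO_RTOL = 1e-4


@dataclass
class ImageVolume:
    """A 3D grayscale grid with isotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities in arbitrary units; cast to float64 on creation.
    spacing_mm : float
        Isotropic voxel edge length in millimetres.
    origin : ndarray of 3 floats, optional
        Physical position of voxel (0, 0, 0) in mm.  Informational only.
    """

    data: np.ndarray
    spacing_mm: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.spacing_mm = float(self.spacing_mm)
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm ** 3


@dataclass
class MaskVolume:
    """A binary grid on the same lattice as the volume it masks."""

    data: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D")
        self.spacing_mm = float(self.spacing_mm)
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.spacing_mm ** 3


def _check_isotropic(spacing_xyz: np.ndarray) -> float:
    s = np.asarray(spacing_xyz, dtype=float)
    if not np.allclose(s, s[0], rtol=_ISO_RTOL, atol=0):
        raise ValueError(f"anisotropic voxel spacing {tuple(s)} is not supported")
    return float(s[0])


def _detect_format(path: str) -> str:
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        return "nifti"
    if low.endswith((".mha", ".mhd")):
        return "metaimage"
    if low.endswith((".tif", ".tiff")) or os.path.isdir(path):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from path: {path!r}")


def read_volume(
    path: str,
    fmt: str | None = None,
    spacing_mm: float | None = None,
) -> ImageVolume:
    """Read a 3D volume with spacing metadata.

    Parameters
    ----------
    path : str
        File (``.nii``/``.nii.gz``, ``.mha``/``.mhd``, multi-page ``.tif``) or
        a directory of per-slice TIFFs (sorted by name, one slice each).
    fmt : {"nifti", "metaimage", "tiff_stack"}, optional
        Override format detection by extension.
    spacing_mm : float, optional
        Voxel spacing override.  Required for TIFF stacks, which carry no
        trustworthy spacing metadata; for NIfTI/MetaImage it replaces the
        stored value.

    Raises
    ------
    ValueError
        If the stored spacing is anisotropic, or a TIFF stack is read without
        an explicit spacing.
    """
    fmt = fmt or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        # nibabel is (x, y, z); internal order is (z, y, x)
        data = np.transpose(data, (2, 1, 0))
        stored = _check_isotropic(img.header.get_zooms()[:3])
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img).astype(np.float64)  # already (z,y,x)
        stored = _check_isotropic(img.GetSpacing())
    elif fmt == "tiff_stack":
        import tifffile

        if os.path.isdir(path):
            slices = sorted(
                glob.glob(os.path.join(path, "*.tif"))
                + glob.glob(os.path.join(path, "*.tiff"))
            )
            if not slices:
                raise ValueError(f"no TIFF slices found in {path!r}")
            data = np.stack([tifffile.imread(s) for s in slices]).astype(np.float64)
        else:
            data = tifffile.imread(path).astype(np.float64)
            if data.ndim == 2:
                data = data[None]
        stored = None
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if spacing_mm is None:
        if stored is None:
            raise ValueError(
                "TIFF stacks carry no voxel spacing; pass spacing_mm explicitly"
            )
        spacing_mm = stored
    return ImageVolume(data, spacing_mm)


def write_volume(path: str, volume: ImageVolume | MaskVolume, fmt: str | None = None) -> None:
    """Write a volume or mask; masks are written as uint8 {0,1}."""
    fmt = fmt or _detect_format(path)
    data = volume.data
    if isinstance(volume, MaskVolume):
        data = data.astype(np.uint8)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([volume.spacing_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine), path)
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing((volume.spacing_mm,) * 3)
        sitk.WriteImage(img, path)
    elif fmt == "tiff_stack":
        import tifffile

        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_mask(path: str, fmt: str | None = None, spacing_mm: float | None = None) -> MaskVolume:
    """Read a binary mask; any nonzero voxel is treated as set."""
    vol = read_volume(path, fmt=fmt, spacing_mm=spacing_mm)
    return MaskVolume(vol.data != 0, vol.spacing_mm)


def extract_voi(volume: ImageVolume, mask: MaskVolume) -> tuple[ImageVolume, MaskVolume]:
    """Crop a volume to the bounding box of its VOI mask.

    Returns the cropped volume together with the cropped mask; downstream
    statistics must be restricted to the mask, which flags the voxels that
    belong to the trabecular compartment.

    Raises
    ------
    ValueError
        On shape/spacing mismatch or an empty mask.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    if not np.isclose(volume.spacing_mm, mask.spacing_mm, rtol=_ISO_RTOL):
        raise ValueError("volume and mask spacing differ")
    if mask.n_voxels == 0:
        raise ValueError("VOI mask is empty")
    idx = np.nonzero(mask.data)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return (
        ImageVolume(volume.data[sl], volume.spacing_mm, volume.origin),
        MaskVolume(mask.data[sl], mask.spacing_mm),
    )


def downsample_block(volume: ImageVolume, factor: int) -> ImageVolume:
    """Block-average downsampling by an integer factor.

    Each output voxel is the arithmetic mean of the corresponding
    ``factor**3`` block; the spacing is multiplied by ``factor``.  Trailing
    voxels that do not fill a complete block are dropped — block-mean
    semantics without invented intensities.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return ImageVolume(volume.data.copy(), volume.spacing_mm, volume.origin)
    if min(volume.shape) < factor:
        raise ValueError("every dimension must be >= factor")
    nz, ny, nx = (s // factor for s in volume.shape)
    d = volume.data[: nz * factor, : ny * factor, : nx * factor]
    d = d.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    return ImageVolume(d, volume.spacing_mm * factor, volume.origin)
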