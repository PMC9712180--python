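"""Volume preparation: I/O, isotropic resampling, HU re-segmentation, discretization.

CT intensities are Hounsfield units (HU). The preparation chain mirrors the
standard radiomics workflow:

1. resample volume and lung mask to an isotropic grid (trilinear image
   interpolation; linear mask interpolation thresholded at 0.5),
2. re-segment the mask to the HU window of interest (default [-1000, 200],
   bounds inclusive),
3. discretize HU to integer gray levels with a fixed bin size (default
   50 HU), anchored at the lower re-segmentation bound so levels are
   comparable across subjects and acquisition domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: default HU re-segmentation window
HU_RANGE: tuple[float, float] = (-1000.0, 200.0)
#: default fixed bin size in HU
BIN_WIDTH_HU: float = 50.0


class GeometryError(ValueError):
    """Volume/mask geometry mismatch or degenerate geometry."""


class EmptyMaskError(ValueError):
    """A mask became empty during preprocessing."""


@dataclass
class Volume:
    """A 3D scalar grid of HU values with voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """A binary region-of-interest mask aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, vol: Volume, subject: str = "<unknown>") -> None:
        if self.shape != vol.shape or not np.allclose(self.spacing, vol.spacing):
            raise GeometryError(
                f"subject {subject}: mask geometry {self.shape}@{self.spacing} does not "
                f"match volume {vol.shape}@{vol.spacing}"
            )


@dataclass
class DiscretizedRoi:
    """Integer gray levels over ROI voxels; 0 outside the ROI.

    Levels run from 1 to ``n_bins`` where ``n_bins = ceil((high - low) / bin_width)``
    over the full re-segmentation window, independent of the values actually
    present in the ROI.
    """

    gray_levels: np.ndarray  # int grid, 0 = background sentinel
    n_bins: int
    bin_width_hu: float
    range_hu: tuple[float, float]
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.gray_levels = np.asarray(self.gray_levels, dtype=np.int32)
        inside = self.gray_levels[self.gray_levels > 0]
        if inside.size and inside.max() > self.n_bins:
            raise ValueError("gray level exceeds n_bins")

    @property
    def mask(self) -> np.ndarray:
        return self.gray_levels > 0

    def n_voxels(self) -> int:
        return int((self.gray_levels > 0).sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return Volume(data, spacing)
    if path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        # SimpleITK is (x,y,z) in spacing but (z,y,x) in array; transpose back
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
        spacing = tuple(float(s) for s in img.GetSpacing())
        return Volume(data, spacing)
    raise ValueError(f"unsupported volume format: {path}")


def read_mask(path) -> RoiMask:
    vol = read_volume(path)
    return RoiMask(vol.data > 0.5, vol.spacing)


def write_volume(vol: Volume, path) -> None:
    """Write as NIfTI with a diagonal affine built from the spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: RoiMask, path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def merge_masks(left: RoiMask, right: RoiMask) -> RoiMask:
    """Merge independently contoured lungs into a single ROI (voxelwise OR)."""
    if left.shape != right.shape:
        raise GeometryError("lung masks have different shapes")
    return RoiMask(left.data | right.data, left.spacing, left.origin)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _resample_grid(data: np.ndarray, spacing, target_mm: float, order: int) -> np.ndarray:
    old_shape = data.shape
    new_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(old_shape, spacing)
    )
    # sample at the centers of the new voxels, expressed in old-index units
    coords = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        data.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )


def resample_isotropic(
    vol: Volume, mask: RoiMask, target_mm: float, subject: str = "<unknown>"
) -> tuple[Volume, RoiMask]:
    """Resample volume and mask to isotropic ``target_mm`` spacing.

    The image is interpolated trilinearly; the mask is interpolated linearly
    as a float field and thresholded at 0.5.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    mask.check_aligned(vol, subject)
    if tuple(np.round(vol.spacing, 9)) == (target_mm,) * 3:
        return vol, mask
    new_data = _resample_grid(vol.data, vol.spacing, target_mm, order=1)
    new_mask = _resample_grid(mask.data.astype(np.float64), mask.spacing, target_mm, order=1)
    out_mask = new_mask >= 0.5
    if not out_mask.any():
        raise EmptyMaskError(f"subject {subject}: mask empty after resampling")
    t = (float(target_mm),) * 3
    return Volume(new_data, t, vol.origin), RoiMask(out_mask, t, mask.origin)


# ---------------------------------------------------------------------------
# Re-segmentation and discretization
# ---------------------------------------------------------------------------

def resegment(
    vol: Volume,
    mask: RoiMask,
    low: float = HU_RANGE[0],
    high: float = HU_RANGE[1],
    subject: str = "<unknown>",
) -> RoiMask:
    """Restrict the mask to voxels with HU in [low, high] (inclusive)."""
    if low >= high:
        raise ValueError("re-segmentation range must satisfy low < high")
    mask.check_aligned(vol, subject)
    keep = mask.data & (vol.data >= low) & (vol.data <= high)
    if not keep.any():
        raise EmptyMaskError(f"subject {subject}: mask empty after re-segmentation")
    return RoiMask(keep, mask.spacing, mask.origin)


def discretize_fbs(
    vol: Volume,
    mask: RoiMask,
    bin_width: float = BIN_WIDTH_HU,
    range_low: float = HU_RANGE[0],
    range_high: float = HU_RANGE[1],
    subject: str = "<unknown>",
) -> DiscretizedRoi:
    """Fixed-bin-size discretization anchored at ``range_low``.

    level(x) = floor((x - range_low) / bin_width) + 1, with the top edge of
    the re-segmentation window clamped into the last bin. Bins are
    [edge, edge) except the last, which is closed.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    mask.check_aligned(vol, subject)
    roi_vals = vol.data[mask.data]
    if roi_vals.size and roi_vals.min() < range_low:
        raise ValueError(
            f"subject {subject}: ROI voxel below {range_low} HU — run re-segmentation first"
        )
    n_bins = int(np.ceil((range_high - range_low) / bin_width))
    levels = np.zeros(vol.shape, dtype=np.int32)
    lv = np.floor((vol.data[mask.data] - range_low) / bin_width).astype(np.int32) + 1
    np.clip(lv, 1, n_bins, out=lv)
    levels[mask.data] = lv
    return DiscretizedRoi(levels, n_bins, float(bin_width), (float(range_low), float(range_high)), mask.spacing)


def prepare_subject(
    vol: Volume,
    mask: RoiMask,
    target_mm: float,
    hu_range: tuple[float, float] = HU_RANGE,
    bin_width: float = BIN_WIDTH_HU,
    subject: str = "<unknown>",
) -> tuple[Volume, RoiMask, DiscretizedRoi]:
    """Full preparation chain: resample -> resegment -> discretize."""
    rvol, rmask = resample_isotropic(vol, mask, target_mm, subject)
    smask = resegment(rvol, rmask, hu_range[0], hu_range[1], subject)
    droi = discretize_fbs(rvol, smask, bin_width, hu_range[0], hu_range[1], subject)
    return rvol, smask, droi
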