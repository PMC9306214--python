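"""Volume/label data model, file I/O and the input-space <-> expanded-space mapping.

Conventions
-----------
* Arrays are ordered ``(z, y, x)``; every slice index is a z index.
* Coordinates are 0-based; intervals are half-open.
* ``spacing`` is stored as ``(s_xy, s_xy, s_z)`` micrometres per voxel, i.e.
  the in-plane spacing twice followed by the slice step.  In expanded space
  the stored z entry is the *effective* spacing ``s_z / expansion_factor``.
* Label 0 is background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional, Tuple

import numpy as np
import SimpleITK as sitk
import tifffile

Space = Literal["input", "expanded"]
MaskKind = Literal["M3D", "M3DE", "M2DE", "seeds"]

__all__ = [
    "VolumeStack",
    "LabelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "collapse_to_input_space",
    "expand_labels_nn",
    "relabel_consecutive",
]


def _check_spacing(spacing: Tuple[float, float, float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing}")
    return spacing


def _check_factor(factor: int) -> int:
    factor = int(factor)
    if factor <= 0 or factor % 2 == 0:
        raise ValueError(f"expansion factor must be a positive odd integer, got {factor}")
    return factor


@dataclass
class VolumeStack:
    """A 3D intensity volume with voxel spacing and space tag."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]  # (s_xy, s_xy, s_z)
    space: Space = "input"
    expansion_factor: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.expansion_factor = _check_factor(self.expansion_factor)
        if self.space == "input" and self.expansion_factor != 1:
            raise ValueError("expansion_factor must be 1 in input space")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing_zyx(self) -> Tuple[float, float, float]:
        s_xy, _, s_z = self.spacing
        return (s_z, s_xy, s_xy)

    @property
    def z_anisotropy(self) -> float:
        """s_z / s_xy on the current grid (1.0 means isotropic)."""
        return self.spacing[2] / self.spacing[0]

    def with_voxels(self, voxels: np.ndarray, **changes) -> "VolumeStack":
        return replace(self, voxels=voxels, **changes)


@dataclass
class LabelVolume:
    """Non-negative integer instance segmentation; 0 is background."""

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    space: Space = "input"
    expansion_factor: int = 1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)
        self.expansion_factor = _check_factor(self.expansion_factor)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def z_anisotropy(self) -> float:
        return self.spacing[2] / self.spacing[0]

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.label_ids().size)

    def with_labels(self, labels: np.ndarray, **changes) -> "LabelVolume":
        return replace(self, labels=labels, **changes)


@dataclass
class BinaryMask:
    """Boolean volume holding a nuclei mask or seeds."""

    voxels: np.ndarray
    mask_kind: MaskKind
    spacing: Tuple[float, float, float]
    space: Space = "expanded"
    expansion_factor: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.voxels.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.expansion_factor = _check_factor(self.expansion_factor)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def z_anisotropy(self) -> float:
        return self.spacing[2] / self.spacing[0]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SITK_EXT = {".nrrd", ".nhdr", ".nii", ".mha", ".mhd"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii.gz") or path.suffix == ".nii"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar_spacing(path: Path) -> Optional[Tuple[float, float, float]]:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "spacing_um" in meta:
            sx, sy, sz = meta["spacing_um"]
            return (float(sx), float(sy), float(sz))
    return None


def _read_any(path, spacing_override):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
        spacing = _read_sidecar_spacing(path) or spacing_override
        if spacing is None:
            raise ValueError(f"spacing unavailable for {path}: no sidecar JSON and no override")
    elif path.suffix.lower() in _SITK_EXT or _is_nifti(path):
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        sx, sy, sz = img.GetSpacing()      # (x, y, z)
        spacing = spacing_override or (float(sx), float(sy), float(sz))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if arr.ndim != 3:
        raise ValueError(f"{path} does not contain a 3D volume (shape {arr.shape})")
    return arr, _check_spacing(spacing)


def read_volume(path, spacing_override: Optional[Tuple[float, float, float]] = None,
                space: Space = "input", expansion_factor: int = 1) -> VolumeStack:
    """Read a multi-page TIFF / NRRD / NIfTI intensity stack.

    Spacing comes from the image header (NRRD/NIfTI) or from a sidecar JSON
    ``{"spacing_um": [sx, sy, sz]}`` next to a TIFF; ``spacing_override``
    wins for TIFF files lacking a sidecar and replaces header values when
    given for ITK formats.
    """
    arr, spacing = _read_any(path, spacing_override)
    return VolumeStack(arr, spacing, space=space, expansion_factor=expansion_factor)


def write_volume(vs: VolumeStack, path) -> None:
    path = Path(path)
    sx, _, sz = vs.spacing
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), vs.voxels, photometric='minisblack')
        _sidecar_path(path).write_text(json.dumps({"spacing_um": [sx, sx, sz]}))
    else:
        img = sitk.GetImageFromArray(vs.voxels)
        img.SetSpacing((sx, sx, sz))
        sitk.WriteImage(img, str(path))


def read_labels(path, spacing_override: Optional[Tuple[float, float, float]] = None,
                space: Space = "input", expansion_factor: int = 1) -> LabelVolume:
    arr, spacing = _read_any(path, spacing_override)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path} holds {arr.dtype} voxels; label volumes must be integer")
    return LabelVolume(arr.astype(np.int64), spacing, space=space,
                       expansion_factor=expansion_factor)


def write_labels(lv: LabelVolume, path, wide: bool = False) -> None:
    """Store labels losslessly (uint16 by default, uint32 with ``wide=True``)."""
    dtype = np.uint32 if wide else np.uint16
    max_label = int(lv.labels.max()) if lv.labels.size else 0
    if max_label > np.iinfo(dtype).max:
        raise ValueError(
            f"max label {max_label} exceeds {dtype().dtype.name} range; pass wide=True"
        )
    out = lv.with_labels(lv.labels.astype(dtype))
    path = Path(path)
    sx, _, sz = lv.spacing
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), out.labels, photometric='minisblack')
        _sidecar_path(path).write_text(json.dumps({"spacing_um": [sx, sx, sz]}))
    else:
        img = sitk.GetImageFromArray(out.labels)
        img.SetSpacing((sx, sx, sz))
        sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Space mapping
# ---------------------------------------------------------------------------

def _nn_resize_slice(sl: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """2D nearest-neighbour resize preserving label values."""
    H, W = shape
    h, w = sl.shape
    yi = np.minimum((np.arange(H) + 0.5) * h / H, h - 1).astype(np.int64)
    xi = np.minimum((np.arange(W) + 0.5) * w / W, w - 1).astype(np.int64)
    return sl[np.ix_(yi, xi)]


def collapse_to_input_space(lv: LabelVolume, original_xy: Tuple[int, int],
                            factor: int) -> LabelVolume:
    """Map an expanded-space segmentation back to the input grid.

    Keeps every ``factor``-th slice starting at index 0 (the slices that
    coincide with original slices), then, if the requested in-plane size
    differs from the current one, resizes each slice with 2D
    nearest-neighbour interpolation.  No new label values are introduced.
    """
    factor = _check_factor(factor)
    if lv.space != "expanded":
        raise ValueError("collapse_to_input_space expects an expanded-space volume")
    if factor != lv.expansion_factor:
        raise ValueError(
            f"factor {factor} does not match the volume's expansion factor "
            f"{lv.expansion_factor}"
        )
    sub = lv.labels[::factor]
    H, W = original_xy
    if (H, W) != sub.shape[1:]:
        sub = np.stack([_nn_resize_slice(sl, (H, W)) for sl in sub])
    else:
        sub = sub.copy()
    s_xy, _, s_z = lv.spacing
    # undo both the z expansion and any xy rescale
    new_sxy = s_xy * lv.shape[2] / W
    return LabelVolume(sub, (new_sxy, new_sxy, s_z * factor), space="input",
                       expansion_factor=1)


def expand_labels_nn(lv: LabelVolume, factor: int) -> LabelVolume:
    """Nearest-neighbour z expansion of a label volume (test transport).

    Output slice ``k`` copies input slice ``round(k / factor)`` clamped to the
    stack; original slices land at ``k % factor == 0``.
    """
    factor = _check_factor(factor)
    if lv.space != "input":
        raise ValueError("expand_labels_nn expects an input-space volume")
    Z = lv.shape[0]
    src = np.minimum(np.round(np.arange(Z * factor) / factor).astype(np.int64), Z - 1)
    s_xy, _, s_z = lv.spacing
    return LabelVolume(lv.labels[src], (s_xy, s_xy, s_z / factor),
                       space="expanded", expansion_factor=factor)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Rename the positive labels to 1..K preserving ascending order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(labels)
    lut = np.zeros(int(ids.max()) + 1, dtype=labels.dtype)
    lut[ids] = np.arange(1, ids.size + 1, dtype=labels.dtype)
    return lut[labels]
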