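"""Reading, writing and windowing of 3D scalar scenes.

A *scene* is a 3D grid of scalar intensities (CT Hounsfield units or an
8-bit rescaled version of them) together with the physical voxel spacing
in millimetres.  Supported on-disk formats are NIfTI (``.nii``/``.nii.gz``,
via nibabel), MetaImage (``.mhd``/``.mha``, via SimpleITK) and a raw binary
array accompanied by a small YAML sidecar describing shape, spacing, dtype
and byte order.

Arrays are indexed ``(x, y, z)``; seed coordinates are given in the same
0-based order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

__all__ = [
    "Scene",
    "SegmentationMask",
    "read_scene",
    "read_mask",
    "write_scene",
    "window_to_byte",
]

Spacing = Tuple[float, float, float]


def _check_3d(values: np.ndarray) -> None:
    if values.ndim != 3:
        raise ValueError(f"scene must be 3D, got {values.ndim} dimensions")


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing components must be > 0, got {spacing}")
    return spacing


@dataclass
class Scene:
    """A 3D intensity grid with voxel spacing in mm."""

    values: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_3d(self.values)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def contains(self, index) -> bool:
        return all(0 <= i < n for i, n in zip(index, self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SegmentationMask:
    """A boolean 3D grid sharing shape and spacing with its source scene."""

    values: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        _check_3d(self.values)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mhd", ".mha")
_SIDECAR_SUFFIXES = (".yaml", ".yml")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_META_SUFFIXES):
        return "metaimage"
    if name.endswith(_SIDECAR_SUFFIXES):
        return "raw"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format= explicitly")


def read_scene(path: str | os.PathLike, format: str | None = None) -> Scene:
    """Read a 3D scalar volume and its voxel spacing.

    ``format`` is ``"nifti"``, ``"metaimage"`` or ``"raw"`` (raw binary plus
    YAML sidecar; ``path`` is the sidecar).  When omitted, it is inferred
    from the file suffix.  Raises if the file is not 3D or if spacing
    metadata is missing — spacing is never silently defaulted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        _check_3d(values)
        zooms = img.header.get_zooms()[:3]
        return Scene(values, _check_spacing(zooms))
    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"scene must be 3D, got {img.GetDimension()} dimensions")
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return Scene(values, _check_spacing(img.GetSpacing()))
    if fmt == "raw":
        return _read_raw(path)
    raise ValueError(f"unsupported format {fmt!r}")


def read_mask(path: str | os.PathLike, format: str | None = None) -> SegmentationMask:
    """Read a segmentation mask (any nonzero voxel is foreground)."""
    scene = read_scene(path, format=format)
    return SegmentationMask(scene.values != 0, scene.spacing)


def _read_raw(sidecar: Path) -> Scene:
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    for key in ("raw_file", "shape", "spacing", "dtype"):
        if key not in meta:
            raise ValueError(f"raw sidecar {sidecar} missing required key {key!r}")
    shape = tuple(int(n) for n in meta["shape"])
    if len(shape) != 3:
        raise ValueError("scene must be 3D")
    dtype = np.dtype(meta["dtype"])
    if meta.get("byte_order", "little") == "big":
        dtype = dtype.newbyteorder(">")
    raw_path = sidecar.parent / meta["raw_file"]
    values = np.fromfile(raw_path, dtype=dtype).reshape(shape)
    return Scene(values, _check_spacing(meta["spacing"]))


def write_scene(
    scene: Scene | SegmentationMask, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a Scene or SegmentationMask; masks are stored as uint8 {0,1}.

    The written file round-trips through :func:`read_scene` with
    bit-identical values and spacing.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    values = scene.values
    if isinstance(scene, SegmentationMask):
        values = values.astype(np.uint8)
    try:
        if fmt == "nifti":
            img = nib.Nifti1Image(values, np.diag((*scene.spacing, 1.0)))
            img.header.set_data_dtype(values.dtype)
            img.header.set_zooms(scene.spacing)
            nib.save(img, str(path))
        elif fmt == "metaimage":
            img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
            img.SetSpacing(tuple(float(s) for s in scene.spacing))
            sitk.WriteImage(img, str(path))
        elif fmt == "raw":
            raw_path = path.with_suffix(".raw")
            values.tofile(raw_path)
            meta = {
                "raw_file": raw_path.name,
                "shape": list(values.shape),
                "spacing": [float(s) for s in scene.spacing],
                "dtype": values.dtype.name,
                "byte_order": "big" if values.dtype.byteorder == ">" else "little",
            }
            with open(path, "w") as fh:
                yaml.safe_dump(meta, fh)
        else:
            raise ValueError(f"unsupported format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed writing scene to {path}: {exc}") from exc


def window_to_byte(scene: Scene, lo: float, hi: float) -> Scene:
    """Linearly map intensities in ``[lo, hi]`` to the 8-bit range 0–255.

    Values outside the window are clamped; the mapped value is rounded
    half-up to the nearest integer.  The connectivity core operates on such
    8-bit scenes (its affinity lookup table covers intensities 0–255), so
    CT volumes in Hounsfield units must pass through this windowing step
    explicitly; a window of [-100, 400] HU brackets contrast-enhanced
    vessels (~100–230 HU after rescale) with parenchyma context.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got lo={lo}, hi={hi}")
    scaled = (scene.values.astype(np.float64) - lo) * (255.0 / (hi - lo))
    byte = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    return Scene(np.clip(byte, 0, 255).astype(np.uint8), scene.spacing)
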