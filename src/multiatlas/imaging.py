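"""Core image/label data model, NIfTI I/O and grid geometry.

A :class:`VolumeImage` is a 3-D scalar grid (CT-like intensities) with
physical spacing, origin and orientation; a :class:`LabelMap` is an integer
grid on the same geometry holding anatomical structure labels (0 is always
background).  An :class:`Atlas` pairs the two: a previously contoured image
used as prior knowledge by multi-atlas segmentation.

All physical quantities are millimetres internally; volumes are reported in
cubic centimetres and surface distances in centimetres where the clinical
convention expects them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class EmptyStructureError(ValueError):
    """Raised when an operation requires a non-empty structure mask."""


@dataclass
class VolumeImage:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities (Hounsfield-unit-like for CT).
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm; all strictly positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    orientation : ndarray, shape (3, 3)
        Direction cosine matrix; identity by default.

    The physical position of voxel index ``i`` is
    ``origin + orientation @ (i * spacing)`` (0-based indices).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.voxels.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation * np.asarray(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "VolumeImage | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.orientation, other.orientation)
        )

    def indices_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to physical mm points."""
        indices = np.atleast_2d(indices).astype(float)
        return (
            np.asarray(self.origin)
            + (indices * np.asarray(self.spacing)) @ self.orientation.T
        )


@dataclass
class LabelMap:
    """An integer structure-label grid aligned to a :class:`VolumeImage`."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"expected a 3-D label map, got {self.labels.ndim} dimensions"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    # Geometry helpers shared with VolumeImage.
    voxel_volume_mm3 = VolumeImage.voxel_volume_mm3
    affine = VolumeImage.affine
    same_grid = VolumeImage.same_grid
    indices_to_physical = VolumeImage.indices_to_physical

    def label_for(self, name: str) -> int:
        for value, n in self.label_names.items():
            if n == name:
                return value
        raise KeyError(f"no label named {name!r}; known: {self.label_names}")

    def binary(self, label: int) -> np.ndarray:
        return self.labels == int(label)


@dataclass
class Atlas:
    """A contoured image: the unit of prior knowledge in MAS."""

    id: str
    image: VolumeImage
    contours: LabelMap

    def __post_init__(self) -> None:
        if not self.image.same_grid(self.contours):
            raise ValueError(f"atlas {self.id}: image and contours grids differ")

    def validate_structures(self, structures: list[str]) -> None:
        """Check every named structure is present and non-empty."""
        present = set(np.unique(self.contours.labels))
        for name in structures:
            lab = self.contours.label_for(name)
            if lab not in present:
                raise EmptyStructureError(
                    f"atlas {self.id}: structure {name!r} (label {lab}) is empty"
                )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _image_from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple, np.ndarray]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got {data.ndim}-D")
    aff = img.affine
    lin = aff[:3, :3]
    spacing = tuple(float(np.linalg.norm(lin[:, j])) for j in range(3))
    orientation = lin / np.asarray(spacing)
    origin = tuple(float(v) for v in aff[:3, 3])
    return data, spacing, origin, orientation


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3-D NIfTI-1 image (optionally gzipped) as a VolumeImage."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error types vary
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data, spacing, origin, orientation = _image_from_nifti(img)
    return VolumeImage(data, spacing, origin, orientation)


def read_labelmap(path: str | Path, names_path: str | Path | None = None) -> LabelMap:
    """Read an integer NIfTI label volume plus optional JSON name sidecar."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data, spacing, origin, orientation = _image_from_nifti(img)
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int32)
    names: dict[int, str] = {}
    if names_path is None:
        candidate = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        candidate = candidate.parent / (candidate.name + ".json")
        if candidate.exists():
            names_path = candidate
    if names_path is not None:
        names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    return LabelMap(data, spacing, origin, orientation, label_names=names)


def write_volume(image: VolumeImage | LabelMap, path: str | Path) -> None:
    """Write a VolumeImage or LabelMap to NIfTI-1; integer dtypes bit-exact.

    For a LabelMap, the label-name mapping goes to a ``<stem>.json`` sidecar.
    """
    path = Path(path)
    data = image.labels if isinstance(image, LabelMap) else image.voxels
    nii = nib.Nifti1Image(data, image.affine)
    nii.header.set_data_dtype(data.dtype)
    nib.save(nii, str(path))
    if isinstance(image, LabelMap) and image.label_names:
        stem = path.with_suffix("").with_suffix("")
        sidecar = stem.parent / (stem.name + ".json")
        sidecar.write_text(
            json.dumps({str(k): v for k, v in image.label_names.items()}, indent=1)
        )


def save_atlas(atlas: Atlas, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.image, directory / f"{atlas.id}_image.nii.gz")
    write_volume(atlas.contours, directory / f"{atlas.id}_labels.nii.gz")


def load_atlas(atlas_id: str, directory: str | Path) -> Atlas:
    directory = Path(directory)
    image = read_volume(directory / f"{atlas_id}_image.nii.gz")
    contours = read_labelmap(directory / f"{atlas_id}_labels.nii.gz")
    return Atlas(atlas_id, image, contours)


# ---------------------------------------------------------------------------
# Geometry operations

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def extract_surface_voxels(mask: LabelMap, label: int) -> np.ndarray:
    """Physical centers (mm) of the surface voxels of one structure.

    A voxel is *surface* if it carries the label and at least one of its six
    face neighbours does not (the image boundary counts as background).

    Returns an ``(n, 3)`` float array of physical points.
    """
    binary = mask.binary(label)
    if not binary.any():
        raise EmptyStructureError(f"label {label} is empty; no surface to extract")
    interior = ndimage.binary_erosion(binary, structure=_FACE_STRUCT, border_value=0)
    surface = binary & ~interior
    idx = np.argwhere(surface)
    return mask.indices_to_physical(idx)


def volume_of_label(mask: LabelMap, label: int) -> float:
    """Volume of one structure in cc: voxel count x voxel volume / 1000.

    The label must be declared in ``label_names`` when the map carries names
    (an empty but declared structure has volume 0.0).
    """
    label = int(label)
    if mask.label_names and label not in mask.label_names:
        raise KeyError(f"label {label} not in label_names {mask.label_names}")
    count = int(np.count_nonzero(mask.labels == label))
    return count * mask.voxel_volume_mm3 / 1000.0


def relabeled(mask: LabelMap, labels: np.ndarray) -> LabelMap:
    """A copy of ``mask`` with new voxel data on the same grid."""
    return replace(mask, labels=np.asarray(labels))
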