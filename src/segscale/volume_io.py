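"""Volume containers, readers/writers and the fixed preprocessing chain.

Tomographic volumes are kept as plain 3D NumPy arrays indexed ``(p, r, c)``
(plane, row, column; 0-based) together with an isotropic voxel size in
micrometres.  The preprocessing applied to every sample before segmentation
is fixed: resample to a common isotropic voxel size (bi-linear), clip the
dynamic range to the 0.5 % / 99.9 % percentiles, then normalise linearly to
[0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger("segscale")

#: default resampling target used for real tomograms, micrometres
DEFAULT_TARGET_VOXEL_UM = 5.0
#: default percentile clip window applied before [0, 1] normalisation
DEFAULT_CLIP_PERCENTILES = (0.5, 99.9)

CLASS_NAMES: Mapping[int, str] = {
    0: "background",
    1: "bone",
    2: "degradation layer",
    3: "residual material",
}
N_CLASSES = len(CLASS_NAMES)
BACKGROUND, BONE, DEGRADATION_LAYER, RESIDUAL_MATERIAL = 0, 1, 2, 3


@dataclass(frozen=True)
class VoxelGeometry:
    """Isotropic voxel geometry; index order is fixed to (p, r, c)."""

    voxel_size_um: float
    origin_convention: str = "prc0"

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def voxel_area_mm2(self) -> float:
        return self.voxel_size_mm**2


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel geometry."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """A 3D grid over the four semantic classes {BG, bone, DL, RM}."""

    data: np.ndarray
    geometry: VoxelGeometry
    class_names: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"LabelVolume requires integer dtype, got {self.data.dtype}")
        bad = np.setdiff1d(np.unique(self.data), np.array(sorted(self.class_names)))
        if bad.size:
            raise ValueError(f"labels outside the class set {sorted(self.class_names)}: {bad}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii", ".gz"}


def _read_tiff_directory(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in directory {path}")
    slices = [tifffile.imread(f) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    return np.stack(slices, axis=0)


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> Volume:
    """Read a volume from a TIFF slice-stack directory, multi-page TIFF or NIfTI.

    The first array axis is the slice index (plane p).  For NIfTI files the
    voxel size is taken from the header when ``voxel_size_um`` is not given;
    TIFF input always requires an explicit voxel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume path does not exist: {path}")
    if path.is_dir():
        data = _read_tiff_directory(path)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    elif path.suffix.lower() in _NIFTI_SUFFIXES or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if voxel_size_um is None:
            zooms = img.header.get_zooms()[:3]
            if not np.allclose(zooms, zooms[0]):
                raise ValueError(f"anisotropic NIfTI voxels {zooms}; pass voxel_size_um")
            voxel_size_um = float(zooms[0]) * 1000.0  # NIfTI zooms stored in mm
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {data.shape}")
    if voxel_size_um is None:
        raise ValueError("voxel_size_um is required for TIFF input")
    if np.issubdtype(data.dtype, np.integer) and data.dtype.itemsize <= 2:
        # widen small integer intensities to float for processing
        data = data.astype(np.float32)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32, copy=False)
    return Volume(data, VoxelGeometry(float(voxel_size_um)))


def read_label_volume(path: str | Path, voxel_size_um: float | None = None) -> LabelVolume:
    """Read a 4-class label volume (integer NIfTI or TIFF)."""
    path = Path(path)
    if path.is_dir():
        data = _read_tiff_directory(path)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(path)
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if voxel_size_um is None:
            voxel_size_um = float(img.header.get_zooms()[0]) * 1000.0
    if voxel_size_um is None:
        raise ValueError("voxel_size_um is required for TIFF labels")
    data = np.rint(np.asarray(data)).astype(np.uint8)
    return LabelVolume(data, VoxelGeometry(float(voxel_size_um)))


def write_volume(v: Volume | LabelVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume; format inferred from the suffix unless given.

    Supported tags: ``"tiff"`` (multi-page), ``"nifti"``.  Integer label
    volumes round-trip bit-exactly; real volumes are stored as float32.
    """
    path = Path(path)
    if format is None:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            format = "tiff"
        elif path.suffix.lower() in _NIFTI_SUFFIXES or path.name.endswith(".nii.gz"):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format from suffix of {path}")
    data = v.data
    if isinstance(v, LabelVolume):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    if format == "tiff":
        tifffile.imwrite(path, data)
    elif format == "nifti":
        affine = np.diag([v.geometry.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise ValueError(f"unknown format tag {format!r}; use 'tiff' or 'nifti'")


# ---------------------------------------------------------------------------
# Preprocessing chain: resample -> clip -> normalize
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def resample_isotropic(
    v: Volume | LabelVolume, target_voxel_um: float, mode: str = "linear"
) -> Volume | LabelVolume:
    """Resample to a new isotropic voxel size.

    Output shape per axis is round(shape * voxel / target) with half-away
    rounding.  Intensities use linear interpolation; label volumes must use
    ``mode="nearest"``.
    """
    if not target_voxel_um > 0:
        raise ValueError(f"target voxel size must be positive, got {target_voxel_um}")
    if isinstance(v, LabelVolume) and mode != "nearest":
        raise ValueError("label volumes must be resampled with mode='nearest'")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    factor = v.geometry.voxel_size_um / target_voxel_um
    new_geom = VoxelGeometry(float(target_voxel_um))
    if math.isclose(factor, 1.0):
        return replace(v, geometry=new_geom)
    new_shape = tuple(max(1, _round_half_away(s * factor)) for s in v.shape)
    # interpolate at the centres of the new voxel grid, in old-index units
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * (old / n) - 0.5
            for n, old in zip(new_shape, v.shape)
        ],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        v.data.astype(np.float32) if mode == "linear" else v.data,
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="nearest",
    ).reshape(new_shape)
    if isinstance(v, LabelVolume):
        return LabelVolume(out.astype(v.data.dtype), new_geom, dict(v.class_names))
    return Volume(out.astype(np.float32), new_geom)


def clip_normalize(
    v: Volume,
    lo_pct: float = DEFAULT_CLIP_PERCENTILES[0],
    hi_pct: float = DEFAULT_CLIP_PERCENTILES[1],
) -> Volume:
    """Clip intensities to the [lo_pct, hi_pct] percentiles and map to [0, 1].

    Percentiles are computed over the entire volume with the linear
    interpolation definition.  A constant volume (degenerate window) maps to
    all zeros with a warning rather than raising, so a batch run never aborts.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError(f"invalid percentile window [{lo_pct}, {hi_pct}]")
    q_lo, q_hi = np.percentile(v.data, [lo_pct, hi_pct])
    if q_hi <= q_lo:
        logger.warning("degenerate intensity window (q_lo == q_hi); output set to zeros")
        return Volume(np.zeros(v.shape, dtype=np.float32), v.geometry)
    out = np.clip(v.data, q_lo, q_hi)
    out = (out - q_lo) / (q_hi - q_lo)
    return Volume(out.astype(np.float32), v.geometry)


def preprocess(
    v: Volume,
    target_voxel_um: float = DEFAULT_TARGET_VOXEL_UM,
    lo_pct: float = DEFAULT_CLIP_PERCENTILES[0],
    hi_pct: float = DEFAULT_CLIP_PERCENTILES[1],
) -> Volume:
    """The fixed chain: resample to target voxel size, clip, normalise to [0, 1]."""
    out = resample_isotropic(v, target_voxel_um, mode="linear")
    return clip_normalize(out, lo_pct, hi_pct)  # type: ignore[arg-type]
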