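"""Multi-axes slicing and prediction fusing.

A 3D volume V(p, r, c) is processed slice-by-slice by a 2D model.  Three
naive slicing sets exist, one per principal axis:

* ``S_rc``: slices fix p, ``S_n(i, j) = V(n, i, j)``
* ``S_cp``: slices fix r, ``S_n(i, j) = V(i, n, j)``
* ``S_pr``: slices fix c, ``S_n(i, j) = V(i, j, n)``

Rotating the volume in-plane by 45 degrees about each principal axis and
slicing along the two non-parallel axes adds six non-redundant planes (the
third would only be an in-plane rotation of a naive plane), for nine in
total.  Per-plane class-probability volumes are mapped back to the original
frame and fused by probability averaging (soft voting) or per-voxel mode
(majority voting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, VoxelGeometry, Volume

logger = logging.getLogger("segscale")

AXES = {"p": 0, "r": 1, "c": 2}
#: plane name by sliced (fixed) axis
PLANE_NAME = {"p": "S_rc", "r": "S_cp", "c": "S_pr"}


@dataclass(frozen=True)
class PlaneTransform:
    """One slicing plane: an optional in-plane 45-degree rotation followed by
    slicing along one principal axis."""

    slicing_axis: str  # 'p' | 'r' | 'c'
    rotation_axis: str | None = None  # None or 'p' | 'r' | 'c'
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.slicing_axis not in AXES:
            raise ValueError(f"invalid slicing axis {self.slicing_axis!r}")
        if self.rotation_axis is None and self.rotation_deg != 0.0:
            raise ValueError("rotation_deg must be 0 without a rotation axis")
        if self.rotation_axis is not None:
            if self.rotation_axis not in AXES:
                raise ValueError(f"invalid rotation axis {self.rotation_axis!r}")
            if self.rotation_deg != 0.0 and self.slicing_axis == self.rotation_axis:
                raise ValueError(
                    "slicing along the rotation axis duplicates a naive plane"
                )

    @property
    def name(self) -> str:
        base = PLANE_NAME[self.slicing_axis]
        if self.rotation_axis is None or self.rotation_deg == 0.0:
            return base
        return f"{base}@rot_{self.rotation_axis}{self.rotation_deg:g}"


@dataclass
class SliceSet:
    """An ordered stack of congruent 2D slices plus its originating transform."""

    slices: np.ndarray  # (N, H, W)
    transform: PlaneTransform

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError(f"slices must be (N, H, W), got {self.slices.shape}")

    def __len__(self) -> int:
        return self.slices.shape[0]


@dataclass
class ProbabilityVolume:
    """Per-voxel k-class probability field, (P, R, C, k)."""

    data: np.ndarray
    geometry: VoxelGeometry
    valid_mask: np.ndarray | None = None  # True where real data supports the value

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"probability data must be 4D, got {self.data.shape}")

    @property
    def n_classes(self) -> int:
        return self.data.shape[-1]


# ---------------------------------------------------------------------------
# Rotation
# ---------------------------------------------------------------------------


def _in_plane_axes(rotation_axis: str) -> tuple[int, int]:
    ax = AXES[rotation_axis]
    return tuple(a for a in (0, 1, 2) if a != ax)  # type: ignore[return-value]


def padded_shape_for(shape: Sequence[int], rotation_axis: str, angle_deg: float) -> tuple[int, int, int]:
    """Bounding-box shape after in-plane rotation (ceil rule, minimal padding)."""
    a1, a2 = _in_plane_axes(rotation_axis)
    h, w = shape[a1], shape[a2]
    th = math.radians(angle_deg)
    c, s = abs(math.cos(th)), abs(math.sin(th))
    new = list(shape)
    new[a1] = math.ceil(h * c + w * s)
    new[a2] = math.ceil(h * s + w * c)
    return tuple(new)  # type: ignore[return-value]


def _pad_to(data: np.ndarray, target: Sequence[int]) -> np.ndarray:
    pads = []
    for old, new in zip(data.shape, target):
        extra = new - old
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(data, pads)


def _crop_to(data: np.ndarray, target: Sequence[int]) -> np.ndarray:
    index = []
    for old, new in zip(data.shape, target):
        extra = old - new
        lo = extra // 2
        index.append(slice(lo, lo + new))
    return data[tuple(index)]


def _rotate_array(data: np.ndarray, rotation_axis: str, angle_deg: float) -> np.ndarray:
    """In-plane rotation about the array centre: bilinear, zero fill."""
    a1, a2 = _in_plane_axes(rotation_axis)
    return ndimage.rotate(
        data, angle_deg, axes=(a1, a2), reshape=False, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )


def rotate_volume(v: Volume, axis: str, angle_deg: float) -> Volume:
    """Rotate every cross-section perpendicular to ``axis`` about the image
    centre (bilinear, zero fill), expanding to the rotated bounding box."""
    target = padded_shape_for(v.shape, axis, angle_deg)
    data = _pad_to(v.data.astype(np.float32), target)
    return Volume(_rotate_array(data, axis, angle_deg), v.geometry)


# ---------------------------------------------------------------------------
# Slicing and restacking
# ---------------------------------------------------------------------------


def slice_volume(v: Volume | np.ndarray, t: PlaneTransform) -> SliceSet:
    """Cut a (possibly pre-rotated) volume into the 2D slice stack of plane t."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    ax = AXES[t.slicing_axis]
    return SliceSet(np.ascontiguousarray(np.moveaxis(data, ax, 0)), t)


def restack(s: SliceSet | np.ndarray, t: PlaneTransform) -> np.ndarray:
    """Inverse of slice_volume: stack slices (N, H, W[, k]) back into a volume.

    Probability slices (N, H, W, k) stack to (P, R, C, k); the class axis
    stays last.  For unrotated planes this is a bit-exact inverse.
    """
    arr = s.slices if isinstance(s, SliceSet) else np.asarray(s)
    ax = AXES[t.slicing_axis]
    return np.moveaxis(arr, 0, ax)


def plane_slice_count(shape: Sequence[int], t: PlaneTransform) -> int:
    """Number of 2D slices plane t produces from a volume of this shape."""
    if t.rotation_axis is not None and t.rotation_deg != 0.0:
        shape = padded_shape_for(shape, t.rotation_axis, t.rotation_deg)
    return int(shape[AXES[t.slicing_axis]])


# ---------------------------------------------------------------------------
# Plane sets
# ---------------------------------------------------------------------------


def generate_plane_set(n_planes: int) -> list[PlaneTransform]:
    """The 3 naive planes, or those plus the 6 non-redundant 45-degree planes."""
    if n_planes not in (3, 9):
        raise ValueError(f"supported plane counts are 3 and 9, got {n_planes}")
    naive = [PlaneTransform(ax) for ax in ("p", "r", "c")]
    if n_planes == 3:
        return naive
    rotated = [
        PlaneTransform(slicing_axis=s, rotation_axis=a, rotation_deg=45.0)
        for a in ("p", "r", "c")
        for s in ("p", "r", "c")
        if s != a  # slicing along the rotation axis adds no information
    ]
    return naive + rotated


# ---------------------------------------------------------------------------
# Back-mapping rotated predictions
# ---------------------------------------------------------------------------


def validity_mask(original_shape: Sequence[int], t: PlaneTransform) -> np.ndarray:
    """Voxels of the original frame whose back-mapped value is fully supported
    by real data (no zero-fill contamination from the rotation padding)."""
    if t.rotation_axis is None or t.rotation_deg == 0.0:
        return np.ones(tuple(original_shape), dtype=bool)
    ones = np.ones(tuple(original_shape), dtype=np.float32)
    target = padded_shape_for(original_shape, t.rotation_axis, t.rotation_deg)
    fwd = _rotate_array(_pad_to(ones, target), t.rotation_axis, t.rotation_deg)
    back = _rotate_array(fwd, t.rotation_axis, -t.rotation_deg)
    return _crop_to(back, original_shape) >= 0.999


def back_map(
    p: ProbabilityVolume, t: PlaneTransform, original_shape: Sequence[int]
) -> ProbabilityVolume:
    """Map a probability volume from the transformed (rotated/padded) frame
    back to the original frame: inverse rotation, centre crop, per-voxel
    renormalisation, and validity masking."""
    original_shape = tuple(original_shape)
    if t.rotation_axis is None or t.rotation_deg == 0.0:
        if p.data.shape[:3] != original_shape:
            raise ValueError(
                f"shape mismatch: {p.data.shape[:3]} vs {original_shape}"
            )
        mask = np.ones(original_shape, dtype=bool)
        return ProbabilityVolume(p.data, p.geometry, mask)
    back = _rotate_array(p.data, t.rotation_axis, -t.rotation_deg)
    back = _crop_to(back, original_shape + (p.n_classes,))
    sums = back.sum(axis=-1, keepdims=True)
    np.clip(sums, 1e-8, None, out=sums)
    back = back / sums
    mask = validity_mask(original_shape, t)
    return ProbabilityVolume(back.astype(np.float32), p.geometry, mask)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def soft_vote(predictions: Sequence[ProbabilityVolume]) -> ProbabilityVolume:
    """Probability averaging over the given predictions, restricted at each
    voxel to the predictions whose validity mask covers it."""
    if not predictions:
        raise ValueError("soft_vote needs at least one prediction")
    shape = predictions[0].data.shape
    acc = np.zeros(shape, dtype=np.float64)
    count = np.zeros(shape[:3], dtype=np.int32)
    for p in predictions:
        if p.data.shape != shape:
            raise ValueError("incongruent prediction shapes")
        mask = p.valid_mask if p.valid_mask is not None else np.ones(shape[:3], bool)
        acc += p.data * mask[..., None]
        count += mask
    uncovered = count == 0
    if uncovered.any():
        logger.warning(
            "%d voxels have no valid prediction; uniform fallback", int(uncovered.sum())
        )
        acc[uncovered] = 1.0 / shape[-1]
        count[uncovered] = 1
    out = (acc / count[..., None]).astype(np.float32)
    return ProbabilityVolume(out, predictions[0].geometry, ~uncovered)


def argmax_labels(p: ProbabilityVolume) -> LabelVolume:
    """Per-voxel arg-max; ties resolve to the lowest class index."""
    labels = p.data.argmax(axis=-1).astype(np.uint8)
    return LabelVolume(labels, p.geometry)


def _vote_counts(
    labels_list: Sequence[np.ndarray], masks: Sequence[np.ndarray] | None, k: int
) -> np.ndarray:
    shape = labels_list[0].shape
    counts = np.zeros(shape + (k,), dtype=np.int32)
    for i, lab in enumerate(labels_list):
        m = masks[i] if masks is not None else np.ones(shape, bool)
        for c in range(k):
            counts[..., c] += ((lab == c) & m)
    return counts


def majority_vote(segmentations: Sequence[LabelVolume]) -> LabelVolume:
    """Per-voxel mode of hard label maps; ties break to the lowest class."""
    if not segmentations:
        raise ValueError("majority_vote needs at least one segmentation")
    k = max(int(s.data.max()) for s in segmentations) + 1
    k = max(k, max(len(s.class_names) for s in segmentations))
    counts = _vote_counts([s.data for s in segmentations], None, k)
    out = counts.argmax(axis=-1).astype(np.uint8)
    return LabelVolume(out, segmentations[0].geometry)


def _masked_majority(
    predictions: Sequence[ProbabilityVolume], geometry: VoxelGeometry
) -> LabelVolume:
    k = predictions[0].n_classes
    labels = [p.data.argmax(axis=-1) for p in predictions]
    masks = [
        p.valid_mask if p.valid_mask is not None else np.ones(p.data.shape[:3], bool)
        for p in predictions
    ]
    counts = _vote_counts(labels, masks, k)
    none_valid = counts.sum(axis=-1) == 0
    if none_valid.any():
        logger.warning("%d voxels with no valid vote; class 0 fallback", int(none_valid.sum()))
    return LabelVolume(counts.argmax(axis=-1).astype(np.uint8), geometry)


# ---------------------------------------------------------------------------
# Full-volume prediction
# ---------------------------------------------------------------------------


def _predict_slices(model, slices: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Run a 2D k-class predictor over a slice stack, reflect-padding each
    slice to the next multiple of the model's divisibility constraint."""
    divisor = getattr(model, "divisor", 1)
    n, h, w = slices.shape
    ph = (-h) % divisor
    pw = (-w) % divisor
    out = None
    for start in range(0, n, batch_size):
        batch = slices[start:start + batch_size].astype(np.float32)
        if ph or pw:
            batch = np.pad(batch, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        probs = model.predict_proba(batch[:, None])  # (B, k, H', W')
        probs = probs[:, :, :h, :w]
        if out is None:
            out = np.empty((n, probs.shape[1], h, w), dtype=np.float32)
        out[start:start + batch_size] = probs
    return out  # (N, k, H, W)


def predict_plane(
    model, v: Volume, t: PlaneTransform, batch_size: int = 8
) -> ProbabilityVolume:
    """rotate (if needed) -> slice -> per-slice predict -> restack -> back-map."""
    work = rotate_volume(v, t.rotation_axis, t.rotation_deg) if (
        t.rotation_axis is not None and t.rotation_deg != 0.0
    ) else v
    sl = slice_volume(work, t)
    probs = _predict_slices(model, sl.slices, batch_size=batch_size)
    stacked = restack(probs.transpose(0, 2, 3, 1), t)  # (P, R, C, k) in work frame
    pv = ProbabilityVolume(stacked, v.geometry)
    return back_map(pv, t, v.shape)


def predict_volume(
    model,
    v: Volume,
    planes: Sequence[PlaneTransform] | int = 3,
    fusion: str = "soft",
    batch_size: int = 8,
    return_probabilities: bool = False,
):
    """Segment a volume by multi-axes prediction fusing.

    ``model`` must map single-channel 2D slices to per-pixel k-class
    probability maps of the same shape (attribute ``divisor`` states the
    spatial divisibility it needs).  ``fusion`` is ``"soft"`` (probability
    averaging then arg-max) or ``"majority"`` (per-plane arg-max then mode).
    """
    if isinstance(planes, int):
        planes = generate_plane_set(planes)
    if fusion not in ("soft", "majority"):
        raise ValueError(f"unknown fusion mode {fusion!r}")
    per_plane = [predict_plane(model, v, t, batch_size=batch_size) for t in planes]
    if fusion == "soft":
        fused = soft_vote(per_plane)
        labels = argmax_labels(fused)
        return (labels, fused) if return_probabilities else labels
    labels = _masked_majority(per_plane, v.geometry)
    return (labels, None) if return_probabilities else labels
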