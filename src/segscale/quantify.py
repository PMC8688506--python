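"""Implant degradation and osseointegration morphometry from label volumes.

Three measures are computed from a 4-class segmentation (background, bone,
degradation layer DL, residual material RM) with known voxel size:

* degradation rate  DR = ((v_i - v_r) / a_i) / t   [mm/year]
* bone-implant contact  BIC = b / a               [fraction]
* bone volume fraction  BV/TV = v_bone / v_ROI    [fraction]

where v_i, a_i are the initial volume and surface area of the implant before
implantation, v_r the residual (RM) volume, b the implant boundary voxels in
face contact with bone, a the implant boundary voxel count, and the ROI is
the shell of a chosen Euclidean distance around the implant (DL and RM
combined), excluding the implant itself.  Surfaces are voxel-count proxies
with 6-connectivity; volume borders count as outside.

The degradation-rate convention divides by the implantation time so the
result carries mm/year; ``dr_formula="multiply_t"`` keeps the alternative
multiplicative form found in part of the corrosion literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import (
    BONE,
    DEGRADATION_LAYER,
    RESIDUAL_MATERIAL,
    LabelVolume,
)

logger = logging.getLogger("segscale")

IMPLANT_CLASSES = frozenset({DEGRADATION_LAYER, RESIDUAL_MATERIAL})
#: default ROI shell distance around the implant, micrometres
DEFAULT_ROI_DISTANCE_UM = 500.0


@dataclass(frozen=True)
class ImplantReference:
    """Pre-implantation implant state: initial volume and surface area."""

    initial_volume_mm3: float
    initial_surface_mm2: float
    source: str = "reference-labelvolume"  # or "analytic-phantom"

    def __post_init__(self) -> None:
        if self.initial_volume_mm3 <= 0 or self.initial_surface_mm2 <= 0:
            raise ValueError("initial volume and surface must be positive")


@dataclass
class QuantResult:
    v_r_mm3: float
    dr_mm_per_year: float
    bic_fraction: float
    bvtv_fraction: float
    b_voxels: int
    a_voxels: int
    v_bone_voxels: int
    v_roi_voxels: int
    t_years: float

    def as_dict(self) -> dict:
        return {
            "v_r_mm3": self.v_r_mm3,
            "dr_mm_per_year": self.dr_mm_per_year,
            "bic_percent": 100.0 * self.bic_fraction,
            "bvtv_percent": 100.0 * self.bvtv_fraction,
            "b_voxels": self.b_voxels,
            "a_voxels": self.a_voxels,
            "v_bone_voxels": self.v_bone_voxels,
            "v_roi_voxels": self.v_roi_voxels,
            "t_years": self.t_years,
        }


_FACE_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def boundary_voxels(
    labels: LabelVolume, region_classes=IMPLANT_CLASSES
) -> tuple[int, dict[int, int]]:
    """Surface voxel count of a region and per-class face-contact counts.

    A region voxel is on the surface if at least one of its 6 face
    neighbours lies outside the region (volume borders count as outside).
    ``contact_counts[c]`` is the number of surface voxels with at least one
    face neighbour of class ``c``.
    """
    lab = labels.data
    region = np.isin(lab, list(region_classes))
    if not region.any():
        logger.warning("boundary_voxels: empty region, returning zeros")
        return 0, {c: 0 for c in range(len(labels.class_names))}
    # pad so the volume border reads as 'outside' with no class (-1)
    lab_p = np.pad(lab.astype(np.int16), 1, constant_values=-1)
    reg_p = np.pad(region, 1, constant_values=False)
    core = (slice(1, -1),) * 3
    surface = np.zeros_like(region)
    neighbour_any: dict[int, np.ndarray] = {
        c: np.zeros_like(region) for c in range(len(labels.class_names))
    }
    for dp, dr, dc in _FACE_SHIFTS:
        sl = tuple(slice(1 + d, lab_p.shape[i] - 1 + d) for i, d in enumerate((dp, dr, dc)))
        nb_reg = reg_p[sl]
        nb_lab = lab_p[sl]
        surface |= ~nb_reg
        for c in neighbour_any:
            neighbour_any[c] |= nb_lab == c
    surface &= region
    contact = {c: int((surface & neighbour_any[c]).sum()) for c in neighbour_any}
    return int(surface.sum()), contact


def residual_volume_mm3(labels: LabelVolume) -> float:
    """Residual-material volume: RM voxel count times the voxel volume."""
    return float((labels.data == RESIDUAL_MATERIAL).sum()) * labels.geometry.voxel_volume_mm3


def degradation_rate(
    ref: ImplantReference,
    labels: LabelVolume,
    t_years: float,
    dr_formula: str = "divide_t",
) -> float:
    """Mean degradation rate from the volume loss of the residual material."""
    if t_years <= 0:
        raise ValueError(f"implantation time must be positive, got {t_years}")
    if dr_formula not in ("divide_t", "multiply_t"):
        raise ValueError(f"unknown dr_formula {dr_formula!r}")
    v_r = residual_volume_mm3(labels)
    loss = ref.initial_volume_mm3 - v_r
    if loss < 0:
        logger.warning(
            "residual volume %.4g exceeds initial volume %.4g; clamping DR to 0",
            v_r, ref.initial_volume_mm3,
        )
        loss = 0.0
    rate = loss / ref.initial_surface_mm2
    return rate / t_years if dr_formula == "divide_t" else rate * t_years


def bone_implant_contact(labels: LabelVolume) -> float:
    """BIC = bone-contact boundary voxels / implant boundary voxels."""
    a, contact = boundary_voxels(labels, IMPLANT_CLASSES)
    if a == 0:
        raise ValueError("bone_implant_contact: implant region is empty")
    return contact[BONE] / a


def build_roi(labels: LabelVolume, distance_um: float = DEFAULT_ROI_DISTANCE_UM) -> np.ndarray:
    """Boolean ROI: voxels within a Euclidean distance of the implant
    (DL and RM combined), excluding the implant itself."""
    implant = np.isin(labels.data, list(IMPLANT_CLASSES))
    if not implant.any():
        raise ValueError("build_roi: implant region is empty")
    dist = ndimage.distance_transform_edt(
        ~implant, sampling=labels.geometry.voxel_size_um
    )
    return (dist > 0) & (dist <= distance_um)


def bone_volume_fraction(labels: LabelVolume, roi: np.ndarray) -> float:
    """BV/TV: bone voxels within the ROI over the ROI voxel count."""
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("bone_volume_fraction: empty ROI")
    return int((labels.data[roi] == BONE).sum()) / n_roi


def quantify(
    labels: LabelVolume,
    ref: ImplantReference,
    t_years: float,
    roi_distance_um: float = DEFAULT_ROI_DISTANCE_UM,
    dr_formula: str = "divide_t",
) -> QuantResult:
    """All three morphometric measures from one segmentation."""
    a, contact = boundary_voxels(labels, IMPLANT_CLASSES)
    if a == 0:
        raise ValueError("quantify: implant region is empty")
    roi = build_roi(labels, roi_distance_um)
    n_roi = int(roi.sum())
    n_bone = int((labels.data[roi] == BONE).sum())
    return QuantResult(
        v_r_mm3=residual_volume_mm3(labels),
        dr_mm_per_year=degradation_rate(ref, labels, t_years, dr_formula),
        bic_fraction=contact[BONE] / a,
        bvtv_fraction=n_bone / n_roi if n_roi else float("nan"),
        b_voxels=contact[BONE],
        a_voxels=a,
        v_bone_voxels=n_bone,
        v_roi_voxels=n_roi,
        t_years=t_years,
    )
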