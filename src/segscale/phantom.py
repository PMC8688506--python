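"""Synthetic screw phantoms with analytic ground truth.

Real bone-implant tomograms for this task are not publicly deposited, so all
testing runs on generated phantoms that emulate their structure: a bright
residual-material (RM) cylinder core, a corroded degradation-layer (DL)
shell of intermediate gray, a partially filled trabecular bone shell, and a
dark background, optionally with phase-contrast-like edge ringing at the
interfaces.  Geometry is an axis-aligned circular cylinder so that volumes
and surfaces have exact closed forms.

Conventions that keep the truth record closed-form:

* the bone region is the full Euclidean-distance capsule around the implant
  (it wraps the end caps as well as the lateral surface), built with the
  same distance transform the ROI of the morphometry module uses;
* trabecular porosity is carved by seeded spherical voids until the bone
  fraction inside the capsule reaches ``bone_occupancy``, so the expected
  BV/TV equals the occupancy by construction;
* void centres keep a two-voxel safety margin from the implant surface, so
  the first bone layer stays intact and the expected bone-implant contact
  of the crack-free phantom is exactly 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import (
    BACKGROUND,
    BONE,
    DEGRADATION_LAYER,
    RESIDUAL_MATERIAL,
    LabelVolume,
    VoxelGeometry,
    Volume,
)

logger = logging.getLogger("segscale")

DEFAULT_INTENSITY_MEANS = {
    BACKGROUND: 0.1,
    BONE: 0.45,
    DEGRADATION_LAYER: 0.6,
    RESIDUAL_MATERIAL: 0.9,
}
DEFAULT_INTENSITY_SIGMAS = {c: 0.03 for c in DEFAULT_INTENSITY_MEANS}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and rendering parameters of a screw phantom.

    ``screw_radius_um`` is the pre-implantation screw radius (RM core plus
    DL shell); the RM core radius is ``screw_radius_um -
    degradation_shell_um``.  All lengths in micrometres.
    """

    grid_shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size_um: float = 5.0
    screw_radius_um: float = 250.0
    screw_length_um: float = 600.0
    degradation_shell_um: float = 100.0
    bone_shell_um: float = 150.0
    bone_occupancy: float = 0.4
    void_radius_um: float = 30.0
    crack_count: int = 0
    crack_width_um: float = 10.0
    intensity_means: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS))
    intensity_sigmas: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_SIGMAS))
    edge_enhancement: bool = False
    edge_amplitude: float = 0.25
    edge_sigma_vox: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bone_occupancy <= 1.0):
            raise ValueError("bone_occupancy must lie in [0, 1]")
        if self.degradation_shell_um >= self.screw_radius_um:
            raise ValueError("degradation shell must be thinner than the screw radius")
        means = self.intensity_means
        if not (means[BACKGROUND] < means[BONE] < means[DEGRADATION_LAYER]
                < means[RESIDUAL_MATERIAL]):
            raise ValueError("intensity means must be ordered BG < bone < DL < RM")
        # nesting: radial and axial extents of the bone capsule must fit
        p, r, c = self.grid_shape
        s = self.voxel_size_um
        if self.screw_radius_um + self.bone_shell_um >= min(r, c) * s / 2:
            raise ValueError("bone capsule exceeds the grid radially")
        if self.screw_length_um + 2 * self.bone_shell_um >= p * s:
            raise ValueError("bone capsule exceeds the grid axially")

    @property
    def rm_radius_um(self) -> float:
        return self.screw_radius_um - self.degradation_shell_um


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form reference values (mm-based units), no voxel tallies."""

    v_i_mm3: float  # initial screw volume, pi r^2 L
    v_r_mm3: float  # residual-material volume
    a_i_mm2: float  # initial screw surface, 2 pi r L + 2 pi r^2
    dl_volume_mm3: float
    roi_volume_mm3: float  # capsule shell volume (Steiner formula)
    expected_bic: float
    expected_bvtv: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PhantomSample:
    image: Volume
    labels: LabelVolume
    truth: PhantomTruth
    spec: PhantomSpec


def _cylinder_truth(radius_um: float, length_um: float) -> tuple[float, float]:
    """(volume mm^3, surface mm^2) of a closed cylinder."""
    r = radius_um / 1000.0
    length = length_um / 1000.0
    return math.pi * r * r * length, 2 * math.pi * r * length + 2 * math.pi * r * r


def _capsule_shell_volume_mm3(radius_um: float, length_um: float, dist_um: float) -> float:
    """Volume of {0 < d(x, cylinder) <= R}: Steiner expansion minus cylinder.

    For a convex solid, vol(K + B_R) = V + S R + M R^2 + 4/3 pi R^3 with M
    the mean-curvature integral; for a cylinder M = pi L + pi^2 r.
    """
    r = radius_um / 1000.0
    length = length_um / 1000.0
    big_r = dist_um / 1000.0
    v = math.pi * r * r * length
    s = 2 * math.pi * r * length + 2 * math.pi * r * r
    m = math.pi * length + math.pi**2 * r
    return s * big_r + m * big_r**2 + (4.0 / 3.0) * math.pi * big_r**3


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form volumes/surfaces of the phantom; BV/TV equals the target
    occupancy and BIC is 1 for the crack-free default construction."""
    v_i, a_i = _cylinder_truth(spec.screw_radius_um, spec.screw_length_um)
    v_r, _ = _cylinder_truth(spec.rm_radius_um, spec.screw_length_um)
    roi = _capsule_shell_volume_mm3(
        spec.screw_radius_um, spec.screw_length_um, spec.bone_shell_um
    )
    if spec.crack_count:
        logger.warning(
            "analytic truth assumes a crack-free phantom; %d cracks requested",
            spec.crack_count,
        )
    return PhantomTruth(
        v_i_mm3=v_i,
        v_r_mm3=v_r,
        a_i_mm2=a_i,
        dl_volume_mm3=v_i - v_r,
        roi_volume_mm3=roi,
        expected_bic=1.0,
        expected_bvtv=spec.bone_occupancy,
    )


def _sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer offsets of voxel centres within a sphere of given radius."""
    n = int(math.ceil(radius_vox))
    g = np.mgrid[-n:n + 1, -n:n + 1, -n:n + 1]
    inside = (g**2).sum(axis=0) <= radius_vox**2
    return np.argwhere(inside) - n


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Build the label volume, carve trabecular voids, render the image."""
    p, r, c = spec.grid_shape
    s = spec.voxel_size_um
    geom = VoxelGeometry(s)
    # physical voxel-centre coordinates relative to the grid centre
    zz = (np.arange(p) + 0.5) * s - p * s / 2.0
    yy = (np.arange(r) + 0.5) * s - r * s / 2.0
    xx = (np.arange(c) + 0.5) * s - c * s / 2.0
    rad2 = (yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
    in_len = np.abs(zz)[:, None, None] <= spec.screw_length_um / 2.0

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    implant = (rad2 <= spec.screw_radius_um**2) & in_len
    rm = (rad2 <= spec.rm_radius_um**2) & in_len
    labels[implant] = DEGRADATION_LAYER
    labels[rm] = RESIDUAL_MATERIAL

    dist = ndimage.distance_transform_edt(~implant, sampling=s)
    bone_region = (dist > 0) & (dist <= spec.bone_shell_um)
    labels[bone_region] = BONE

    rng = np.random.default_rng(spec.seed)
    if spec.bone_occupancy < 1.0:
        _carve_voids(labels, dist, bone_region, spec, rng)

    if spec.crack_count:
        _carve_cracks(labels, rad2, in_len, spec, rng)

    image = render_grayscale(LabelVolume(labels, geom), spec, rng=rng)
    return PhantomSample(
        image=image,
        labels=LabelVolume(labels, geom),
        truth=analytic_truth(spec),
        spec=spec,
    )


def _carve_voids(
    labels: np.ndarray,
    dist: np.ndarray,
    bone_region: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> None:
    """Remove seeded spherical voids from the bone shell until the bone
    fraction inside the capsule reaches the target occupancy."""
    s = spec.voxel_size_um
    void_vox = spec.void_radius_um / s
    offsets = _sphere_offsets(void_vox)
    margin = spec.void_radius_um + 2.0 * s  # keep the contact layer intact
    lo, hi = margin, spec.bone_shell_um + spec.void_radius_um
    candidates = np.argwhere((dist > lo) & (dist <= hi))
    if candidates.size == 0:
        logger.warning("no admissible void centres; occupancy target unreachable")
        return
    n_region = int(bone_region.sum())
    n_bone = n_region
    target = spec.bone_occupancy * n_region
    shape = labels.shape
    max_iter = 100000
    for _ in range(max_iter):
        if n_bone <= target:
            break
        centre = candidates[rng.integers(len(candidates))]
        pts = centre + offsets
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        idx = tuple(pts.T)
        hit = labels[idx] == BONE
        n_bone -= int(hit.sum())
        vals = labels[idx]
        vals[hit] = BACKGROUND
        labels[idx] = vals
    else:
        logger.warning("void carving hit the iteration cap before the target")


def _carve_cracks(
    labels: np.ndarray,
    rad2: np.ndarray,
    in_len: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> None:
    """Planar radial cracks: thin background slabs through the DL shell."""
    p, r, c = labels.shape
    s = spec.voxel_size_um
    yy = (np.arange(r) + 0.5) * s - r * s / 2.0
    xx = (np.arange(c) + 0.5) * s - c * s / 2.0
    for _ in range(spec.crack_count):
        phi = rng.uniform(0, 2 * math.pi)
        n_y, n_x = math.cos(phi), math.sin(phi)
        plane_dist = np.abs(n_y * yy[None, :, None] + n_x * xx[None, None, :])
        half_plane = (n_x * yy[None, :, None] - n_y * xx[None, None, :]) >= 0
        slab = (plane_dist <= spec.crack_width_um / 2.0) & half_plane
        crack = slab & (labels == DEGRADATION_LAYER) & in_len & (
            rad2 > spec.rm_radius_um**2
        )
        labels[crack] = BACKGROUND


def render_grayscale(
    labels: LabelVolume, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> Volume:
    """Per-class Gaussian intensities plus optional interface ringing.

    The ringing term is a difference-of-Gaussian response of the piecewise
    class-mean image: a signed over/undershoot confined to a few voxels
    around each class boundary, mimicking propagation-based phase contrast.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    means = np.zeros(max(spec.intensity_means) + 1, dtype=np.float32)
    sigmas = np.zeros_like(means)
    for cls, m in spec.intensity_means.items():
        means[cls] = m
    for cls, sg in spec.intensity_sigmas.items():
        sigmas[cls] = sg
    mean_img = means[labels.data]
    img = mean_img + sigmas[labels.data] * rng.standard_normal(labels.shape).astype(
        np.float32
    )
    if spec.edge_enhancement:
        smooth = ndimage.gaussian_filter(mean_img, spec.edge_sigma_vox)
        img = img + spec.edge_amplitude * (mean_img - smooth)
    return Volume(np.clip(img, 0.0, 1.0).astype(np.float32), labels.geometry)
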