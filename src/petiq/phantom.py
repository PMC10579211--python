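"""Digital NEMA IEC image-quality phantom and synthetic clinical volumes.

The NEMA IEC body phantom is a torso-shaped shell (interior volume 9780 ml,
height 19.4 cm) carrying six fillable spheres (10, 13, 17, 22, 28 and 37 mm
inner diameter) on a ring in one transverse plane, and a low-density lung
insert along the central axis.  This module voxelizes that geometry into an
activity map with per-voxel region labels and an exact ground-truth
concentration per region, which is what recovery-coefficient and
contrast-recovery analysis needs.

Conventions
-----------
* Axis order is ``(z, y, x)`` for 3-D volumes and ``(y, x)`` for the 2-D
  single-slice fast mode; coordinates are voxel-center based, 0-indexed.
* The body cross-section is approximated as a half-ellipse on top of a
  rectangle, uniformly scaled so the analytic volume matches
  ``body_volume_ml`` — only the volume, not the exact outline, enters the
  downstream metrics.
* A voxel takes the label of its center point (no subsampling), a documented
  partial-volume bias of the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "GridSpec",
    "LabeledVolume",
    "SyntheticLesion",
    "PhantomError",
    "LABEL_OUTSIDE",
    "LABEL_BACKGROUND",
    "LABEL_LUNG",
    "LABEL_LIVER",
    "sphere_label",
    "build_nema_phantom",
    "build_clinical_synthetic",
    "BACKGROUND_KBQ_ML",
]

LABEL_OUTSIDE = 0
LABEL_BACKGROUND = 1
LABEL_LUNG = 2
LABEL_LIVER = 3
_SPHERE_BASE = 10
_LESION_BASE = 100

#: background activity concentration (kBq/ml) used at each lesion-to-background
#: ratio in the phantom study this package re-creates.
BACKGROUND_KBQ_ML = {2: 5.1, 4: 4.9, 8: 5.0}

# Unscaled body cross-section: half-ellipse (semi-axes RX0 x RY0) above a
# RX0*2 x RH0 rectangle.  Uniformly rescaled at build time to hit the target
# interior volume.
_RX0, _RY0, _RH0 = 150.0, 115.0, 115.0


def sphere_label(i: int) -> int:
    """Label id of the i-th sphere (0-based, smallest first)."""
    return _SPHERE_BASE + i


class PhantomError(ValueError):
    """Invalid phantom specification or voxelization request."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and activity description of the NEMA IEC phantom.

    ``lbr`` is the hot-sphere to background activity concentration ratio
    (a_H/a_B); sphere truth is ``background_activity_kbq_ml * lbr`` and the
    lung insert is cold (zero activity).
    """

    sphere_diameters_mm: tuple = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    background_activity_kbq_ml: float = 4.9
    lbr: float = 4.0
    lung_insert: bool = True
    lung_diameter_mm: float = 50.0
    body_volume_ml: float = 9780.0
    body_height_mm: float = 194.0
    sphere_ring_radius_mm: float = 57.2

    def __post_init__(self):
        d = np.asarray(self.sphere_diameters_mm, dtype=float)
        if d.size and (np.any(d <= 0) or np.any(np.diff(d) <= 0)):
            raise PhantomError(
                "sphere_diameters_mm must be positive and strictly increasing"
            )
        if self.lbr < 1:
            raise PhantomError("lbr must be >= 1")
        if self.background_activity_kbq_ml <= 0:
            raise PhantomError("background activity must be > 0")
        if self.body_volume_ml <= 0 or self.body_height_mm <= 0:
            raise PhantomError("body volume and height must be > 0")

    @classmethod
    def for_lbr(cls, lbr: float, **kwargs) -> "PhantomSpec":
        """Spec at one of the study's lesion-to-background ratios.

        The background concentration follows the filling scheme used per LBR
        (5.1, 4.9, 5.0 kBq/ml at 2:1, 4:1, 8:1); other ratios default to
        5.0 kBq/ml.
        """
        bg = BACKGROUND_KBQ_ML.get(int(lbr), 5.0)
        return cls(background_activity_kbq_ml=bg, lbr=float(lbr), **kwargs)

    # --- analytic geometry -------------------------------------------------

    def body_scale(self) -> float:
        """Uniform in-plane scale factor applied to the template outline."""
        target_area = self.body_volume_ml * 1000.0 / self.body_height_mm
        base_area = math.pi * _RX0 * _RY0 / 2.0 + 2.0 * _RX0 * _RH0
        return math.sqrt(target_area / base_area)

    def body_halfwidth_mm(self) -> float:
        return _RX0 * self.body_scale()

    def body_extent_mm(self):
        """(y_min, y_max, x_min, x_max) of the body outline, body center at 0."""
        s = self.body_scale()
        return (-_RH0 * s, _RY0 * s, -_RX0 * s, _RX0 * s)

    def inside_body(self, y_mm, x_mm):
        """Vectorized membership test of in-plane points in the body outline."""
        s = self.body_scale()
        rx, ry, rh = _RX0 * s, _RY0 * s, _RH0 * s
        y = np.asarray(y_mm, dtype=float)
        x = np.asarray(x_mm, dtype=float)
        upper = (y >= 0) & ((x / rx) ** 2 + (y / ry) ** 2 <= 1.0)
        lower = (y < 0) & (y >= -rh) & (np.abs(x) <= rx)
        return upper | lower

    def sphere_centers_mm(self):
        """In-plane (y, x) sphere centers on the standard ring.

        Spheres sit at 60-degree increments on a 57.2 mm ring; the smallest
        sphere is placed at 180 degrees (pointing -x) so the largest spheres
        fall in the upper half where background clearance is widest.
        """
        n = len(self.sphere_diameters_mm)
        centers = []
        for k in range(n):
            theta = math.radians(180.0 + k * 360.0 / max(n, 1))
            centers.append(
                (
                    self.sphere_ring_radius_mm * math.sin(theta),
                    self.sphere_ring_radius_mm * math.cos(theta),
                )
            )
        return centers

    def analytic_total_activity_kbq(self) -> float:
        """Total activity (kBq) implied by the spec, exact geometry."""
        sph_vol_ml = sum(
            4.0 / 3.0 * math.pi * (d / 2.0) ** 3 / 1000.0
            for d in self.sphere_diameters_mm
        )
        lung_vol_ml = 0.0
        if self.lung_insert:
            lung_vol_ml = (
                math.pi
                * (self.lung_diameter_mm / 2.0) ** 2
                * self.body_height_mm
                / 1000.0
            )
        bg_vol_ml = self.body_volume_ml - sph_vol_ml - lung_vol_ml
        return self.background_activity_kbq_ml * (bg_vol_ml + self.lbr * sph_vol_ml)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: ``shape`` and ``spacing_mm`` per axis, (z, y, x) order.

    The grid is centered on the phantom: world coordinate of voxel i along an
    axis is ``(i - (n - 1) / 2) * spacing``.
    """

    shape: tuple
    spacing_mm: tuple

    def __post_init__(self):
        if len(self.shape) != len(self.spacing_mm):
            raise PhantomError("shape and spacing dimensionality differ")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("spacing must be > 0")
        # in-plane axes need real extent; the z axis may be a thin stack
        if any(n < 16 for n in self.shape[-2:]) or any(n < 1 for n in self.shape):
            raise PhantomError("grid must be at least 16 voxels per in-plane axis")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        n, sp = self.shape[axis], self.spacing_mm[axis]
        return (np.arange(n) - (n - 1) / 2.0) * sp

    def voxel_volume_ml(self) -> float:
        v = float(np.prod(self.spacing_mm))
        if self.ndim == 2:  # treat a single slice as 1 voxel thick in z
            v *= 1.0
        return v / 1000.0

    @classmethod
    def default_3d(cls, spacing_mm: float = 2.0) -> "GridSpec":
        # generous margins around a ~272 x 209 x 194 mm body
        nx = int(math.ceil(320.0 / spacing_mm))
        ny = int(math.ceil(260.0 / spacing_mm))
        nz = int(math.ceil(220.0 / spacing_mm))
        return cls((nz, ny, nx), (spacing_mm,) * 3)

    @classmethod
    def fast_2d(cls, n: int = 128, spacing_mm: float = 2.5) -> "GridSpec":
        return cls((n, n), (spacing_mm, spacing_mm))


@dataclass
class LabeledVolume:
    """Voxelized activity map with region labels and ground truth.

    ``truth`` maps region label -> true concentration (kBq/ml); pre-noise
    volumes satisfy ``activity == truth[labels]`` voxel-wise.  ``meta`` keeps
    analytic geometry (sphere centers/radii in mm, grid) needed by ROI/VOI
    placement.
    """

    activity: np.ndarray
    labels: np.ndarray
    truth: dict
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.activity.shape != self.labels.shape:
            raise PhantomError("activity and labels must share a shape")

    @property
    def spacing_mm(self) -> tuple:
        return self.grid.spacing_mm

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def sphere_labels(self):
        return sorted(l for l in self.truth if _SPHERE_BASE <= l < _LESION_BASE)

    def voxel_counted_volume_ml(self) -> float:
        """Volume of all interior (non-outside) voxels, in ml."""
        n_inside = int(np.count_nonzero(self.labels != LABEL_OUTSIDE))
        return n_inside * self.grid.voxel_volume_ml()

    def total_activity_kbq(self) -> float:
        return float(self.activity.sum()) * self.grid.voxel_volume_ml()


def _world_grids(grid: GridSpec):
    """Broadcastable world-coordinate arrays (z, y, x) or (y, x)."""
    coords = [grid.axis_coords(a) for a in range(grid.ndim)]
    return np.meshgrid(*coords, indexing="ij", sparse=True)


def build_nema_phantom(spec: PhantomSpec, grid: GridSpec) -> LabeledVolume:
    """Voxelize the NEMA IEC phantom onto ``grid``.

    For 3-D grids the spheres lie in the transverse plane closest to the
    phantom mid-height; 2-D grids produce that single slice directly.

    Raises
    ------
    PhantomError
        If the grid is too coarse for the smallest sphere (must span >= 3
        voxels across) or if two spheres would overlap.
    """
    in_plane_spacing = max(grid.spacing_mm[-1], grid.spacing_mm[-2])
    dmin = min(spec.sphere_diameters_mm)
    if dmin / in_plane_spacing < 3.0:
        raise PhantomError(
            f"grid too coarse: {dmin:g} mm sphere spans "
            f"{dmin / in_plane_spacing:.2f} < 3 voxels"
        )

    centers = spec.sphere_centers_mm()
    radii = [d / 2.0 for d in spec.sphere_diameters_mm]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dist = math.hypot(
                centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
            )
            if dist < radii[i] + radii[j]:
                raise PhantomError(f"spheres {i} and {j} overlap on the ring")
    if spec.lung_insert:
        for i, (cy, cx) in enumerate(centers):
            if math.hypot(cy, cx) < radii[i] + spec.lung_diameter_mm / 2.0:
                raise PhantomError(f"sphere {i} overlaps the lung insert")

    if grid.ndim == 3:
        Z, Y, X = _world_grids(grid)
    else:
        Y, X = _world_grids(grid)
        Z = None

    labels = np.zeros(grid.shape, dtype=np.int16)
    body = spec.inside_body(Y, X)
    if Z is not None:
        body = body & (np.abs(Z) <= spec.body_height_mm / 2.0)
    labels[body] = LABEL_BACKGROUND

    if spec.lung_insert:
        lung = (Y**2 + X**2) <= (spec.lung_diameter_mm / 2.0) ** 2
        labels[body & lung] = LABEL_LUNG

    # sphere plane: transverse slice nearest mid-height
    if Z is not None:
        zc = grid.axis_coords(0)
        plane_z = float(zc[np.argmin(np.abs(zc))])
    else:
        plane_z = 0.0

    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        d2 = (Y - cy) ** 2 + (X - cx) ** 2
        if Z is not None:
            d2 = d2 + (Z - plane_z) ** 2
        mask = d2 <= r**2
        if not mask.any():
            raise PhantomError(f"sphere {i} captured no voxels")
        labels[mask & body] = sphere_label(i)

    bg = spec.background_activity_kbq_ml
    truth = {LABEL_OUTSIDE: 0.0, LABEL_BACKGROUND: bg}
    if spec.lung_insert:
        truth[LABEL_LUNG] = 0.0
    for i in range(len(centers)):
        truth[sphere_label(i)] = bg * spec.lbr

    activity = np.zeros(grid.shape, dtype=float)
    for lab, val in truth.items():
        if val:
            activity[labels == lab] = val

    meta = {
        "sphere_centers_mm": [(plane_z, cy, cx) for (cy, cx) in centers],
        "sphere_diameters_mm": list(spec.sphere_diameters_mm),
        "sphere_plane_z_mm": plane_z,
        "lung_center_mm": (0.0, 0.0),
        "lung_diameter_mm": spec.lung_diameter_mm if spec.lung_insert else None,
        "lbr": spec.lbr,
        "background_kbq_ml": bg,
    }
    return LabeledVolume(activity, labels, truth, grid, meta)


# ---------------------------------------------------------------------------
# synthetic clinical volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticLesion:
    """Ground truth for one synthetic lesion."""

    lesion_id: int
    size_group: str  # "small" (<= 10 mm) or "large" (> 10 mm)
    diameter_mm: float
    center_mm: tuple
    suv: float
    label: int


def build_clinical_synthetic(
    n_small: int = 27,
    n_large: int = 18,
    liver_suv_mean: float = 2.2,
    lesion_suv_median: float = 17.0,
    lesion_suv_sigma_log: float = 0.45,
    noise_sd: float = 0.15,
    seed: int = 0,
    grid: GridSpec | None = None,
    max_retries: int = 200,
):
    """Synthetic whole-body-like volume: liver slab + spherical lesions.

    Emulates the structure of the clinical arm (27 lesions <= 10 mm and 18
    lesions > 10 mm over a cohort with liver SUVmean ~2.2): a rectangular
    liver slab at ``liver_suv_mean`` with additive Gaussian noise of SD
    ``noise_sd`` and lesions with SUV drawn lognormally (median
    ``lesion_suv_median``, log-SD ``lesion_suv_sigma_log``, matched to the
    spread of the small-lesion table).  Lesions are kept out of the liver
    region so liver-noise ROIs stay lesion-free.

    Returns ``(volume, lesions)`` where ``lesions`` is the ground-truth list.
    """
    if n_small < 0 or n_large < 0:
        raise PhantomError("lesion counts must be >= 0")
    if grid is None:
        grid = GridSpec((48, 96, 96), (4.0, 4.0, 4.0))
    if grid.ndim != 3:
        raise PhantomError("clinical synthetic volumes are 3-D")

    rng = np.random.default_rng(seed)
    nz, ny, nx = grid.shape
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[:] = LABEL_BACKGROUND

    # liver slab occupies a fixed block in the upper-left of the volume
    liver_slc = (
        slice(nz // 4, nz // 4 + max(6, nz // 3)),
        slice(ny // 8, ny // 8 + ny // 3),
        slice(nx // 8, nx // 8 + nx // 2),
    )
    labels[liver_slc] = LABEL_LIVER

    activity = np.ones(grid.shape, dtype=float)  # soft-tissue background SUV 1
    liver_mask = labels == LABEL_LIVER
    activity[liver_mask] = liver_suv_mean + noise_sd * rng.standard_normal(
        int(liver_mask.sum())
    )

    # exclusion zone: liver block plus one lesion-diameter margin
    coords = _world_grids(grid)
    zc = grid.axis_coords(0)
    yc = grid.axis_coords(1)
    xc = grid.axis_coords(2)
    liver_lo = np.array([zc[liver_slc[0].start], yc[liver_slc[1].start], xc[liver_slc[2].start]])
    liver_hi = np.array(
        [zc[liver_slc[0].stop - 1], yc[liver_slc[1].stop - 1], xc[liver_slc[2].stop - 1]]
    )

    lesions = []
    specs = [("small", rng.uniform(6.0, 10.0)) for _ in range(n_small)] + [
        ("large", rng.uniform(12.0, 30.0)) for _ in range(n_large)
    ]
    extent = [
        (zc[0] + 20.0, zc[-1] - 20.0),
        (yc[0] + 20.0, yc[-1] - 20.0),
        (xc[0] + 20.0, xc[-1] - 20.0),
    ]
    for idx, (group, diam) in enumerate(specs):
        r = diam / 2.0
        placed = False
        for _ in range(max_retries):
            c = np.array([rng.uniform(lo, hi) for lo, hi in extent])
            # reject if sphere (with margin) intersects the liver block
            nearest = np.clip(c, liver_lo, liver_hi)
            if np.linalg.norm(c - nearest) < r + 10.0:
                continue
            taken = [l for l in lesions if np.linalg.norm(np.array(l.center_mm) - c) < r + l.diameter_mm / 2 + 4.0]
            if taken:
                continue
            placed = True
            break
        if not placed:
            raise PhantomError(f"could not place lesion {idx} after {max_retries} tries")
        suv = lesion_suv_median * math.exp(lesion_suv_sigma_log * rng.standard_normal())
        lab = _LESION_BASE + idx
        d2 = (
            (coords[0] - c[0]) ** 2 + (coords[1] - c[1]) ** 2 + (coords[2] - c[2]) ** 2
        )
        mask = d2 <= r**2
        labels[mask] = lab
        activity[mask] = suv
        lesions.append(
            SyntheticLesion(idx + 1, group, float(diam), tuple(c), float(suv), lab)
        )

    truth = {LABEL_BACKGROUND: 1.0, LABEL_LIVER: liver_suv_mean}
    truth.update({l.label: l.suv for l in lesions})
    meta = {"liver_slices": (liver_slc[0].start, liver_slc[0].stop)}
    vol = LabeledVolume(activity, labels, truth, grid, meta)
    return vol, lesions
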