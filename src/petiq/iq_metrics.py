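"""NEMA phantom image-quality analysis: ROI/VOI placement and metrics.

Implements the standard phantom read-out: 10 mm background ROIs placed on the
central sphere slice and the two slices on either side (12 per slice, 60
total), kept at least 15 mm clear of every sphere surface and of the phantom
edge; one spherical VOI per hot sphere with diameter equal to the sphere's
physical inner diameter; and the derived metrics

* CR  = ((C_H/C_B) - 1) / (a_H/a_B - 1)          (contrast recovery)
* RC  = measured mean / true concentration        (recovery coefficient)
* BV  = SD / mean over background-ROI means, in % (background variability,
        the coefficient of variation used as the noise surrogate)
* LE  = lung mean / background mean, in %         (lung residual error)
* contrast = VOI mean / background mean
* SNR = VOI mean / background SD
* SUVmax analog = VOI max / true background concentration (ideal value = LBR)

and the pairwise relative difference used to compare reconstructions:

    delta_feature(a-b)% = (feature_a - feature_b) / feature_a * 100

Conventions: population SD (ddof=0) everywhere; the background mean is the
mean of per-ROI means; "mean count" and "mean activity" both mean the mean
voxel value in calibrated concentration units (the units cancel in every
ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .phantom import LABEL_BACKGROUND, LABEL_LUNG, LABEL_OUTSIDE, LabeledVolume

__all__ = [
    "ROI",
    "ROISet",
    "VOI",
    "VOISet",
    "MetricsTable",
    "ComparisonResult",
    "PlacementError",
    "central_sphere_slice",
    "place_background_rois",
    "place_sphere_vois",
    "contrast_recovery",
    "recovery_coefficient",
    "background_variability",
    "lung_error",
    "sphere_contrast_and_snr",
    "relative_difference",
    "build_metrics_table",
    "lung_mean",
]


class PlacementError(RuntimeError):
    """ROI placement could not satisfy the clearance constraints."""


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ROI:
    slice_index: int | None  # None for 2-D volumes
    center_mm: tuple  # in-plane (y, x)
    diameter_mm: float
    voxel_index: tuple  # arrays indexing member voxels in the full volume

    def values(self, image: np.ndarray) -> np.ndarray:
        return image[self.voxel_index]

    def mean(self, image) -> float:
        return float(self.values(image).mean())

    def sd(self, image) -> float:
        return float(self.values(image).std(ddof=0))


@dataclass
class ROISet:
    rois: list
    clearance_mm: float
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.rois)

    def means(self, image) -> np.ndarray:
        return np.array([r.mean(image) for r in self.rois])

    def background_mean(self, image) -> float:
        return float(self.means(image).mean())

    def background_sd(self, image) -> float:
        """Population SD over per-ROI means."""
        return float(self.means(image).std(ddof=0))


@dataclass(frozen=True)
class VOI:
    sphere_index: int
    center_mm: tuple
    diameter_mm: float
    voxel_index: tuple

    def mean(self, image) -> float:
        return float(image[self.voxel_index].mean())

    def max(self, image) -> float:
        return float(image[self.voxel_index].max())

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_index[0])


@dataclass
class VOISet:
    vois: list

    def __iter__(self):
        return iter(self.vois)

    def __len__(self):
        return len(self.vois)


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    recon_a: str
    recon_b: str
    feature_a: float
    feature_b: float
    delta_pct: float


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def central_sphere_slice(vol: LabeledVolume) -> int:
    """Transverse slice maximizing total sphere cross-sectional area."""
    if vol.labels.ndim == 2:
        return 0
    if vol.meta.get("replicated_2d"):
        return vol.labels.shape[0] // 2
    sphere = np.isin(vol.labels, vol.sphere_labels())
    per_slice = sphere.reshape(sphere.shape[0], -1).sum(axis=1)
    if per_slice.max() == 0:
        raise PlacementError("volume contains no sphere voxels")
    return int(per_slice.argmax())


def _slice_geometry(vol: LabeledVolume, k: int | None):
    """2-D label slice plus (y, x) coordinate vectors."""
    grid = vol.grid
    if vol.labels.ndim == 2:
        lab2d = vol.labels
        ax_y, ax_x = 0, 1
    else:
        lab2d = vol.labels[k]
        ax_y, ax_x = 1, 2
    return lab2d, grid.axis_coords(ax_y), grid.axis_coords(ax_x)


def _sphere_surface_distance(vol: LabeledVolume, y: float, x: float, z: float) -> float:
    """Distance (mm) from a point to the nearest sphere *surface*."""
    best = np.inf
    for (cz, cy, cx), d in zip(
        vol.meta["sphere_centers_mm"], vol.meta["sphere_diameters_mm"]
    ):
        dist = math.sqrt((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) - d / 2.0
        best = min(best, dist)
    return best


def _circle_index(lab2d_shape, yc_mm, xc_mm, ycoords, xcoords, radius_mm):
    Y, X = np.meshgrid(ycoords, xcoords, indexing="ij")
    return np.nonzero((Y - yc_mm) ** 2 + (X - xc_mm) ** 2 <= radius_mm**2)


def place_background_rois(
    vol: LabeledVolume,
    roi_diameter_mm: float = 10.0,
    clearance_mm: float = 15.0,
    n_per_slice: int = 12,
    n_slices: int = 5,
) -> ROISet:
    """Deterministic background-ROI placement.

    ROIs are laid out on a fixed angular template (offset 15 degrees from the
    sphere ring so no ROI ray points straight at a sphere), each shifted
    greedily inward from the phantom edge until its center clears every
    sphere surface and the body edge by ``clearance_mm``.  Slices are the
    central sphere slice plus ``(n_slices - 1) / 2`` slices on either side.

    Raises :class:`PlacementError` if any requested ROI cannot be placed.
    """
    grid = vol.grid
    is2d = vol.labels.ndim == 2
    if is2d and n_slices != 1:
        raise PlacementError("2-D volume has a single slice; use n_slices=1")
    if n_slices < 1 or n_slices % 2 == 0:
        raise PlacementError("n_slices must be odd (central slice +/- k)")

    kc = central_sphere_slice(vol)
    half = (n_slices - 1) // 2
    plane_z = vol.meta.get("sphere_plane_z_mm", 0.0)
    if not is2d:
        if kc - half < 0 or kc + half >= grid.shape[0]:
            raise PlacementError("requested slices fall outside the volume")
        slice_ids = list(range(kc - half, kc + half + 1))
        if vol.meta.get("replicated_2d"):
            # replicate slices are independent realizations of the sphere plane
            z_of = {k: plane_z for k in slice_ids}
        else:
            z_of = {k: float(grid.axis_coords(0)[k]) for k in slice_ids}
    else:
        slice_ids = [None]
        z_of = {None: plane_z}

    roi_r = roi_diameter_mm / 2.0
    edge_clear = max(clearance_mm, roi_r)
    rois = []
    for k in slice_ids:
        lab2d, ycoords, xcoords = _slice_geometry(vol, k)
        inside = lab2d != LABEL_OUTSIDE
        if not inside.any():
            raise PlacementError(f"slice {k}: no body voxels")
        dy, dx = (
            (grid.spacing_mm[1], grid.spacing_mm[2])
            if not is2d
            else grid.spacing_mm
        )
        edge_dist = distance_transform_edt(inside, sampling=(dy, dx))

        if n_per_slice == 1:
            roi = _place_farthest(
                vol, k, lab2d, ycoords, xcoords, edge_dist, roi_r, clearance_mm,
                edge_clear, z_of[k],
            )
            rois.append(roi)
            continue

        placed_here = []
        angles = [
            math.radians(15.0 + i * 360.0 / n_per_slice) for i in range(n_per_slice)
        ]
        r_hi = float(max(abs(ycoords).max(), abs(xcoords).max()))
        for ang in angles:
            uy, ux = math.sin(ang), math.cos(ang)
            found = None
            for r in np.arange(r_hi, roi_diameter_mm, -1.0):
                yc, xc = r * uy, r * ux
                iy = int(round((yc - ycoords[0]) / dy))
                ix = int(round((xc - xcoords[0]) / dx))
                if not (0 <= iy < lab2d.shape[0] and 0 <= ix < lab2d.shape[1]):
                    continue
                if edge_dist[iy, ix] < edge_clear:
                    continue
                if _sphere_surface_distance(vol, yc, xc, z_of[k]) < clearance_mm:
                    continue
                if any(
                    math.hypot(yc - p.center_mm[0], xc - p.center_mm[1])
                    < roi_diameter_mm
                    for p in placed_here
                ):
                    continue
                found = (yc, xc)
                break
            if found is None:
                raise PlacementError(
                    f"slice {k}, angle {math.degrees(ang):.0f} deg: no radius "
                    f"satisfies clearance {clearance_mm} mm from spheres and edge"
                )
            idx2d = _circle_index(lab2d.shape, *found, ycoords, xcoords, roi_r)
            if not np.all(lab2d[idx2d] == LABEL_BACKGROUND):
                raise PlacementError(
                    f"slice {k}: ROI at {found} not fully in background"
                )
            voxel_index = idx2d if is2d else (np.full(idx2d[0].shape, k),) + idx2d
            roi = ROI(k, found, roi_diameter_mm, voxel_index)
            placed_here.append(roi)
            rois.append(roi)
    return ROISet(rois, clearance_mm, meta={"central_slice": kc, "n_slices": n_slices})


def _place_farthest(vol, k, lab2d, ycoords, xcoords, edge_dist, roi_r, clearance_mm,
                    edge_clear, z_mm):
    """Single-ROI case: the feasible center farthest from all sphere surfaces."""
    best, best_d = None, -np.inf
    for iy in range(lab2d.shape[0]):
        for ix in range(lab2d.shape[1]):
            if edge_dist[iy, ix] < edge_clear:
                continue
            yc, xc = float(ycoords[iy]), float(xcoords[ix])
            d = _sphere_surface_distance(vol, yc, xc, z_mm)
            if d >= clearance_mm and d > best_d:
                best, best_d = (yc, xc), d
    if best is None:
        raise PlacementError("no feasible single-ROI position")
    idx2d = _circle_index(lab2d.shape, *best, ycoords, xcoords, roi_r)
    is2d = vol.labels.ndim == 2
    voxel_index = idx2d if is2d else (np.full(idx2d[0].shape, k),) + idx2d
    return ROI(k, best, 2 * roi_r, voxel_index)


def place_sphere_vois(vol: LabeledVolume) -> VOISet:
    """One VOI per hot sphere, centered on truth, diameter = inner diameter."""
    grid = vol.grid
    is2d = vol.labels.ndim == 2
    vois = []
    for i, ((cz, cy, cx), d) in enumerate(
        zip(vol.meta["sphere_centers_mm"], vol.meta["sphere_diameters_mm"])
    ):
        r = d / 2.0
        if is2d:
            Y, X = np.meshgrid(grid.axis_coords(0), grid.axis_coords(1), indexing="ij")
            idx = np.nonzero((Y - cy) ** 2 + (X - cx) ** 2 <= r**2)
        elif vol.meta.get("replicated_2d"):
            # every slice is an independent realization of the sphere plane:
            # pool the in-plane circle across all slices
            Y, X = np.meshgrid(grid.axis_coords(1), grid.axis_coords(2), indexing="ij")
            iy, ix = np.nonzero((Y - cy) ** 2 + (X - cx) ** 2 <= r**2)
            nz = grid.shape[0]
            idx = (
                np.repeat(np.arange(nz), iy.size),
                np.tile(iy, nz),
                np.tile(ix, nz),
            )
        else:
            Z, Y, X = np.meshgrid(
                grid.axis_coords(0),
                grid.axis_coords(1),
                grid.axis_coords(2),
                indexing="ij",
                sparse=False,
            )
            idx = np.nonzero((Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2 <= r**2)
        if len(idx[0]) == 0:
            raise PlacementError(f"sphere {i} VOI captured no voxels")
        vois.append(VOI(i, (cz, cy, cx), d, idx))
    return VOISet(vois)


def lung_mean(vol: LabeledVolume, image: np.ndarray, roi_diameter_mm: float = 30.0) -> float:
    """Mean value in a 30 mm ROI at the lung-insert center, central slice."""
    if vol.meta.get("lung_diameter_mm") is None:
        raise MetricError("phantom has no lung insert")
    k = central_sphere_slice(vol)
    lab2d, ycoords, xcoords = _slice_geometry(vol, None if vol.labels.ndim == 2 else k)
    cy, cx = vol.meta["lung_center_mm"]
    idx2d = _circle_index(lab2d.shape, cy, cx, ycoords, xcoords, roi_diameter_mm / 2.0)
    if image.ndim == 2:
        return float(image[idx2d].mean())
    if vol.meta.get("replicated_2d"):  # pool the lung ROI across replicate slices
        return float(image[:, idx2d[0], idx2d[1]].mean())
    return float(image[k][idx2d].mean())


# ---------------------------------------------------------------------------
# metric definitions
# ---------------------------------------------------------------------------


def contrast_recovery(c_h: float, c_b: float, ratio: float) -> float:
    """CR = ((C_H/C_B) - 1) / (a_H/a_B - 1)."""
    if c_b <= 0:
        raise MetricError("background mean must be > 0")
    if ratio <= 1:
        raise MetricError("CR undefined for hot:background ratio <= 1")
    return ((c_h / c_b) - 1.0) / (ratio - 1.0)


def recovery_coefficient(measured_mean: float, true_value: float) -> float:
    """RC = measured / true; the ideal value is 1."""
    if true_value <= 0:
        raise MetricError("true value must be > 0")
    return measured_mean / true_value


def background_variability(roiset: ROISet, image: np.ndarray) -> float:
    """BV (%) = population SD / mean over the background-ROI means."""
    if len(roiset) < 2:
        raise MetricError("BV needs at least 2 ROIs")
    means = roiset.means(image)
    mu = means.mean()
    if mu == 0:
        raise MetricError("background mean is zero")
    return float(means.std(ddof=0) / mu * 100.0)


def lung_error(lung_mean_value: float, background_mean: float) -> float:
    """LE (%) = lung mean / background mean * 100."""
    if background_mean <= 0:
        raise MetricError("background mean must be > 0")
    return lung_mean_value / background_mean * 100.0


def sphere_contrast_and_snr(voi_mean: float, bg_mean: float, bg_sd: float):
    """contrast = VOI mean / BG mean; SNR = VOI mean / BG SD."""
    if bg_mean <= 0:
        raise MetricError("background mean must be > 0")
    if bg_sd == 0:
        raise MetricError("SNR undefined for zero background SD")
    return voi_mean / bg_mean, voi_mean / bg_sd


def relative_difference(feature_a: float, feature_b: float) -> float:
    """Signed percent difference (a - b) / a * 100.

    The denominator is feature_a by convention, so swapping the pair changes
    the magnitude as well as the sign.
    """
    if feature_a == 0:
        raise MetricError("relative difference undefined for feature_a == 0")
    return (feature_a - feature_b) / feature_a * 100.0


# ---------------------------------------------------------------------------
# full table
# ---------------------------------------------------------------------------


@dataclass
class MetricsTable:
    """Per-(reconstruction, sphere) metrics plus per-reconstruction BV/LE.

    ``sphere_metrics`` columns: recon, sphere_index, diameter_mm, CR, RC,
    contrast, SNR, suvmax.  ``recon_metrics`` columns: recon, BV_pct, LE_pct,
    background_mean.
    """

    sphere_metrics: pd.DataFrame
    recon_metrics: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def sphere_value(self, recon: str, diameter_mm: float, metric: str) -> float:
        df = self.sphere_metrics
        row = df[(df.recon == recon) & (df.diameter_mm == diameter_mm)]
        if len(row) != 1:
            raise MetricError(f"no unique row for {recon}, {diameter_mm} mm")
        return float(row[metric].iloc[0])

    def recon_value(self, recon: str, metric: str) -> float:
        df = self.recon_metrics
        row = df[df.recon == recon]
        if len(row) != 1:
            raise MetricError(f"no unique row for {recon}")
        return float(row[metric].iloc[0])

    def compare(self, metric: str, recon_a: str, recon_b: str,
                diameter_mm: float | None = None) -> ComparisonResult:
        if diameter_mm is None:
            fa = self.recon_value(recon_a, metric)
            fb = self.recon_value(recon_b, metric)
        else:
            fa = self.sphere_value(recon_a, diameter_mm, metric)
            fb = self.sphere_value(recon_b, diameter_mm, metric)
        return ComparisonResult(
            metric, recon_a, recon_b, fa, fb, relative_difference(fa, fb)
        )

    def to_tidy(self) -> pd.DataFrame:
        """One row per reconstruction x sphere x metric (long format)."""
        long = self.sphere_metrics.melt(
            id_vars=["recon", "sphere_index", "diameter_mm"],
            var_name="metric",
            value_name="value",
        )
        per_recon = self.recon_metrics.melt(
            id_vars=["recon"], var_name="metric", value_name="value"
        )
        return pd.concat([long, per_recon], ignore_index=True)


def build_metrics_table(
    recons,
    phantom: LabeledVolume,
    roiset: ROISet | None = None,
    roi_kwargs: dict | None = None,
) -> MetricsTable:
    """Full NEMA read-out for a list of reconstructions of one phantom.

    ``recons`` is a list of ReconResult (or ``(label, image)`` pairs); all
    images must live on the phantom grid.  The SUVmax analog is the VOI max
    divided by the true background concentration, so its ideal hot-sphere
    value equals the LBR.
    """
    if roiset is None:
        kwargs = dict(roi_kwargs or {})
        if phantom.labels.ndim == 2:
            kwargs.setdefault("n_slices", 1)
        roiset = place_background_rois(phantom, **kwargs)
    vois = place_sphere_vois(phantom)
    bg_truth = phantom.truth[LABEL_BACKGROUND]
    lbr = phantom.meta["lbr"]

    sphere_rows, recon_rows = [], []
    for item in recons:
        if hasattr(item, "image"):
            label, image = item.label, item.image
        else:
            label, image = item
        if image.shape != phantom.labels.shape:
            raise MetricError(f"{label}: image grid differs from phantom grid")
        c_b = roiset.background_mean(image)
        bg_sd = roiset.background_sd(image)
        for voi in vois:
            c_h = voi.mean(image)
            if bg_sd == 0:  # noiseless ideal limit: SNR diverges
                contrast, snr = c_h / c_b, np.inf
            else:
                contrast, snr = sphere_contrast_and_snr(c_h, c_b, bg_sd)
            sphere_rows.append(
                {
                    "recon": label,
                    "sphere_index": voi.sphere_index,
                    "diameter_mm": voi.diameter_mm,
                    "CR": contrast_recovery(c_h, c_b, lbr),
                    "RC": recovery_coefficient(c_h, bg_truth * lbr),
                    "contrast": contrast,
                    "SNR": snr,
                    "suvmax": voi.max(image) / bg_truth,
                }
            )
        row = {
            "recon": label,
            "BV_pct": background_variability(roiset, image),
            "background_mean": c_b,
        }
        if phantom.meta.get("lung_diameter_mm") is not None:
            row["LE_pct"] = lung_error(lung_mean(phantom, image), c_b)
        recon_rows.append(row)
    return MetricsTable(
        pd.DataFrame(sphere_rows),
        pd.DataFrame(recon_rows),
        meta={"lbr": lbr, "n_rois": len(roiset)},
    )
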