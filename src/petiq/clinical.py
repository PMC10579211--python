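"""Clinical-arm analysis: lesion table, liver noise, SNR/SBR, group summaries.

The clinical study behind this analysis measured SUVmax of 45 rectal-cancer
lesions (27 with diameter <= 10 mm, 18 with diameter > 10 mm; 15 primary
rectal tumors, 12 lung metastases, 18 pelvic metastases) under six
reconstructions: BSREM with penalization factors 100-500 and routine OSEM.
The per-lesion values ship with this package as a version-pinned CSV
transcription (``data/table1_lesions.csv``); every clinical number downstream
flows from that file, never from constants in code.

Liver-based noise follows the standard read-out: nine 30 mm ROIs across the
three largest liver slices; liver noise = SD / mean of the ROI means;
SNR = lesion SUVmax / liver noise; SBR = lesion SUVmax / liver SUVmean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .iq_metrics import ROI, ROISet, PlacementError, relative_difference
from .phantom import LABEL_LIVER, LabeledVolume

__all__ = [
    "RECON_IDS",
    "BETA_IDS",
    "LesionRecord",
    "LiverStats",
    "FixtureError",
    "fixture_path",
    "load_lesion_fixture",
    "lesion_table",
    "liver_metrics",
    "lesion_snr_sbr",
    "summarize_groups",
    "monotone_beta_exceptions",
    "group_mean_table",
]

BETA_IDS = ("beta100", "beta200", "beta300", "beta400", "beta500")
RECON_IDS = BETA_IDS + ("osem",)
_EXPECTED_COUNTS = {"total": 45, "small": 27, "large": 18}
_EXPECTED_TYPES = {
    "primary_rectal": 15,
    "lung_metastasis": 12,
    "pelvic_metastasis": 18,
}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    size_group: str  # "small" (<= 10 mm) or "large" (> 10 mm)
    tumor_type: str
    values: dict  # reconstruction id -> SUVmax

    def __post_init__(self):
        missing = [r for r in RECON_IDS if r not in self.values]
        if missing:
            raise FixtureError(f"{self.lesion_id}: missing values for {missing}")
        bad = [r for r in RECON_IDS if not self.values[r] > 0]
        if bad:
            raise FixtureError(f"{self.lesion_id}: non-positive values for {bad}")


@dataclass
class LiverStats:
    roiset: ROISet
    roi_means: np.ndarray
    liver_suv_mean: float
    liver_noise: float  # SD / mean over ROI means
    meta: dict = field(default_factory=dict)


def fixture_path() -> Path:
    return Path(resources.files("petiq.data") / "table1_lesions.csv")


def lesion_table(path=None) -> pd.DataFrame:
    """Raw lesion table as a DataFrame, validated."""
    path = Path(path) if path is not None else fixture_path()
    if not path.exists():
        raise FixtureError(f"lesion fixture not found: {path}")
    df = pd.read_csv(path)
    required = ["lesion_id", "size_group", "tumor_type", *RECON_IDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FixtureError(f"fixture missing columns: {missing}")
    if df["lesion_id"].duplicated().any():
        dup = df.loc[df["lesion_id"].duplicated(), "lesion_id"].tolist()
        raise FixtureError(f"duplicate lesion ids: {dup}")
    n_small = int((df.size_group == "small").sum())
    n_large = int((df.size_group == "large").sum())
    if len(df) != _EXPECTED_COUNTS["total"] or n_small != _EXPECTED_COUNTS["small"]:
        raise FixtureError(
            f"expected 45 lesions (27 small / 18 large), got {len(df)} "
            f"({n_small} small / {n_large} large)"
        )
    types = df.tumor_type.value_counts().to_dict()
    if types != _EXPECTED_TYPES:
        raise FixtureError(f"tumor-type counts {types} != {_EXPECTED_TYPES}")
    bad = df[df[list(RECON_IDS)].le(0).any(axis=1)]
    if len(bad):
        raise FixtureError(f"non-positive values in rows {bad.lesion_id.tolist()}")
    return df


def load_lesion_fixture(path=None):
    """Parse the packaged lesion table into LesionRecord objects."""
    df = lesion_table(path)
    return [
        LesionRecord(
            r.lesion_id,
            r.size_group,
            r.tumor_type,
            {rid: float(getattr(r, rid)) for rid in RECON_IDS},
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# liver ROIs and noise
# ---------------------------------------------------------------------------


def liver_metrics(
    volume: LabeledVolume,
    roi_diameter_mm: float = 30.0,
    n_rois: int = 9,
    n_slices: int = 3,
) -> LiverStats:
    """Place 30 mm liver ROIs and compute liver SUVmean and noise.

    ROIs are distributed over the ``n_slices`` transverse slices with the
    largest liver cross-section, ``n_rois / n_slices`` per slice, placed
    deterministically (raster scan of feasible centers, greedy non-overlap).
    """
    labels = volume.labels
    if labels.ndim != 3:
        raise PlacementError("liver metrics need a 3-D volume")
    liver = labels == LABEL_LIVER
    if not liver.any():
        raise PlacementError("no liver region in labels")
    if n_rois % n_slices:
        raise PlacementError("n_rois must be divisible by n_slices")
    per_slice = n_rois // n_slices

    area = liver.reshape(liver.shape[0], -1).sum(axis=1)
    slice_ids = sorted(np.argsort(area)[::-1][:n_slices].tolist())
    if area[slice_ids[-1]] == 0:
        raise PlacementError("fewer liver-bearing slices than requested")

    grid = volume.grid
    dy, dx = grid.spacing_mm[1], grid.spacing_mm[2]
    ycoords, xcoords = grid.axis_coords(1), grid.axis_coords(2)
    roi_r = roi_diameter_mm / 2.0
    rois = []
    for k in slice_ids:
        mask = liver[k]
        inner = distance_transform_edt(mask, sampling=(dy, dx)) >= roi_r
        feas = np.argwhere(inner)
        placed = []
        for iy, ix in feas:  # raster order -> deterministic
            yc, xc = float(ycoords[iy]), float(xcoords[ix])
            if any(
                np.hypot(yc - p[0], xc - p[1]) < roi_diameter_mm for p in placed
            ):
                continue
            Y, X = np.meshgrid(ycoords, xcoords, indexing="ij")
            idx2d = np.nonzero((Y - yc) ** 2 + (X - xc) ** 2 <= roi_r**2)
            voxel_index = (np.full(idx2d[0].shape, k),) + idx2d
            rois.append(ROI(int(k), (yc, xc), roi_diameter_mm, voxel_index))
            placed.append((yc, xc))
            if len(placed) == per_slice:
                break
        if len(placed) < per_slice:
            raise PlacementError(
                f"slice {k}: liver too small for {per_slice} x "
                f"{roi_diameter_mm:g} mm ROIs"
            )
    roiset = ROISet(rois, clearance_mm=0.0, meta={"slices": slice_ids})
    means = roiset.means(volume.activity)
    mu = float(means.mean())
    noise = float(means.std(ddof=0) / mu)
    return LiverStats(roiset, means, mu, noise, meta={"slices": slice_ids})


def lesion_snr_sbr(record: LesionRecord, liver: LiverStats, recon_id: str):
    """SNR = SUVmax / liver noise; SBR = SUVmax / liver SUVmean."""
    if recon_id not in record.values:
        raise FixtureError(f"unknown reconstruction id {recon_id!r}")
    if liver.liver_noise <= 0:
        raise FixtureError("SNR undefined for zero liver noise")
    if liver.liver_suv_mean <= 0:
        raise FixtureError("SBR undefined for non-positive liver mean")
    suvmax = record.values[recon_id]
    return suvmax / liver.liver_noise, suvmax / liver.liver_suv_mean


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


def summarize_groups(
    records,
    pair,
    metric: str = "suvmax",
    aggregation: str = "mean_of_ratios",
):
    """Group-level relative difference between two reconstructions.

    ``aggregation='mean_of_ratios'`` averages the per-lesion relative
    differences; ``'ratio_of_means'`` applies the relative difference to the
    group means.  Both are provided because the two differ and the source
    analysis does not state which it used.

    Returns ``{size_group: delta_pct}``.
    """
    recon_a, recon_b = pair
    if aggregation not in ("mean_of_ratios", "ratio_of_means"):
        raise FixtureError(f"unknown aggregation {aggregation!r}")
    if metric != "suvmax":
        raise FixtureError("only the SUVmax series is tabulated per lesion")
    groups: dict = {}
    for rec in records:
        groups.setdefault(rec.size_group, []).append(rec)
    out = {}
    for group, recs in sorted(groups.items()):
        if not recs:
            raise FixtureError(f"empty group {group}")
        a = np.array([r.values[recon_a] for r in recs])
        b = np.array([r.values[recon_b] for r in recs])
        if aggregation == "mean_of_ratios":
            out[group] = float(np.mean((a - b) / a * 100.0))
        else:
            out[group] = relative_difference(float(a.mean()), float(b.mean()))
    return out


def monotone_beta_exceptions(records):
    """Lesions whose SUVmax is not non-increasing along beta 100 -> 500.

    The dominant trend is monotone decrease with increasing penalization;
    the handful of table rows violating it (non-monotonic mid-beta entries)
    are reported explicitly, not silently passed.
    """
    exceptions = []
    for rec in records:
        series = [rec.values[b] for b in BETA_IDS]
        if any(later > earlier for earlier, later in zip(series, series[1:])):
            exceptions.append(rec.lesion_id)
    return exceptions


def group_mean_table(records) -> pd.DataFrame:
    """Group-mean SUVmax per reconstruction (rows: size group)."""
    rows = []
    for group in ("small", "large"):
        recs = [r for r in records if r.size_group == group]
        rows.append(
            {"size_group": group, "n": len(recs)}
            | {rid: float(np.mean([r.values[rid] for r in recs])) for rid in RECON_IDS}
        )
    return pd.DataFrame(rows)
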