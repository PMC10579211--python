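"""Slice-wise parallel-beam forward model with detector blur and Poisson noise.

The acquisition model is deliberately simple — a 2-D parallel-beam Radon
transform per transverse slice, a radial Gaussian point-spread function in the
projection domain, and independent Poisson counting noise — because the study
question is how penalization strength trades noise against recovery, not
scanner physics.  Attenuation, scatter and randoms are out of scope.

The projector is pixel-driven with linear interpolation onto detector bins,
and its adjoint (back-projector) uses the *same* interpolation weights, so
``<A x, y> == <x, A^T y>`` holds to floating-point precision.  A matched
adjoint pair is what makes EM-type updates correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

__all__ = ["Geometry", "Sinogram", "Projector", "forward_project", "sample_poisson"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam sampling: angles over [0, pi), radial bins, blur width."""

    n_angles: int = 192
    n_radial_bins: int = 192
    radial_spacing_mm: float = 2.5
    psf_fwhm_mm: float = 4.5

    def __post_init__(self):
        if self.n_angles < 8:
            raise SimulationError("need at least 8 projection angles")
        if self.psf_fwhm_mm < 0:
            raise SimulationError("psf_fwhm_mm must be >= 0")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    def radial_coords_mm(self) -> np.ndarray:
        n = self.n_radial_bins
        return (np.arange(n) - (n - 1) / 2.0) * self.radial_spacing_mm


@dataclass
class Sinogram:
    """Projection-domain data.

    ``expectation`` marks noiseless mean data; sampled sinograms are
    integer-valued.  ``scale`` is counts per (kBq/ml * mm) of line integral —
    dividing a reconstruction by it restores concentration units.
    """

    counts: np.ndarray
    geometry: Geometry
    expectation: bool = True
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise SimulationError("sinogram counts must be nonnegative")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def save(self, path):
        """Write counts as .npz with a JSON geometry sidecar."""
        path = Path(path)
        np.savez_compressed(path, counts=self.counts)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_angles": self.geometry.n_angles,
                    "n_radial_bins": self.geometry.n_radial_bins,
                    "radial_spacing_mm": self.geometry.radial_spacing_mm,
                    "psf_fwhm_mm": self.geometry.psf_fwhm_mm,
                    "expectation": self.expectation,
                    "scale": self.scale,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path) -> "Sinogram":
        path = Path(path)
        counts = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))[
            "counts"
        ]
        side = json.loads(path.with_suffix(".json").read_text())
        geom = Geometry(
            side["n_angles"],
            side["n_radial_bins"],
            side["radial_spacing_mm"],
            side["psf_fwhm_mm"],
        )
        return cls(counts, geom, side["expectation"], side["scale"])


class Projector:
    """Matched forward/back projector for one 2-D slice.

    Parameters
    ----------
    image_shape : (ny, nx)
    spacing_mm : (dy, dx) voxel spacing
    geom : Geometry
    apply_psf : include the radial Gaussian blur in both A and A^T (the blur
        kernel is symmetric, so (G A)^T = A^T G).
    """

    def __init__(self, image_shape, spacing_mm, geom: Geometry, apply_psf=True):
        if len(image_shape) != 2:
            raise SimulationError("Projector operates on 2-D slices")
        self.image_shape = tuple(image_shape)
        self.spacing_mm = tuple(spacing_mm)
        self.geom = geom
        self.apply_psf = apply_psf and geom.psf_fwhm_mm > 0
        self._sigma_bins = (
            geom.psf_fwhm_mm * FWHM_TO_SIGMA / geom.radial_spacing_mm
        )

        ny, nx = self.image_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing_mm[0]
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing_mm[1]
        Y, X = np.meshgrid(y, x, indexing="ij")
        nb = geom.n_radial_bins
        dr = geom.radial_spacing_mm
        pix_per_bin = self.spacing_mm[0] * self.spacing_mm[1] / dr
        npix = ny * nx
        cols_all, rows_all, data_all = [], [], []
        for a, theta in enumerate(geom.angles_rad):
            s = X.ravel() * np.cos(theta) + Y.ravel() * np.sin(theta)
            t = s / dr + (nb - 1) / 2.0
            i0 = np.floor(t).astype(np.int64)
            w = t - i0
            # pixels projecting outside the detector get zero weight
            valid = (i0 >= 0) & (i0 < nb - 1)
            i0v = i0[valid]
            wv = w[valid]
            pix = np.nonzero(valid)[0]
            rows_all.append(a * nb + i0v)
            cols_all.append(pix)
            data_all.append((1.0 - wv) * pix_per_bin)
            rows_all.append(a * nb + i0v + 1)
            cols_all.append(pix)
            data_all.append(wv * pix_per_bin)
        self._A = sparse.csr_array(
            (
                np.concatenate(data_all),
                (np.concatenate(rows_all), np.concatenate(cols_all)),
            ),
            shape=(geom.n_angles * nb, npix),
        )
        self._AT = self._A.T.tocsr()

    # -- core linear maps ---------------------------------------------------

    def subset_matrix(self, angle_indices):
        """Row block of the system matrix for a subset of angles (and its
        transpose); both CSR, sharing the interpolation weights exactly."""
        nb = self.geom.n_radial_bins
        rows = (np.asarray(angle_indices)[:, None] * nb + np.arange(nb)).ravel()
        A = self._A[rows]
        return A, A.T.tocsr()

    def project(self, image: np.ndarray, angle_indices=None) -> np.ndarray:
        """A x : noiseless line-integral profile (value-units * mm).

        Accepts a single image ``(ny, nx)`` or a batch ``(..., ny, nx)``;
        batches map to leading sinogram axes.
        """
        image = np.asarray(image, dtype=float)
        lead = image.shape[:-2]
        flat = image.reshape(-1, image.shape[-2] * image.shape[-1])
        if angle_indices is None:
            out = (self._A @ flat.T).T.reshape(
                *lead, self.geom.n_angles, self.geom.n_radial_bins
            )
        else:
            A, _ = self.subset_matrix(angle_indices)
            out = (A @ flat.T).T.reshape(
                *lead, len(angle_indices), self.geom.n_radial_bins
            )
        if self.apply_psf:
            out = gaussian_filter1d(out, self._sigma_bins, axis=-1, mode="constant")
        return out

    def backproject(self, sino_rows: np.ndarray, angle_indices=None) -> np.ndarray:
        """A^T y, using identical interpolation weights (exact adjoint)."""
        rows = np.asarray(sino_rows, dtype=float)
        if self.apply_psf:
            rows = gaussian_filter1d(rows, self._sigma_bins, axis=-1, mode="constant")
        lead = rows.shape[:-2]
        flat = rows.reshape(-1, rows.shape[-2] * rows.shape[-1])
        if angle_indices is None:
            img = (self._AT @ flat.T).T
        else:
            _, AT = self.subset_matrix(angle_indices)
            img = (AT @ flat.T).T
        return img.reshape(*lead, *self.image_shape)


def forward_project(vol, geom: Geometry, spacing_mm=None) -> Sinogram:
    """Noiseless expectation sinogram of a LabeledVolume or bare image.

    2-D inputs give a ``(n_angles, n_bins)`` sinogram; 3-D inputs are
    projected slice-by-slice into ``(n_slices, n_angles, n_bins)``.  Bare
    arrays default to 1 mm voxels unless ``spacing_mm`` says otherwise.
    """
    from .phantom import LabeledVolume  # local import to avoid cycle

    if isinstance(vol, LabeledVolume):
        image = vol.activity
        spacing = vol.spacing_mm
    else:
        image = np.asarray(vol, dtype=float)
        spacing = tuple(spacing_mm) if spacing_mm is not None else (1.0,) * image.ndim
    if np.any(image < 0):
        raise SimulationError("activity must be nonnegative")

    if image.ndim == 2:
        proj = Projector(image.shape, spacing[-2:], geom)
    elif image.ndim == 3:
        proj = Projector(image.shape[1:], spacing[-2:], geom)
    else:
        raise SimulationError("expected a 2-D slice or 3-D volume")
    counts = proj.project(image)
    return Sinogram(counts, geom, expectation=True, scale=1.0)


def sample_poisson(expectation: Sinogram, target_total_counts: float, seed: int) -> Sinogram:
    """Rescale the expectation to a target count level and draw Poisson noise.

    The count level stands in for acquisition duration; the applied scale is
    kept on the sinogram so reconstructions can be calibrated back to kBq/ml.
    """
    if target_total_counts <= 0:
        raise SimulationError("target_total_counts must be > 0")
    total = expectation.counts.sum()
    if total <= 0:
        raise SimulationError("cannot scale an all-zero expectation")
    scale = target_total_counts / total
    lam = expectation.counts * scale
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.int64)
    return Sinogram(
        counts,
        expectation.geometry,
        expectation=False,
        scale=expectation.scale * scale,
        meta={"seed": seed, "target_total_counts": target_total_counts},
    )
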