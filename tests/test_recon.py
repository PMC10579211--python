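import numpy as np
import pytest

from petiq.phantom import GridSpec, PhantomSpec, build_nema_phantom
from petiq.projections import Geometry, Projector, Sinogram, forward_project, sample_poisson
from petiq.recon import (
    ReconConfig,
    ReconError,
    bsrem_reconstruct,
    gaussian_postfilter,
    osem_reconstruct,
    poisson_loglik,
    rdp_value_and_gradient,
)

SPACING = (2.0, 2.0)
SHAPE = (48, 48)


@pytest.fixture(scope="module")
def small_case():
    """Small noisy acquisition of a hot disk on a warm background."""
    geom = Geometry(n_angles=48, n_radial_bins=96, radial_spacing_mm=2.0,
                    psf_fwhm_mm=0.0)
    c = (np.arange(48) - 23.5) * 2.0
    Y, X = np.meshgrid(c, c, indexing="ij")
    img = np.zeros(SHAPE)
    img[Y**2 + X**2 <= 40.0**2] = 1.0
    img[(Y - 10) ** 2 + (X - 10) ** 2 <= 8.0**2] = 4.0
    sino = sample_poisson(forward_project(img, geom, spacing_mm=(2.0, 2.0)), 2e5, seed=5)
    return img, geom, sino


class TestOsem:
    def test_single_subset_is_mlem(self, small_case):
        _, _, sino = small_case
        base = dict(algorithm="osem", iterations=3, psf_fwhm_mm=0.0)
        r1 = osem_reconstruct(sino, ReconConfig(**base, subsets=1), SHAPE, SPACING)
        # reference MLEM: explicit multiplicative update with the full system
        proj = Projector(SHAPE, SPACING, sino.geometry, apply_psf=False)
        sens = proj.backproject(np.ones_like(np.asarray(sino.counts, float)))
        y = np.asarray(sino.counts, float)
        x = np.full(SHAPE, y.sum() / proj.project(np.ones(SHAPE)).sum())
        for _ in range(3):
            yhat = proj.project(x)
            ratio = np.where(yhat > 0, y / np.where(yhat > 0, yhat, 1), 0.0)
            x = np.where(sens > 0, x * proj.backproject(ratio) / np.where(sens > 0, sens, 1), x)
        assert np.allclose(r1.image * sino.scale, x, rtol=1e-10)

    def test_mlem_loglikelihood_monotone(self, small_case):
        _, _, sino = small_case
        cfg = ReconConfig(algorithm="osem", iterations=15, subsets=1, psf_fwhm_mm=0.0)
        res = osem_reconstruct(sino, cfg, SHAPE, SPACING)
        tr = np.array(res.objective_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_noiseless_disk_recovered_within_one_percent(self):
        geom = Geometry(n_angles=48, n_radial_bins=96, radial_spacing_mm=2.0,
                        psf_fwhm_mm=0.0)
        c = (np.arange(48) - 23.5) * 2.0
        Y, X = np.meshgrid(c, c, indexing="ij")
        truth = np.zeros(SHAPE)
        disk = Y**2 + X**2 <= 30.0**2
        truth[disk] = 5.0
        sino = forward_project(truth, geom, spacing_mm=(2.0, 2.0))
        cfg = ReconConfig(algorithm="osem", iterations=200, subsets=1, psf_fwhm_mm=0.0)
        res = osem_reconstruct(sino, cfg, SHAPE, SPACING)
        inner = Y**2 + X**2 <= 24.0**2  # clear of the discretized edge
        assert res.image[inner].mean() == pytest.approx(5.0, rel=0.01)

    def test_image_nonnegative(self, small_case):
        _, _, sino = small_case
        res = osem_reconstruct(sino, ReconConfig.osem_default(), SHAPE, SPACING)
        assert res.image.min() >= 0

    def test_subsets_must_divide_angles(self, small_case):
        _, _, sino = small_case
        cfg = ReconConfig(algorithm="osem", iterations=1, subsets=7)
        with pytest.raises(ReconError, match="divide"):
            osem_reconstruct(sino, cfg, SHAPE, SPACING)


class TestRdp:
    def test_constant_image_has_zero_penalty_and_gradient(self):
        v, g = rdp_value_and_gradient(np.full((6, 7), 3.2))
        assert v == 0.0
        assert np.all(g == 0.0)

    def test_two_voxel_hand_value(self):
        # (4-2)^2 / (4+2+2*|4-2|) = 4/10 = 0.4 with unit weight, gamma=2
        x = np.array([[4.0, 2.0]])
        v, g = rdp_value_and_gradient(x, gamma=2.0, eps=0.0)
        assert v == pytest.approx(0.4, abs=1e-15)
        # numerical gradient check
        h = 1e-7
        for idx in [(0, 0), (0, 1)]:
            xp = x.copy(); xp[idx] += h
            num = (rdp_value_and_gradient(xp, 2.0, 0.0)[0] - v) / h
            assert g[idx] == pytest.approx(num, rel=1e-5)

    def test_mirror_symmetry(self, rng):
        x = rng.random((9, 11)) * 10
        v1, _ = rdp_value_and_gradient(x)
        v2, _ = rdp_value_and_gradient(x[::-1, ::-1].copy())
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_rejects_negative_image(self):
        with pytest.raises(ReconError):
            rdp_value_and_gradient(np.array([[-1.0, 2.0]]))

    def test_gradient_matches_numerical_on_random_image(self, rng):
        x = rng.random((5, 5)) * 4 + 0.1
        v, g = rdp_value_and_gradient(x, gamma=2.0, eps=1e-9)
        h = 1e-6
        for idx in [(0, 0), (2, 3), (4, 4), (1, 2)]:
            xp = x.copy(); xp[idx] += h
            xm = x.copy(); xm[idx] -= h
            num = (rdp_value_and_gradient(xp)[0] - rdp_value_and_gradient(xm)[0]) / (2 * h)
            assert g[idx] == pytest.approx(num, rel=1e-5)


class TestBsrem:
    def test_zero_beta_matches_osem_trajectory(self, small_case):
        _, _, sino = small_case
        common = dict(iterations=4, subsets=8, psf_fwhm_mm=0.0)
        b = bsrem_reconstruct(
            sino,
            ReconConfig(algorithm="bsrem", beta=0.0, relaxation_alpha0=1.0,
                        relaxation_decay=0.0, **common),
            SHAPE, SPACING,
        )
        o = osem_reconstruct(
            sino, ReconConfig(algorithm="osem", postfilter_fwhm_mm=0.0, **common),
            SHAPE, SPACING,
        )
        assert np.allclose(b.image, o.image, rtol=1e-6, atol=1e-9)

    def test_image_nonnegative(self, small_case):
        _, _, sino = small_case
        res = bsrem_reconstruct(sino, ReconConfig.bsrem_default(300, iterations=5),
                                SHAPE, SPACING)
        assert res.image.min() >= 0

    def test_higher_beta_smooths_background_more(self, small_case):
        img, _, sino = small_case
        lo = bsrem_reconstruct(sino, ReconConfig.bsrem_default(50, iterations=10),
                               SHAPE, SPACING)
        hi = bsrem_reconstruct(sino, ReconConfig.bsrem_default(500, iterations=10),
                               SHAPE, SPACING)
        bg = (img == 1.0)
        assert hi.image[bg].std() < lo.image[bg].std()

    def test_penalized_objective_nondecreasing_on_noiseless_data(self):
        geom = Geometry(n_angles=24, n_radial_bins=48, radial_spacing_mm=2.0,
                        psf_fwhm_mm=0.0)
        c = (np.arange(24) - 11.5) * 2.0
        Y, X = np.meshgrid(c, c, indexing="ij")
        truth = np.zeros((24, 24))
        truth[Y**2 + X**2 <= 16**2] = 2.0
        sino = forward_project(truth, geom, spacing_mm=(2.0, 2.0))
        cfg = ReconConfig.bsrem_default(200, iterations=15, subsets=4,
                                        psf_fwhm_mm=0.0)
        res = bsrem_reconstruct(sino, cfg, (24, 24), (2.0, 2.0))
        tr = np.array(res.objective_trace)
        assert np.all(np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1))

    def test_full_iteration_matches_numerical_gradient_step(self):
        """One single-subset BSREM step equals x + alpha*(x/s)*grad(Phi) with the
        gradient taken numerically on the penalized objective."""
        geom = Geometry(n_angles=8, n_radial_bins=6, radial_spacing_mm=2.0,
                        psf_fwhm_mm=0.0)
        shape, spacing = (2, 2), (2.0, 2.0)
        proj = Projector(shape, spacing, geom, apply_psf=False)
        truth = np.array([[1.0, 2.0], [3.0, 4.0]])
        y = np.round(proj.project(truth) * 3 + 0.5)
        sino = Sinogram(y, geom, expectation=False, scale=1.0)
        beta_label, gamma = 100.0, 2.0
        cfg = ReconConfig(algorithm="bsrem", iterations=1, subsets=1,
                          beta=beta_label, rdp_gamma=gamma, psf_fwhm_mm=0.0,
                          relaxation_alpha0=0.5, relaxation_decay=0.0)
        res = bsrem_reconstruct(sino, cfg, shape, spacing)

        beta_eff = cfg.beta_effective
        sens = proj.backproject(np.ones_like(y))
        x0 = np.full(shape, y.sum() / proj.project(np.ones(shape)).sum())

        def phi(x):
            return poisson_loglik(y, proj.project(x)) - beta_eff * (
                rdp_value_and_gradient(x, gamma)[0]
            )

        h = 1e-6
        grad = np.zeros(shape)
        for i in range(2):
            for j in range(2):
                xp = x0.copy(); xp[i, j] += h
                xm = x0.copy(); xm[i, j] -= h
                grad[i, j] = (phi(xp) - phi(xm)) / (2 * h)
        expected = np.maximum(x0 + 0.5 * (x0 / sens) * grad, 0.0)
        assert np.allclose(res.image, expected, rtol=1e-5)

    def test_divergence_aborts_with_diagnostic(self, small_case):
        _, _, sino = small_case
        cfg = ReconConfig.bsrem_default(500, iterations=30, subsets=8,
                                        relaxation_alpha0=30.0,
                                        relaxation_decay=0.0)
        with pytest.raises(ReconError, match="relaxation"):
            bsrem_reconstruct(sino, cfg, SHAPE, SPACING)


class TestPostfilter:
    def test_zero_fwhm_is_identity(self, rng):
        img = rng.random((20, 20))
        assert np.array_equal(gaussian_postfilter(img, 0.0, (2.0, 2.0)), img)

    def test_mean_preserved(self, rng):
        img = rng.random((40, 40))
        out = gaussian_postfilter(img, 4.8, (2.0, 2.0))
        assert out.mean() == pytest.approx(img.mean(), abs=1e-9)

    def test_white_noise_variance_reduction_matches_kernel(self, rng):
        # filtered white noise variance shrinks by sum(k^2) of the 2-D kernel
        from scipy.ndimage import gaussian_filter

        spacing, fwhm = 2.0, 4.8
        sigma = fwhm / 2.3548200450309493 / spacing
        delta = np.zeros((41, 41)); delta[20, 20] = 1.0
        k2 = (gaussian_filter(delta, sigma, mode="constant") ** 2).sum()
        noise = rng.standard_normal((600, 600))
        out = gaussian_postfilter(noise, fwhm, (spacing, spacing))
        inner = out[20:-20, 20:-20]
        assert inner.var() == pytest.approx(k2, rel=0.05)
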