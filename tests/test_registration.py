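"""Similarity metrics, the Powell wrapper, and adaptive registration."""

import numpy as np
import pytest
from scipy import ndimage

from pctreg import Volume, synthesize_template
from pctreg.phantom import PhantomTruth, sample_affine_truth, _invert_global
from pctreg.registration import (
    NonFiniteObjectiveError,
    RegistrationConfig,
    RegistrationError,
    _AFFINE_SCALES,
    _W_SCALE,
    nmi_from_samples,
    normalized_cross_correlation,
    normalized_mutual_information,
    powell_minimize,
    register_adaptive,
)
from pctreg.transforms import AffineTransform, TransformChain
from pctreg.volume import build_pyramid, sample_at_world


def _warp_template(template_vol, affine, grid):
    """Subject-space copy of a template image under a known affine truth."""
    truth = PhantomTruth(burden=0.0, affine_true=affine)
    src = _invert_global(truth, grid.grid_world_coordinates())
    idx = grid.world_to_voxel(src)
    img = ndimage.map_coordinates(
        template_vol.data, idx.T, order=1, mode="grid-constant", cval=0.0, prefilter=False
    ).reshape(grid.shape)
    return Volume(img, grid.affine.copy())


class TestNMI:
    def test_self_information_is_two(self, rng):
        a = rng.random((20, 20, 20))
        assert normalized_mutual_information(a, a, bins=32) == pytest.approx(2.0, abs=1e-6)

    def test_symmetry(self, rng):
        a, b = rng.random((16, 16, 16)), rng.random((16, 16, 16))
        assert normalized_mutual_information(a, b) == pytest.approx(
            normalized_mutual_information(b, a), abs=1e-12
        )

    def test_independent_images_approach_one(self, rng):
        a = rng.random((64, 64, 64))
        b = rng.random((64, 64, 64))
        assert normalized_mutual_information(a, b, bins=64) < 1.05

    def test_constant_image_defined_as_one_with_warning(self, rng):
        a = np.full((10, 10, 10), 3.0)
        b = rng.random((10, 10, 10))
        with pytest.warns(UserWarning):
            assert normalized_mutual_information(a, b) == 1.0

    def test_too_few_voxels_rejected(self, rng):
        a = rng.random((3, 3, 3))
        with pytest.raises(RegistrationError):
            normalized_mutual_information(a, a)

    def test_mask_restriction(self, rng):
        a = rng.random((16, 16, 16))
        b = a + 0.01 * rng.random((16, 16, 16))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[:8] = True
        full = normalized_mutual_information(a, b)
        masked = normalized_mutual_information(a, b, mask=mask)
        assert masked != full  # different sample, different histogram
        assert 1.0 <= masked <= 2.0


class TestNCC:
    def test_self_correlation(self, rng):
        a = rng.random((10, 10, 10))
        m = np.ones_like(a, dtype=bool)
        assert normalized_cross_correlation(a, a, m) == pytest.approx(1.0)

    def test_affine_antirelation(self, rng):
        a = rng.random((10, 10, 10))
        m = np.ones_like(a, dtype=bool)
        assert normalized_cross_correlation(a, -a + 5, m) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        a = rng.random((10, 10, 10))
        m = np.ones_like(a, dtype=bool)
        assert normalized_cross_correlation(a, 2 * a + 3, m) == pytest.approx(1.0)

    def test_constant_input_rejected(self, rng):
        a = rng.random((10, 10, 10))
        m = np.ones_like(a, dtype=bool)
        with pytest.raises(RegistrationError):
            normalized_cross_correlation(a, np.ones_like(a), m)


class TestPowell:
    def test_convex_quadratic(self):
        x, f, n = powell_minimize(
            lambda p: (p[0] - 3) ** 2 + (p[1] + 1) ** 2,
            np.zeros(2),
            xtol=1e-8,
            ftol=1e-12,
            max_iter=100,
        )
        np.testing.assert_allclose(x, [3.0, -1.0], atol=1e-6)
        assert n > 0

    def test_rosenbrock(self):
        def rosen(p):
            return 100.0 * (p[1] - p[0] ** 2) ** 2 + (1 - p[0]) ** 2

        x, f, _ = powell_minimize(
            rosen, np.array([-1.2, 1.0]), xtol=1e-8, ftol=1e-12, max_iter=1000
        )
        assert f < 1e-8
        np.testing.assert_allclose(x, [1.0, 1.0], atol=1e-3)

    def test_stationary_point_with_loose_tolerance(self):
        x, f, _ = powell_minimize(
            lambda p: float(p @ p), np.zeros(3), xtol=1.0, ftol=1.0, max_iter=5
        )
        np.testing.assert_allclose(x, np.zeros(3), atol=1e-8)

    def test_nonfinite_objective_aborts_with_vector(self):
        def bad(p):
            return np.inf if p[0] > 0.5 else float(p @ p + 1.0)

        with pytest.raises(NonFiniteObjectiveError) as exc:
            powell_minimize(bad, np.array([0.0, 0.0]), xtol=1e-6, ftol=1e-9, max_iter=50)
        assert exc.value.x is not None

    def test_deterministic(self):
        def rosen(p):
            return 100.0 * (p[1] - p[0] ** 2) ** 2 + (1 - p[0]) ** 2

        r1 = powell_minimize(rosen, np.array([-1.2, 1.0]))
        r2 = powell_minimize(rosen, np.array([-1.2, 1.0]))
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1] == r2[1] and r1[2] == r2[2]


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RegistrationConfig(nmi_bins=32, w_bounds=(-0.5, 0.5))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = RegistrationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_invalid_w_bounds_rejected(self):
        with pytest.raises(RegistrationError):
            RegistrationConfig(w_bounds=(-2.0, 1.0))

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(RegistrationError):
            RegistrationConfig(xtol=0.0)


class TestRegisterAdaptive:
    def test_already_registered_subject(self, anatomy, model, config):
        """A template-grid subject at w = -1 needs no transform and keeps w."""
        subject = synthesize_template(model, -1.0).volume
        chain = register_adaptive(subject, model, config, anatomy.cerebral_mask_noventricles)
        assert abs(chain.weight - (-1.0)) <= 0.02
        assert np.all(np.abs(chain.affine.parameters[:3]) < 0.5)  # mm
        assert np.all(np.abs(chain.affine.parameters[3:6]) < 0.01)  # rad

    def test_deterministic_chain(self, anatomy, model, config):
        subject = synthesize_template(model, 0.5).volume
        c1 = register_adaptive(subject, model, config, anatomy.cerebral_mask_noventricles)
        c2 = register_adaptive(subject, model, config, anatomy.cerebral_mask_noventricles)
        np.testing.assert_array_equal(c1.affine.parameters, c2.affine.parameters)
        assert c1.weight == c2.weight
        if c1.polynomial is not None:
            np.testing.assert_array_equal(
                c1.polynomial.coefficients, c2.polynomial.coefficients
            )

    def test_per_level_objective_never_worsens(self, anatomy, model, config):
        rng = np.random.default_rng(77)
        center = 0.5 * (np.add(*anatomy.grid.world_bounds()))
        A = sample_affine_truth(rng, center, 5, 4, (0.97, 1.03))
        subject = _warp_template(synthesize_template(model, 0.5).volume, A, anatomy.grid)
        chain = register_adaptive(subject, model, config, anatomy.cerebral_mask_noventricles)
        for s in chain.metadata["stages"]:
            if "nmi_start" in s:
                assert s["nmi"] >= s["nmi_start"] - 1e-12

    def test_w_recovery_under_noise(self, anatomy, model, config):
        """Additive noise at 5% of the brain mean leaves the mean absolute
        error of the recovered appearance weight within 0.1 over the w grid."""
        rng = np.random.default_rng(31)
        center = 0.5 * (np.add(*anatomy.grid.world_bounds()))
        brain = anatomy.brain_mask
        errs = []
        for w_true in (-1.0, -0.5, 0.0, 0.5, 1.0):
            A = sample_affine_truth(rng, center, 8, 6, (0.95, 1.05))
            subject = _warp_template(
                synthesize_template(model, w_true).volume, A, anatomy.grid
            )
            sigma = 0.05 * abs(subject.data[brain]).mean()
            noisy = Volume(
                subject.data + sigma * rng.standard_normal(subject.shape),
                subject.affine,
            )
            chain = register_adaptive(
                noisy, model, config, anatomy.cerebral_mask_noventricles
            )
            errs.append(abs(chain.weight - w_true))
        assert np.mean(errs) <= 0.1

    def test_reduces_to_plain_affine_registration_in_the_limit(self, anatomy, model):
        """Polynomial stage off + frozen w == standard affine NMI registration."""
        rng = np.random.default_rng(7)
        center = 0.5 * (np.add(*anatomy.grid.world_bounds()))
        A = sample_affine_truth(rng, center, 4, 3, (0.98, 1.02))
        w_true = 0.5
        subject = _warp_template(
            synthesize_template(model, w_true).volume, A, anatomy.grid
        )
        cfg = RegistrationConfig(freeze_w=w_true, enable_polynomial_stage=False)
        chain = register_adaptive(subject, model, cfg, None)
        assert chain.polynomial is None
        assert chain.weight == w_true

        # direct affine-only implementation: fixed template at w_true, same
        # pyramids, metric and optimizer schedule as the adaptive cascade
        sm = cfg.template_presmooth_voxels
        pc1 = model.components[0]
        pc2 = model.components[1]
        pc1 = pc1.like(ndimage.gaussian_filter(np.asarray(pc1.data, float), sm))
        pc2 = pc2.like(ndimage.gaussian_filter(np.asarray(pc2.data, float), sm))
        pyr1 = build_pyramid(pc1, cfg.n_levels, cfg.pyramid_fwhm_voxels)
        pyr2 = build_pyramid(pc2, cfg.n_levels, cfg.pyramid_fwhm_voxels)
        mov_sm = subject.like(
            ndimage.gaussian_filter(np.asarray(subject.data, float), sm)
        )
        pyr_m = build_pyramid(mov_sm, cfg.n_levels, cfg.pyramid_fwhm_voxels)
        u = AffineTransform.identity().parameters / _AFFINE_SCALES

        def centroid(vol):
            wgt = np.abs(np.asarray(vol.data, dtype=float)).ravel()
            pts0 = vol.grid_world_coordinates()
            return (pts0 * wgt[:, None]).sum(axis=0) / wgt.sum()

        def level_objective(li):
            lvl, lvl2, mov = pyr1[li], pyr2[li], pyr_m[li]
            stride = cfg.sampling_stride if li == cfg.n_levels - 1 else 1
            sl = (slice(None, None, stride),) * 3
            ii = np.indices(lvl.shape, dtype=float)[(slice(None),) + sl]
            pts = lvl.voxel_to_world(ii.reshape(3, -1).T)
            tv = (
                np.asarray(lvl.data[sl], dtype=np.float64).ravel()
                + w_true * np.asarray(lvl2.data[sl], dtype=np.float64).ravel()
            )

            def obj(uu):
                p12 = (uu * _AFFINE_SCALES).copy()
                p12[6:9] = np.maximum(p12[6:9], 0.1)
                aff = AffineTransform(p12, center)
                sv = sample_at_world(mov, aff.map_points(pts))
                return -nmi_from_samples(tv, sv, cfg.nmi_bins)

            return obj

        # initialization mirror: centroid translation + rotation-grid scan
        u[:3] = centroid(pyr_m[0]) - centroid(pyr1[0])
        obj0 = level_objective(0)
        rot_step = np.deg2rad(8.0) / _AFFINE_SCALES[3]
        best_init, best_u = np.inf, u.copy()
        for rx in (-rot_step, 0.0, rot_step):
            for ry in (-rot_step, 0.0, rot_step):
                for rz in (-rot_step, 0.0, rot_step):
                    uc = u.copy()
                    uc[3:6] = [rx, ry, rz]
                    f = obj0(uc)
                    if f < best_init:
                        best_init, best_u = f, uc
        u = best_u
        for li in range(cfg.n_levels):
            obj = level_objective(li)
            best = obj(u)
            for _ in range(cfg.max_restarts):
                u_new, f_new, _ = powell_minimize(
                    obj, u, xtol=cfg.xtol, ftol=cfg.ftol, max_iter=cfg.max_iter
                )
                if f_new < best - abs(cfg.ftol) * max(1.0, abs(best)):
                    u, best = u_new, f_new
                else:
                    if f_new < best:
                        u, best = u_new, f_new
                    break
        direct = u * _AFFINE_SCALES
        direct[6:9] = np.maximum(direct[6:9], 0.1)
        np.testing.assert_allclose(chain.affine.parameters, direct, atol=1e-12)
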