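"""Gram-form PCA model: oracles against dense decompositions and the
synthetic-template algebra."""

import numpy as np
import pytest

from pctreg.pca import (
    ImageStack,
    PCAError,
    compute_mean,
    explained_variance_fraction,
    fit_pc_model,
    fix_component_signs,
    load_model,
    save_model,
    synthesize_template,
)
from pctreg.volume import Volume

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def _stack(arrays):
    return ImageStack([Volume(a, AFF) for a in arrays])


def _random_stack(rng, n, shape=(6, 6, 6)):
    return _stack([rng.normal(size=shape) for _ in range(n)])


class TestMean:
    def test_mean_of_identical_volumes(self, rng):
        a = rng.random((4, 4, 4))
        m = compute_mean(_stack([a, a, a]))
        np.testing.assert_allclose(m.data, a)

    def test_simple_arithmetic(self):
        m = compute_mean(_stack([np.zeros((3, 3, 3)), np.full((3, 3, 3), 2.0)]))
        np.testing.assert_array_equal(m.data, np.ones((3, 3, 3)))

    def test_against_loop_oracle(self, rng):
        arrays = [rng.random((4, 4, 4)) for _ in range(5)]
        expected = np.zeros((4, 4, 4))
        for a in arrays:
            for idx in np.ndindex(4, 4, 4):
                expected[idx] += a[idx] / 5.0
        np.testing.assert_allclose(compute_mean(_stack(arrays)).data, expected)


class TestFit:
    def test_identical_volumes_zero_variance(self, rng):
        a = rng.random((4, 4, 4))
        m = fit_pc_model(_stack([a, a, a]))
        np.testing.assert_allclose(m.eigenvalues, 0.0, atol=1e-20)
        np.testing.assert_allclose(m.mean_image.data, a)

    def test_two_point_closed_form(self, rng):
        mu = rng.random((4, 4, 4))
        d = rng.normal(size=(4, 4, 4))
        m = fit_pc_model(_stack([mu + d, mu - d]))
        # n = 2: the single nonzero eigenvalue of D'D/(n-1) is 2 ||d||^2
        np.testing.assert_allclose(m.eigenvalues[0], 2 * (d**2).sum(), rtol=1e-10)
        comp = m.components[0].data.ravel()
        dn = d.ravel()
        cos = comp @ dn / (np.linalg.norm(comp) * np.linalg.norm(dn))
        assert abs(abs(cos) - 1.0) < 1e-10  # component parallel to d

    def test_matches_dense_covariance_oracle(self, rng):
        """n x n Gram path vs. brute-force p x p covariance at tiny p."""
        stack = _random_stack(rng, 6)
        m = fit_pc_model(stack, k=2)
        X = np.stack([v.data.ravel() for v in stack.volumes], axis=1)
        D = X - X.mean(axis=1, keepdims=True)
        dense = D @ D.T / (X.shape[1] - 1)  # 216 x 216
        evals = np.sort(np.linalg.eigvalsh(dense))[::-1]
        np.testing.assert_allclose(m.eigenvalues, evals[:5], rtol=1e-8, atol=1e-10)
        # top-2 subspace agreement: project eigenimages onto the dense top-2
        w, v = np.linalg.eigh(dense)
        basis = v[:, np.argsort(w)[::-1][:2]]
        for comp in m.components:
            c = comp.data.ravel()
            proj = basis @ (basis.T @ c)
            np.testing.assert_allclose(proj, c, atol=1e-8 * np.linalg.norm(c))

    def test_reconstruction_from_all_components(self, rng):
        stack = _random_stack(rng, 5)
        m = fit_pc_model(stack)  # k = n - 1
        mu = m.mean_image.data.ravel()
        basis = [c.data.ravel() / np.linalg.norm(c.data) for c in m.components]
        for v in stack.volumes:
            d = v.data.ravel() - mu
            rec = mu + sum((d @ e) * e for e in basis)
            err = np.linalg.norm(rec - v.data.ravel()) / np.linalg.norm(v.data)
            assert err <= 1e-4

    def test_component_orthogonality(self, rng):
        m = fit_pc_model(_random_stack(rng, 6))
        for i in range(len(m.components)):
            for j in range(i + 1, len(m.components)):
                a = m.components[i].data.ravel()
                b = m.components[j].data.ravel()
                assert abs(a @ b) <= 1e-6 * np.linalg.norm(a) * np.linalg.norm(b)

    def test_eigenimage_norm_carries_eigenvalue_scale(self, rng):
        stack = _random_stack(rng, 6)
        m = fit_pc_model(stack)
        for lam, comp in zip(m.eigenvalues, m.components):
            np.testing.assert_allclose(
                np.linalg.norm(comp.data), np.sqrt((len(stack) - 1) * lam), rtol=1e-8
            )

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(PCAError):
            fit_pc_model(_random_stack(rng, 4), k=4)

    def test_mismatched_grids_rejected(self, rng):
        v1 = Volume(rng.random((4, 4, 4)), AFF)
        v2 = Volume(rng.random((4, 4, 4)), np.eye(4))
        with pytest.raises(PCAError):
            ImageStack([v1, v2])


class TestExplainedVariance:
    def test_all_components_reach_one(self, rng):
        m = fit_pc_model(_random_stack(rng, 6))
        assert explained_variance_fraction(m, 5) == pytest.approx(1.0)

    def test_rank_one_stack(self, rng):
        mu = rng.random((4, 4, 4))
        d = rng.normal(size=(4, 4, 4))
        m = fit_pc_model(_stack([mu + d, mu - d]))
        assert explained_variance_fraction(m, 1) == pytest.approx(1.0)

    def test_non_decreasing_in_m(self, rng):
        m = fit_pc_model(_random_stack(rng, 7))
        fr = [explained_variance_fraction(m, i) for i in range(1, 7)]
        assert all(b >= a for a, b in zip(fr, fr[1:]))
        assert fr[-1] == pytest.approx(1.0)

    def test_m_below_one_rejected(self, rng):
        with pytest.raises(PCAError):
            explained_variance_fraction(fit_pc_model(_random_stack(rng, 4)), 0)


class TestSynthesize:
    def test_w_zero_is_first_component(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        t = synthesize_template(m, 0.0)
        np.testing.assert_array_equal(t.volume.data, m.components[0].data)

    def test_affine_in_w(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        t1 = synthesize_template(m, 0.8).volume.data
        t2 = synthesize_template(m, -0.4).volume.data
        tm = synthesize_template(m, 0.2).volume.data
        np.testing.assert_allclose(t1 + t2, 2 * tm, atol=1e-12)

    def test_w_step_is_scaled_second_component(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        d = synthesize_template(m, 0.4).volume.data - synthesize_template(m, 0.0).volume.data
        np.testing.assert_allclose(d, 0.4 * m.components[1].data, atol=1e-12)

    def test_out_of_range_w_clamped_with_warning(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        with pytest.warns(UserWarning):
            t = synthesize_template(m, 1.5)
        assert t.weight == 1.0

    def test_single_component_model_rejected(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=1)
        with pytest.raises(PCAError):
            synthesize_template(m, 0.0)


class TestSignFixing:
    def test_idempotent(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        mask = np.ones((6, 6, 6), dtype=bool)
        once = fix_component_signs(m, mask)
        twice = fix_component_signs(once, mask)
        for a, b in zip(once.components, twice.components):
            np.testing.assert_array_equal(a.data, b.data)
        assert once.sign_flips == twice.sign_flips

    def test_negated_component_restored(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        mask = np.ones((6, 6, 6), dtype=bool)
        fixed = fix_component_signs(m, mask)
        flipped = fix_component_signs(
            type(m)(
                mean_image=m.mean_image,
                components=[fixed.components[0], fixed.components[1].like(-fixed.components[1].data)],
                eigenvalues=m.eigenvalues,
                n_train=m.n_train,
            ),
            mask,
        )
        np.testing.assert_array_equal(
            flipped.components[1].data, fixed.components[1].data
        )
        # synthesize(w) after fixing equals synthesize(-w) before fixing
        np.testing.assert_allclose(
            synthesize_template(flipped, 0.3).volume.data,
            fixed.components[0].data + 0.3 * fixed.components[1].data,
        )

    def test_empty_mask_rejected(self, rng):
        m = fit_pc_model(_random_stack(rng, 5), k=2)
        with pytest.raises(PCAError):
            fix_component_signs(m, np.zeros((6, 6, 6), dtype=bool))


class TestPersistence:
    def test_directory_round_trip(self, tmp_path, rng):
        x = np.indices((8, 8, 8), dtype=float).sum(axis=0)
        stack = _stack([x + rng.normal(size=(8, 8, 8)) for _ in range(5)])
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:7, 1:7, 1:7] = True
        m = fit_pc_model(stack, k=2, mask=mask)
        save_model(m, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.n_train == m.n_train
        np.testing.assert_allclose(back.eigenvalues, m.eigenvalues, rtol=1e-6)
        np.testing.assert_allclose(
            back.components[0].data, m.components[0].data, atol=1e-4
        )
        np.testing.assert_array_equal(back.mask, m.mask)
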