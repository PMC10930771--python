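"""Sparsemax, localisation, affine inference/constraints, grids, sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magnet import constrain_params, infer_affine_params, make_grid, sparsemax
from magnet.attention import (
    AffineParams,
    Branch,
    bilinear_sample,
    infer_affine_params_t,
    linearized_sample,
    localize,
)
from magnet._tensor import Tensor
from magnet.errors import ContractError

RNG = np.random.default_rng(17)


def simplex_projection_bruteforce(z):
    """Oracle: exhaustive active-set enumeration of the QP
    min ||p - z||^2 s.t. p >= 0, sum p = 1."""
    K = len(z)
    best, best_dist = None, np.inf
    for size in range(1, K + 1):
        for support in itertools.combinations(range(K), size):
            s = list(support)
            p = np.zeros(K)
            p[s] = z[s] - (z[s].sum() - 1.0) / size
            if (p[s] < -1e-12).any():
                continue
            dist = ((p - z) ** 2).sum()
            if dist < best_dist:
                best, best_dist = p, dist
    return best


class TestSparsemax:
    def test_uniform_for_equal_inputs(self):
        for K in (1, 2, 5, 56 * 56):
            out = sparsemax(np.full(K, 0.37))
            np.testing.assert_allclose(out, np.full(K, 1.0 / K))

    def test_two_element_closed_form(self):
        # p1 = clip((z1 - z2 + 1) / 2, 0, 1)
        out = sparsemax(np.array([0.6, 0.0]))
        np.testing.assert_allclose(out, [0.8, 0.2])

    def test_dominant_value_one_hot(self):
        z = np.array([0.1, 0.2, 1.5, 0.05, 0.3])
        out = sparsemax(z)
        np.testing.assert_allclose(out, [0, 0, 1, 0, 0], atol=1e-12)

    def test_matches_bruteforce_qp(self):
        for _ in range(200):
            K = int(RNG.integers(1, 7))
            z = RNG.normal(0, 1, K)
            np.testing.assert_allclose(
                sparsemax(z), simplex_projection_bruteforce(z), atol=1e-9
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_simplex_and_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 2, int(rng.integers(2, 30)))
        p = sparsemax(z)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()
        np.testing.assert_allclose(sparsemax(z + 3.7), p, atol=1e-9)
        # order preservation
        order = np.argsort(z)
        assert (np.diff(p[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sparsemax(np.array([]))


class TestLocalize:
    def test_map_is_probability_mass(self):
        branch = Branch(channels=2, rng=np.random.default_rng(0))
        view = RNG.integers(0, 255, (56, 56, 3), dtype=np.uint8)
        amap = localize(view, branch)
        assert amap.shape == (56, 56)
        assert amap.sum() == pytest.approx(1.0, abs=1e-5)
        assert (amap >= 0).all()

    def test_constant_input_gives_uniform_interior(self):
        # a spatially constant input yields a constant interior response;
        # only cells within the receptive field of the zero padding may
        # deviate, so the map is uniform away from the borders and the
        # inferred translations stay near zero
        branch = Branch(channels=2, rng=np.random.default_rng(1))
        view = np.full((56, 56, 3), 120, dtype=np.uint8)
        amap = localize(view, branch)
        interior = amap[6:-6, 6:-6]
        assert interior.max() - interior.min() < 1e-8
        _, tx, ty = infer_affine_params(amap / amap.sum())
        assert abs(tx) < 0.05 and abs(ty) < 0.05

    def test_slot_specific_branches_differ(self):
        b1 = Branch(channels=2, rng=np.random.default_rng(2))
        b2 = Branch(channels=2, rng=np.random.default_rng(3))
        view = RNG.integers(0, 255, (56, 56, 3), dtype=np.uint8)
        assert not np.allclose(localize(view, b1), localize(view, b2))


class TestInferAffineParams:
    def test_point_mass_at_centre(self):
        amap = np.zeros((56, 56))
        amap[28, 28] = 1.0
        s, tx, ty = infer_affine_params(amap)
        assert s == pytest.approx(0.0, abs=1e-12)
        assert abs(tx) < 0.02 and abs(ty) < 0.02

    def test_uniform_map_yields_unit_scale(self):
        amap = np.full((56, 56), 1.0 / 56**2)
        s, tx, ty = infer_affine_params(amap)
        # E|u| over the 56 cell centres is exactly 0.5 per axis
        assert s == pytest.approx(1.0, abs=1e-9)
        assert tx == pytest.approx(0.0, abs=1e-12)
        assert ty == pytest.approx(0.0, abs=1e-12)

    def test_left_mass_gives_negative_tx(self):
        amap = np.zeros((56, 56))
        amap[:, :20] = 1.0
        amap /= amap.sum()
        _, tx, _ = infer_affine_params(amap)
        assert tx < -0.2

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_mirror_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        amap = rng.random((56, 56))
        amap /= amap.sum()
        s, tx, ty = infer_affine_params(amap)
        sm, txm, tym = infer_affine_params(np.ascontiguousarray(amap[:, ::-1]))
        assert txm == pytest.approx(-tx, abs=1e-9)
        assert tym == pytest.approx(ty, abs=1e-9)
        assert sm == pytest.approx(s, abs=1e-9)

    def test_unnormalised_map_rejected(self):
        with pytest.raises(ContractError):
            infer_affine_params(np.full((56, 56), 1.0))

    def test_batched_matches_single(self):
        maps = RNG.random((3, 56, 56))
        maps /= maps.sum(axis=(1, 2), keepdims=True)
        s, tx, ty = infer_affine_params_t(Tensor(maps))
        for b in range(3):
            sb, txb, tyb = infer_affine_params(maps[b])
            assert s.data[b] == pytest.approx(sb, abs=1e-6)
            assert tx.data[b] == pytest.approx(txb, abs=1e-6)


class TestConstrainParams:
    def test_scale_floor(self):
        assert constrain_params(0.01, 0, 0).s == pytest.approx(0.05)
        assert constrain_params(0.7, 0, 0).s == pytest.approx(0.7)

    def test_tanh_fixed_point_and_value(self):
        assert constrain_params(1.0, 0.0, 0.0).tx == pytest.approx(0.0)
        assert constrain_params(1.0, 1.0, 0.0).tx == pytest.approx(0.7616, abs=1e-4)

    def test_theta_matrix_layout(self):
        p = constrain_params(0.3, 0.5, -0.2)
        np.testing.assert_allclose(
            p.theta, [[p.s, 0.0, p.tx], [0.0, p.s, p.ty]]
        )

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        pa = constrain_params(a, a, a)
        pb = constrain_params(b, b, b)
        assert pa.s >= 0.05 and -1 < pa.tx < 1 and -1 < pa.ty < 1
        if a < b:
            assert pa.s <= pb.s and pa.tx <= pb.tx


class TestMakeGrid:
    def test_identity_grid_spans_unit_square(self):
        grid = make_grid(AffineParams.identity(), 56)
        assert grid.shape == (56, 56, 2)
        assert grid[..., 0].min() == pytest.approx(-1.0)
        assert grid[..., 0].max() == pytest.approx(1.0)
        np.testing.assert_allclose(grid[0, :, 0], np.linspace(-1, 1, 56))

    def test_half_scale_spans_half(self):
        grid = make_grid((0.5, 0.0, 0.0), 24)
        assert grid[..., 0].min() == pytest.approx(-0.5)
        assert grid[..., 1].max() == pytest.approx(0.5)

    def test_scale_plus_translation(self):
        grid = make_grid((0.5, 0.5, 0.0), 24)
        assert grid[..., 0].min() == pytest.approx(0.0)
        assert grid[..., 0].max() == pytest.approx(1.0)


class TestLinearizedSample:
    def test_identity_zero_noise_reconstructs(self):
        img = RNG.uniform(0, 255, (12, 12, 3))
        out = linearized_sample(img, make_grid((1, 0, 0), 12), noise_sd=0.0)
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_constant_image_exact(self):
        img = np.full((10, 10, 3), 42.0)
        out = linearized_sample(
            img, make_grid((0.5, 0.2, -0.1), 8), k_aux=6, noise_sd=0.01,
            rng=np.random.default_rng(0),
        )
        np.testing.assert_allclose(out, 42.0, atol=1e-8)

    def test_small_noise_matches_bilinear_oracle(self):
        img = RNG.uniform(0, 1, (8, 8, 3))
        grid = make_grid((0.45, 0.1, -0.05), 16)
        lin = linearized_sample(
            img, grid, k_aux=8, noise_sd=1e-4, rng=np.random.default_rng(5)
        )
        oracle = bilinear_sample(img, grid)
        assert np.abs(lin - oracle).max() < 1e-2

    def test_default_noise_depends_on_out_side(self):
        img = RNG.uniform(0, 1, (8, 8, 3))
        out = linearized_sample(
            img, make_grid((1, 0, 0), 8), rng=np.random.default_rng(0)
        )
        assert out.shape == (8, 8, 3)


class TestGradientSanityUnderScaling:
    """Qualitative check that linearized sampling keeps transform gradients
    usable under 8x minification while plain bilinear gradients degrade
    into aliasing noise (finite differences through each sampler)."""

    IMG = np.random.default_rng(4).uniform(0, 1, (256, 256, 3))

    @staticmethod
    def _lin(image, grid):
        return linearized_sample(
            image, grid, k_aux=8, noise_sd=1.0 / grid.shape[0],
            rng=np.random.default_rng(7),
        )

    @classmethod
    def _fd_grad(cls, sampler, img, center, offset, eps=1e-3, out_side=32):
        target = sampler(img, make_grid((1.0, center + offset, 0.0), out_side))

        def loss(tx):
            pred = sampler(img, make_grid((1.0, tx, 0.0), out_side))
            return float(((pred - target) ** 2).mean())

        return (loss(center + eps) - loss(center - eps)) / (2 * eps)

    @classmethod
    def _sign_agreement(cls, sampler, img, n=40):
        # fraction of random alignment problems where the FD gradient points
        # toward the target offset
        r = np.random.default_rng(123)
        correct = 0
        for _ in range(n):
            center = r.uniform(-0.3, 0.3)
            offset = r.choice([-0.25, 0.25])
            g = cls._fd_grad(sampler, img, center, offset)
            if np.sign(g) == -np.sign(offset):
                correct += 1
        return correct / n

    def test_linearized_gradient_norm_resilient_to_scale(self):
        g1 = np.mean([
            abs(self._fd_grad(self._lin, self.IMG[:32, :32], c, 0.25))
            for c in np.linspace(-0.3, 0.3, 7)
        ])
        g8 = np.mean([
            abs(self._fd_grad(self._lin, self.IMG, c, 0.25))
            for c in np.linspace(-0.3, 0.3, 7)
        ])
        assert 0.1 < g8 / g1 < 10.0  # within a factor of 10 of the 1x case

    def test_bilinear_gradients_less_informative_when_minified(self):
        lin_8x = self._sign_agreement(self._lin, self.IMG)
        bil_8x = self._sign_agreement(bilinear_sample, self.IMG)
        assert lin_8x >= 0.7  # linearized still finds the target
        assert bil_8x <= 0.6  # bilinear is near chance level
        assert lin_8x > bil_8x + 0.1
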