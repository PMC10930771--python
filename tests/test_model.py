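"""Patch accounting, trace structure, frozen patch, heads, checkpoints."""

from math import prod

import numpy as np
import pytest

from magnet import MagNet, MagNetConfig, count_patches, load_checkpoint, save_checkpoint
from magnet.attention import AffineParams
from magnet.errors import ContractError, InvalidRequestError
from magnet.model import auxiliary_predict

from conftest import TINY_MODEL

RNG = np.random.default_rng(23)


def trace_budget_bruteforce(patches):
    """Oracle: enumerate the extraction tree name by name."""
    names = ["I1"]
    frontier = ["I1"]
    for p_l in patches:
        frontier = [n + str(p + 1) for n in frontier for p in range(p_l)]
        names.extend(frontier)
    # "I" + root digit + one digit per layer
    leaves = [n for n in names if len(n) == len(patches) + 2]
    return names, leaves


class TestCountPatches:
    def test_three_layer_printed_budget(self):
        b = count_patches(MagNetConfig(layers=3, patches=(3, 2, 3)))
        assert (b.n_small, b.n_large, b.total) == (10, 18, 28)
        assert b.pixels_total == 2_803_584  # ~3 million pixels

    def test_four_layer_printed_budget(self):
        b = count_patches(MagNetConfig(layers=4, patches=(3, 2, 3, 2)))
        assert (b.n_small, b.n_large, b.total) == (28, 36, 64)
        assert b.pixels_total == 5_682_432  # ~6 million pixels

    def test_single_patch_chain(self):
        b = count_patches(MagNetConfig(layers=3, patches=(1, 1, 1)))
        assert (b.n_small, b.n_large) == (3, 1)  # input + one per layer

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(1, 5))
            P = tuple(int(rng.integers(1, 4)) for _ in range(L))
            names, leaves = trace_budget_bruteforce(P)
            b = count_patches(MagNetConfig(layers=L, patches=P))
            assert b.total == len(names)
            assert b.n_large == len(leaves)

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidRequestError):
            MagNetConfig(layers=2, patches=(3,))
        with pytest.raises(InvalidRequestError):
            MagNetConfig(layers=1, patches=(0,))


class TestForwardTrace:
    def test_three_layer_trace_counts(self, tiny_model_323, small_slide):
        pyramid, _ = small_slide
        res = tiny_model_323.forward(pyramid)
        trace = res.traces[0]
        assert len(trace) == 28
        assert len(trace.at_resolution(56)) == 10
        assert len(trace.at_resolution(224)) == 18
        assert len(trace.leaves()) == 18

    def test_names_encode_extraction_path(self, tiny_model_323, small_slide):
        pyramid, _ = small_slide
        trace = tiny_model_323.forward(pyramid).traces[0]
        lookup = trace.by_name()
        expect_names, _ = trace_budget_bruteforce((3, 2, 3))
        assert sorted(lookup) == sorted(expect_names)
        for e in trace.entries:
            if e.parent is not None:
                assert e.parent in lookup
        # leaf names carry one digit per layer plus the root digit
        for leaf in trace.leaves():
            assert len(leaf.name) == 1 + 1 + 3

    def test_trace_agrees_with_budget_for_random_configs(self, small_slide):
        pyramid, _ = small_slide
        rng = np.random.default_rng(6)
        for _ in range(6):
            L = int(rng.integers(1, 4))
            P = tuple(int(rng.integers(1, 4)) for _ in range(L))
            cfg = MagNetConfig(layers=L, patches=P, **TINY_MODEL)
            model = MagNet(cfg, rng=rng).eval()
            trace = model.forward(pyramid).traces[0]
            budget = count_patches(cfg)
            assert len(trace) == budget.total
            assert len(trace.at_resolution(224)) == budget.n_large

    def test_y_hat_is_probability_and_deterministic(self, tiny_model_323, small_slide):
        pyramid, _ = small_slide
        r1 = tiny_model_323.forward(pyramid)
        r2 = tiny_model_323.forward(pyramid)
        assert 0.0 < r1.y_hat < 1.0
        assert r1.y_hat == r2.y_hat

    def test_aux_layers_present(self, tiny_model_323, small_slide):
        pyramid, _ = small_slide
        res = tiny_model_323.forward(pyramid)
        assert set(res.aux) == {1, 3}
        assert all(0.0 <= p <= 1.0 for p in res.aux.values())


class TestFrozenPatch:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_layer2_slot1_frame_equals_parent(self, small_slide, seed):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=3, patches=(2, 2, 2), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(seed)).eval()
        trace = model.forward(pyramid).traces[0]
        lookup = trace.by_name()
        for e in trace.entries:
            if e.layer == 2 and e.slot == 1:
                parent = lookup[e.parent]
                assert e.frame.center_x == parent.frame.center_x
                assert e.frame.center_y == parent.frame.center_y
                assert e.frame.half_w == parent.frame.half_w
                assert e.frame.half_h == parent.frame.half_h

    def test_frozen_disabled_uses_branch(self, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(
            layers=2, patches=(2, 2), frozen_patch=False, **TINY_MODEL
        )
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        trace = model.forward(pyramid).traces[0]
        lookup = trace.by_name()
        frames_equal = [
            e.frame == lookup[e.parent].frame
            for e in trace.entries
            if e.layer == 2 and e.slot == 1
        ]
        assert not all(frames_equal)


class TestThetaOverride:
    def test_identity_everywhere_keeps_frames(self, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=2, patches=(2, 2), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        res = model.forward(
            pyramid, theta_override=lambda l, v, p: AffineParams.identity()
        )
        root = res.traces[0].entries[0].frame
        for e in res.traces[0].entries:
            assert e.frame.half_w == root.half_w
            assert e.frame.center_x == root.center_x

    def test_constant_scale_compounds_geometrically(self, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=3, patches=(1, 1, 1), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        res = model.forward(
            pyramid, theta_override=lambda l, v, p: AffineParams(0.5, 0.0, 0.0)
        )
        root = res.traces[0].entries[0].frame
        for e in res.traces[0].entries:
            depth = len(e.name) - 2
            assert e.frame.hc == pytest.approx(root.hc * 0.5**depth)

    def test_zoom_monotone_when_s_below_one(self, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=3, patches=(2, 1, 2), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        res = model.forward(
            pyramid, theta_override=lambda l, v, p: AffineParams(0.8, 0.1, -0.1)
        )
        lookup = res.traces[0].by_name()
        for e in res.traces[0].entries:
            if e.parent is not None:
                assert e.frame.half_w <= lookup[e.parent].frame.half_w + 1e-9


class TestHeads:
    def test_gru_sequence_length_equals_n_large(self, tiny_model_323, small_slide):
        pyramid, _ = small_slide
        trace = tiny_model_323.forward(pyramid).traces[0]
        finals = trace.at_resolution(224)
        assert len(finals) == count_patches(tiny_model_323.config).n_large

    def test_classification_head_contract(self, tiny_model_323):
        patches = [RNG.integers(0, 255, (224, 224, 3), dtype=np.uint8)] * 4
        y1 = tiny_model_323.classification_head(patches)
        y2 = tiny_model_323.classification_head(patches)
        assert 0.0 < y1 < 1.0 and y1 == y2
        with pytest.raises(ContractError):
            tiny_model_323.classification_head([])

    def test_auxiliary_predict_semantics(self, tiny_model_323):
        aux = tiny_model_323.aux["1"]
        patch = RNG.integers(0, 255, (56, 56, 3), dtype=np.uint8)
        p_pos = auxiliary_predict([patch], aux, 1)
        p_neg = auxiliary_predict([patch], aux, 0)
        assert p_pos == pytest.approx(1.0 - p_neg)
        assert 0.0 <= p_pos <= 1.0
        with pytest.raises(ContractError):
            auxiliary_predict([], aux, 1)

    def test_auxiliary_mean_then_complement(self, monkeypatch, tiny_model_323):
        # two patches with probabilities 0.6 and 0.8 under y=0 -> 0.3
        aux = tiny_model_323.aux["1"]
        from magnet._tensor import Tensor

        outputs = iter([np.array([[0.6]]), np.array([[0.8]])])

        class Stub:
            training = False

            def eval(self):
                return self

            def train(self, mode=True):
                return self

            def __call__(self, patches):
                probs = [Tensor(next(outputs).reshape(-1)) for _ in patches]
                return sum(probs[1:], probs[0]) / float(len(probs))

        patch = RNG.integers(0, 255, (56, 56, 3), dtype=np.uint8)
        assert auxiliary_predict([patch, patch], Stub(), 0) == pytest.approx(0.3)


class TestMagnifyingLayerOp:
    def test_patch_multiplication(self, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=2, patches=(2, 2), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        from magnet import read_region, root_frame

        frame = root_frame(pyramid)
        views = [(frame, read_region(pyramid, frame, 56))] * 3
        children, entries = model.magnifying_layer(views, pyramid, 1)
        assert len(children) == 6  # 3 views x 2 slots
        assert all(img.shape == (56, 56, 3) for _, img in children)

    def test_final_layer_resolution(self, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=2, patches=(2, 2), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        from magnet import read_region, root_frame

        frame = root_frame(pyramid)
        views = [(frame, read_region(pyramid, frame, 56))]
        children, entries = model.magnifying_layer(views, pyramid, 2)
        assert all(img.shape == (224, 224, 3) for _, img in children)
        assert all(e.resolution == 224 for e in entries)


class TestCheckpoint:
    def test_round_trip_reproduces_forward(self, tmp_path, small_slide):
        pyramid, _ = small_slide
        cfg = MagNetConfig(layers=2, patches=(2, 2), **TINY_MODEL)
        model = MagNet(cfg, rng=np.random.default_rng(0)).eval()
        y1 = model.forward(pyramid).y_hat
        save_checkpoint(tmp_path / "ckpt.npz", model, extra={"note": "t"})
        loaded, extra = load_checkpoint(tmp_path / "ckpt.npz")
        assert extra == {"note": "t"}
        y2 = loaded.eval().forward(pyramid).y_hat
        assert y1 == pytest.approx(y2, abs=1e-7)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(InvalidRequestError):
            MagNet(
                MagNetConfig(layers=1, patches=(1,), backbone="nope"),
                rng=np.random.default_rng(0),
            )

    def test_pretrained_backbones_need_registration(self):
        with pytest.raises(NotImplementedError):
            MagNet(
                MagNetConfig(layers=1, patches=(1,), backbone="inception-v3"),
                rng=np.random.default_rng(0),
            )
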