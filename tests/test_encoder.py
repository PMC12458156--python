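"""Adapter-augmented encoder: layouts, residual identity, sharing."""

import math

import numpy as np
import pytest

import fewpick as fp
from fewpick.encoder import LARGE_DEPTHS, LARGE_DIMS


class TestStageSpecs:
    def test_paper_large_layout(self):
        specs = fp.make_stage_specs("paper_large")
        assert [s.embed_dim for s in specs] == [144, 288, 576, 1152]
        assert [s.depth for s in specs] == [2, 6, 36, 4]
        assert specs[2].embed_dim == 576 and specs[2].depth == 36

    def test_total_adapter_count(self):
        specs = fp.make_stage_specs("paper_large")
        assert sum(s.depth for s in specs) == 2 + 6 + 36 + 4

    def test_toy_scaling(self):
        specs = fp.make_stage_specs("toy", toy_scale=8)
        assert [s.embed_dim for s in specs] == [18, 36, 72, 144]
        assert [s.depth for s in specs] == list(LARGE_DEPTHS)

    def test_non_divisible_toy_scale_rejected(self):
        with pytest.raises(ValueError, match="does not divide"):
            fp.make_stage_specs("toy", toy_scale=7)


class TestInitAdapters:
    def test_layer_counts_paper_preset(self):
        bank = fp.init_adapters(fp.make_stage_specs("paper_large"))
        assert bank.n_unshared_layers == 48
        assert bank.n_shared_layers == 4

    def test_deterministic_init(self, toy_specs):
        a = fp.init_adapters(toy_specs, seed=5)
        b = fp.init_adapters(toy_specs, seed=5)
        for (na, pa, _), (nb, pb, _) in zip(
            a.named_parameters(), b.named_parameters()
        ):
            assert na == nb and np.array_equal(pa, pb)

    def test_full_ratio_gives_square_unshared(self, toy_specs):
        bank = fp.init_adapters(toy_specs, bottleneck_ratio=1.0)
        for stage in bank.blocks:
            for ad in stage:
                assert ad.W_down.shape[0] == ad.W_down.shape[1]

    def test_global_sharing_rejected_without_common_bottleneck(self, toy_specs):
        with pytest.raises(ValueError, match="common bottleneck"):
            fp.init_adapters(toy_specs, sharing="global")

    def test_global_sharing_with_explicit_bottleneck(self, toy_specs):
        bank = fp.init_adapters(toy_specs, sharing="global", bottleneck_dim=6)
        # one globally shared core: perturbing it moves every stage's output
        rng = np.random.default_rng(0)
        feats = [
            fp.FeatureMap(rng.normal(size=(1, 4, 4, s.embed_dim)), s.index, 0)
            for s in toy_specs
        ]
        before = [
            fp.adapter_apply(bank.adapter(si, 0), f).values
            for si, f in enumerate(feats)
        ]
        core = dict((n, p) for n, p, _ in bank.named_parameters())["adapter.core.W"]
        core += 0.1
        after = [
            fp.adapter_apply(bank.adapter(si, 0), f).values
            for si, f in enumerate(feats)
        ]
        for b, a in zip(before, after):
            assert not np.allclose(b, a)


class TestAdapterApply:
    def test_zero_up_projection_is_identity(self, toy_specs):
        bank = fp.init_adapters(toy_specs, seed=0)  # up starts at zero
        rng = np.random.default_rng(1)
        f = fp.FeatureMap(rng.normal(size=(2, 8, 8, 18)), 1, 0)
        out = fp.adapter_apply(bank.adapter(0, 0), f)
        assert np.array_equal(out.values, f.values)

    def test_scalar_closed_form(self):
        # 1-channel adapter: y = x + 0.5 * gelu(2x), gelu(z) = z * Phi(z)
        ad = fp.AdapterParams(
            W_down=np.array([[2.0]]),
            b_down=np.zeros(1),
            up_layers=((np.array([[0.5]]), np.zeros(1)),),
            name_down="a",
            names_up=("u",),
        )
        f = fp.FeatureMap(np.ones((1, 1, 1, 1)), 1, 0)
        out = fp.adapter_apply(ad, f).values.item()
        phi2 = 0.5 * (1.0 + math.erf(2.0 / math.sqrt(2.0)))
        assert out == pytest.approx(1.0 + 0.5 * 2.0 * phi2, rel=1e-12)

    def test_shape_preserved_each_stage(self, toy_specs):
        bank = fp.init_adapters(toy_specs, seed=2)
        rng = np.random.default_rng(3)
        for si, spec in enumerate(toy_specs):
            f = fp.FeatureMap(
                rng.normal(size=(2, 8, 8, spec.embed_dim)), spec.index, 0
            )
            assert fp.adapter_apply(bank.adapter(si, 0), f).values.shape == (
                2, 8, 8, spec.embed_dim,
            )

    def test_dimension_mismatch_rejected(self, toy_specs):
        bank = fp.init_adapters(toy_specs)
        f = fp.FeatureMap(np.zeros((1, 4, 4, 7)), 1, 0)
        with pytest.raises(ValueError, match="channels"):
            fp.adapter_apply(bank.adapter(0, 0), f)

    def test_shared_layer_aliasing_within_stage(self, toy_specs):
        """Mutating a stage's shared up-projection changes every block."""
        bank = fp.init_adapters(toy_specs, seed=4)
        rng = np.random.default_rng(5)
        f = fp.FeatureMap(rng.normal(size=(1, 4, 4, 18)), 1, 0)
        bank.adapter(0, 0).up_layers[0][0][...] += 0.3  # shared W_up of stage 1
        for bj in range(toy_specs[0].depth):
            out = fp.adapter_apply(bank.adapter(0, bj), f)
            assert not np.allclose(out.values, f.values)


class TestEncode:
    def test_zero_adapters_match_backbone_exactly(self, toy_specs):
        backbone = fp.ToyBackbone(toy_specs, seed=0)
        adapters = fp.init_adapters(toy_specs, seed=1)
        x = np.random.default_rng(2).normal(size=(64, 64))
        with_ad = fp.encode(x, backbone, adapters)
        bare = fp.encode(x, backbone, None)
        for a, b in zip(with_ad, bare):
            assert np.array_equal(a.values, b.values)

    def test_deterministic_features(self, toy_specs):
        backbone = fp.ToyBackbone(toy_specs, seed=0)
        adapters = fp.init_adapters(toy_specs, seed=1)
        x = np.random.default_rng(3).normal(size=(64, 64))
        f1 = fp.encode(x, backbone, adapters)
        f2 = fp.encode(x, backbone, adapters)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.values, b.values)

    def test_spatial_dims_follow_stage_scales(self, toy_specs):
        backbone = fp.ToyBackbone(toy_specs, seed=0)
        feats = fp.encode(np.zeros((64, 64)), backbone, None)
        for f, spec in zip(feats, toy_specs):
            expected = 64 // spec.spatial_scale
            assert f.values.shape[1:3] == (expected, expected)

    def test_backbone_adapter_mismatch_rejected(self, toy_specs):
        backbone = fp.ToyBackbone(toy_specs, seed=0)
        other = fp.init_adapters(fp.make_stage_specs("toy", toy_scale=4))
        with pytest.raises(ValueError, match="do not match"):
            fp.encode(np.zeros((64, 64)), backbone, other)


class TestCountTrainableParams:
    def test_analytic_count_toy_model(self):
        model = fp.build_toy_model(toy_scale=8, input_size=64, seed=0)
        dims = [d // 8 for d in LARGE_DIMS]
        expected = 0
        for d, depth in zip(dims, LARGE_DEPTHS):
            b = max(1, round(d * 0.25))
            expected += depth * (d * b + b)  # unshared down-projections
            expected += b * d + d  # shared up-projection per stage
        expected += sum(dims) + 2  # decoder stage weights + image skip + bias
        assert fp.count_trainable_params(model) == expected

    def test_all_frozen_counts_zero(self, toy_specs):
        backbone = fp.ToyBackbone(toy_specs, seed=0)
        assert fp.count_trainable_params(backbone) == 0

    def test_unfreezing_backbone_increases_count(self):
        model = fp.build_toy_model(toy_scale=8, input_size=64, seed=0)
        frozen = fp.count_trainable_params(model)
        model.backbone.frozen = False
        assert fp.count_trainable_params(model) > frozen
        model.backbone.frozen = True
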