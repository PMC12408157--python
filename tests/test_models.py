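"""Model assembly: encoder stage contracts, aggregation semantics, shape
contracts, determinism, gradient reach and the E-vs-U parameter property."""

import numpy as np
import pytest

from esegnet.config import ModelConfig, build_model
from esegnet.models import (EModel, MirrorDecoder, ToyEncoder2D, ToyEncoder3D,
                            build_encoder, e_ify, verify_contract)
from esegnet.types import EncoderStageSpec, FeatureMap, StagePyramid


class TestToyEncoders:
    def test_2d_stride_pyramid(self, rng):
        enc = ToyEncoder2D(widths=(16, 24, 32, 48, 64), rng=rng)
        enc.eval()
        pyr = enc.forward_pyramid(np.zeros((1, 1, 64, 64), np.float32))
        sizes = [fm.spatial for fm in pyr.stages]
        assert sizes == [(32, 32), (16, 16), (8, 8), (4, 4), (2, 2)]
        assert [s.stride for s in pyr.specs] == [
            (2, 2), (4, 4), (8, 8), (16, 16), (32, 32)]

    def test_3d_patch_embedding_and_plane_halvings(self, rng):
        enc = ToyEncoder3D(rng=rng)
        enc.eval()
        pyr = enc.forward_pyramid(np.zeros((1, 1, 32, 32, 16), np.float32))
        sizes = [fm.spatial for fm in pyr.stages]
        assert sizes == [(8, 8, 8), (8, 8, 8), (4, 4, 8), (2, 2, 8), (1, 1, 8)]

    def test_seed_determinism(self):
        a = ToyEncoder2D(rng=np.random.default_rng(11))
        b = ToyEncoder2D(rng=np.random.default_rng(11))
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_wrong_width_count_rejected(self, rng):
        with pytest.raises(ValueError, match="5 stage widths"):
            ToyEncoder2D(widths=(8, 16), rng=rng)

    def test_contract_verification_names_bad_stage(self, rng):
        enc = ToyEncoder2D(rng=rng)
        # corrupt the metadata of stage 3 to simulate a missing tap
        enc.stage_specs[2] = EncoderStageSpec(3, (4, 4), enc.stage_specs[2].channels)
        with pytest.raises(ValueError, match="stage 3"):
            verify_contract(enc)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown encoder"):
            build_encoder("mobilenetv4")


class TestAggregation:
    def _model(self, subset, rng):
        enc = ToyEncoder2D(rng=rng)
        return EModel(enc, 4, aggregation_width=16, stage_subset=subset,
                      refinement="none", rng=rng)

    def test_singleton_subset_equals_upconv(self, rng):
        m = self._model([3], np.random.default_rng(2))
        m.eval()
        x = rng.standard_normal((1, 1, 64, 64)).astype(np.float32)
        pyr = m.encoder.forward_pyramid(x)
        agg = m.aggregate(pyr, (64, 64))
        direct = m.upconvs[0](pyr.stage(3).values, (64, 64))
        np.testing.assert_array_equal(agg, direct)

    def test_sum_matches_direct_addition(self, rng):
        m = self._model([2, 5], np.random.default_rng(2))
        m.eval()
        x = rng.standard_normal((1, 1, 64, 64)).astype(np.float32)
        pyr = m.encoder.forward_pyramid(x)
        a = m.upconvs[0](pyr.stage(2).values, (64, 64))
        b = m.upconvs[1](pyr.stage(5).values, (64, 64))
        np.testing.assert_allclose(m.aggregate(pyr, (64, 64)), a + b,
                                   atol=1e-6)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            self._model([], rng)

    def test_subset_outside_stages_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            self._model([6], rng)


class TestEModel2D:
    def test_output_shape_contract(self, rng):
        m = EModel(ToyEncoder2D(in_channels=3, rng=rng), 9, rng=rng)
        m.eval()
        y = m(np.zeros((2, 3, 64, 64), np.float32))
        assert y.shape == (2, 9, 64, 64)

    def test_default_subset_is_all_five_stages(self, rng):
        m = EModel(ToyEncoder2D(rng=rng), 4, rng=rng)
        assert m.stage_subset == (1, 2, 3, 4, 5)

    def test_indivisible_input_rejected(self, rng):
        m = EModel(ToyEncoder2D(rng=rng), 4, rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            m(np.zeros((1, 1, 60, 60), np.float32))

    def test_zeroed_head_gives_zero_logits(self, rng):
        m = EModel(ToyEncoder2D(rng=rng), 4, refinement="none", rng=rng)
        m.head.weight.data[...] = 0.0
        m.head.bias.data[...] = 0.0
        m.eval()
        y = m(np.random.default_rng(0).standard_normal(
            (1, 1, 64, 64)).astype(np.float32))
        assert np.all(y == 0.0)

    def test_inference_determinism(self):
        cfg = ModelConfig(dim=2, num_classes=4, seed=5)
        x = np.random.default_rng(1).standard_normal(
            (1, 1, 64, 64)).astype(np.float32)
        outs = []
        for _ in range(2):
            m = build_model(cfg)
            m.eval()
            outs.append(m(x))
        np.testing.assert_array_equal(outs[0], outs[1])
        np.testing.assert_array_equal(m(x), outs[1])  # repeated call too

    def test_total_params_equal_encoder_plus_head(self, rng):
        m = EModel(ToyEncoder2D(rng=rng), 4, rng=rng)
        assert m.num_params() == m.encoder.num_params() + m.head_num_params()


class TestEModel3D:
    def test_output_shape_contract(self, rng):
        m = EModel(ToyEncoder3D(rng=rng), 4, aggregation_width=16, rng=rng)
        m.eval()
        y = m(np.zeros((1, 1, 64, 64, 16), np.float32))
        assert y.shape == (1, 4, 64, 64, 16)

    def test_default_subset_excludes_patch_embedding(self, rng):
        m = EModel(ToyEncoder3D(rng=rng), 4, aggregation_width=16, rng=rng)
        assert m.stage_subset == (2, 3, 4, 5)
        assert len(m.upconvs) == 4
        full = EModel(ToyEncoder3D(rng=rng), 4, aggregation_width=16,
                      stage_subset=[1, 2, 3, 4, 5], rng=rng)
        assert len(full.upconvs) == 5

    def test_slice_axis_divisibility(self, rng):
        m = EModel(ToyEncoder3D(rng=rng), 4, aggregation_width=16, rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            m(np.zeros((1, 1, 32, 32, 15), np.float32))


class TestGradientReach:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_every_parameter_receives_gradient(self, dim):
        rng = np.random.default_rng(17)
        if dim == 2:
            m = EModel(ToyEncoder2D(widths=(8, 12, 16, 24, 32), rng=rng), 3,
                       aggregation_width=16, rng=rng)
            x = rng.standard_normal((2, 1, 64, 64)).astype(np.float32)
        else:
            m = EModel(ToyEncoder3D(widths=(8, 12, 16, 24, 32), rng=rng), 3,
                       aggregation_width=8, rng=rng)
            x = rng.standard_normal((1, 1, 32, 32, 8)).astype(np.float32)
        m.train()
        y = m(x)
        m.zero_grad()
        m.backward(rng.standard_normal(y.shape).astype(np.float32))
        dead = [n for n, p in m.named_parameters() if np.all(p.grad == 0.0)]
        assert dead == []


class TestParameterMonotonicity:
    def test_param_count_grows_with_subset(self):
        prev = 0
        for k in range(1, 6):
            m = EModel(ToyEncoder2D(rng=np.random.default_rng(0)), 4,
                       stage_subset=list(range(1, k + 1)),
                       rng=np.random.default_rng(0))
            n = m.num_params()
            assert n > prev
            prev = n


class TestEify:
    def test_head_params_are_sum_of_block_counts(self):
        rng = np.random.default_rng(3)
        enc = ToyEncoder2D(rng=rng)
        m = e_ify(enc, 4, aggregation_width=32, rng=rng)
        expect = sum(u.num_params() for u in m.upconvs)
        expect += m.refine.num_params() + m.head.num_params()
        assert m.head_num_params() == expect

    def test_head_params_independent_of_encoder_depth_beyond_taps(self):
        rng = np.random.default_rng(3)
        a = e_ify(ToyEncoder2D(widths=(8, 8, 8, 8, 8), rng=rng), 4,
                  stage_subset=[4, 5], rng=rng)
        b = e_ify(ToyEncoder2D(widths=(16, 32, 48, 8, 8), rng=rng), 4,
                  stage_subset=[4, 5], rng=rng)
        assert a.head_num_params() == b.head_num_params()

    @pytest.mark.parametrize("dim", [2, 3])
    def test_e_head_smaller_than_mirror_decoder(self, dim):
        rng = np.random.default_rng(4)
        enc = (ToyEncoder2D(rng=rng) if dim == 2
               else ToyEncoder3D(rng=rng))
        width = 64 if dim == 2 else 16
        m = e_ify(enc, 4, aggregation_width=width, rng=rng)
        mirror = MirrorDecoder(enc, 4, rng=rng)
        assert m.head_num_params() < mirror.num_params()

    def test_mirror_decoder_runs(self, rng):
        enc = ToyEncoder2D(widths=(8, 12, 16, 24, 32),
                           rng=np.random.default_rng(1))
        enc.eval()
        mirror = MirrorDecoder(enc, 4, rng=np.random.default_rng(1))
        mirror.eval()
        x = np.zeros((1, 1, 64, 64), np.float32)
        pyr = enc.forward_pyramid(x)
        assert mirror(pyr, (64, 64)).shape == (1, 4, 64, 64)
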