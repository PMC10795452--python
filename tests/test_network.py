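"""Architecture contracts: layer shapes, attention properties, fusion bounds."""

import numpy as np
import pytest

from st4dseg.nn.autograd import Tensor
from st4dseg.core import TripletPair
from st4dseg.network import (
    BaselineUNet,
    ChannelAttention,
    DualPathUNet,
    EncoderPath,
    NetworkConfig,
    SpatialAttention,
    load_checkpoint,
    save_checkpoint,
    shape_table,
)

SMALL = NetworkConfig(base_channels=8, seed=0)


def _rows_dict(rows):
    return {name: out for name, _, out in rows}


@pytest.fixture(scope="module")
def rows():
    return _rows_dict(shape_table(NetworkConfig(base_channels=64), 512))


class TestShapeContract:
    """The full-scale (512 input, 64 base channels) per-layer output table."""

    def test_encoder_sides_halve_and_channels_double(self, rows):
        expected = {
            "Conv_1": "512x512x64",
            "Conv_2": "256x256x128",
            "Conv_3": "128x128x256",
            "Conv_4": "64x64x512",
            "Conv_5": "32x32x1024",
        }
        for name, out in expected.items():
            assert rows[name] == out
            assert rows[name + "_1"] == out

    def test_bottleneck_is_one_sixteenth_with_16c_channels(self, rows):
        assert rows["Conv_5_1"] == "32x32x1024"

    def test_fused_map_shape(self, rows):
        assert rows["Fuse"] == "32x32x1024"

    def test_decoder_rows(self, rows):
        assert rows["Conv_6"] == "64x64x1024"
        assert rows["Conv_7"] == "128x128x512"
        assert rows["Conv_8"] == "256x256x256"
        assert rows["Conv_9"] == "512x512x128"
        assert rows["Conv_10"] == "512x512x1"

    def test_spatial_attention_kernel_is_7(self):
        cfg = NetworkConfig(base_channels=64)
        assert cfg.spatial_kernel == 7
        att = SpatialAttention(cfg.spatial_kernel, np.random.default_rng(0))
        assert att.conv.weight.data.shape == (1, 2, 7, 7)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            shape_table(NetworkConfig(base_channels=64), 500)


class TestEncoder:
    def test_desk_scale_bottom_map(self, rng):
        enc = EncoderPath(3, 8, np.random.default_rng(0))
        levels = enc(rng.random((1, 3, 64, 64)).astype(np.float32))
        assert len(levels) == 5
        assert levels[-1].shape == (1, 128, 4, 4)
        sides = [lv.shape[2] for lv in levels]
        assert sides == [64, 32, 16, 8, 4]

    def test_zero_input_gives_zero_features(self):
        enc = EncoderPath(3, 4, np.random.default_rng(0))
        for m in enc.modules():
            m.training = False  # eval BN: identity on zeros with fresh buffers
        levels = enc(np.zeros((1, 3, 32, 32), dtype=np.float32))
        for lv in levels:
            assert np.all(lv.data == 0)


@pytest.fixture()
def att_c():
    return ChannelAttention(32, 16, np.random.default_rng(1))


class TestChannelAttention:

    def test_outputs_in_open_unit_interval(self, att_c, rng):
        f_s = rng.standard_normal((2, 16, 4, 4)).astype(np.float32)
        f_t = rng.standard_normal((2, 16, 4, 4)).astype(np.float32)
        m = att_c(Tensor(f_s), Tensor(f_t)).data
        assert m.shape == (2, 32)
        assert np.all((m > 0) & (m < 1))

    def test_spatial_permutation_invariance(self, att_c, rng):
        f_s = rng.standard_normal((1, 16, 4, 4)).astype(np.float32)
        f_t = rng.standard_normal((1, 16, 4, 4)).astype(np.float32)
        perm = rng.permutation(16)
        def permute(f):
            flat = f.reshape(1, 16, 16)[:, :, perm]
            return flat.reshape(1, 16, 4, 4)
        base = att_c(Tensor(f_s), Tensor(f_t)).data
        shuffled = att_c(Tensor(permute(f_s)), Tensor(permute(f_t))).data
        assert shuffled == pytest.approx(base, abs=1e-6)

    def test_zero_input_gives_half(self, att_c):
        z = np.zeros((1, 16, 4, 4), dtype=np.float32)
        assert att_c(Tensor(z), Tensor(z)).data == pytest.approx(0.5)


@pytest.fixture()
def att_s():
    return SpatialAttention(7, np.random.default_rng(2))


class TestSpatialAttention:

    def test_output_extent_matches_input(self, att_s, rng):
        f = rng.standard_normal((1, 24, 8, 8)).astype(np.float32)
        m = att_s(Tensor(f)).data
        assert m.shape == (1, 1, 8, 8)
        assert np.all((m > 0) & (m < 1))

    def test_channel_permutation_invariance(self, att_s, rng):
        f = rng.standard_normal((1, 24, 8, 8)).astype(np.float32)
        perm = rng.permutation(24)
        base = att_s(Tensor(f)).data
        shuffled = att_s(Tensor(f[:, perm])).data
        assert shuffled == pytest.approx(base, abs=1e-6)

    def test_zeroed_kernel_gives_uniform_half(self, rng):
        att = SpatialAttention(7, np.random.default_rng(3))
        att.conv.weight.data[:] = 0
        att.conv.bias.data[:] = 0
        f = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        assert att(Tensor(f)).data == pytest.approx(0.5)


class TestFusion:
    def test_fused_shape_and_magnitude_bound(self, rng):
        model = DualPathUNet(SMALL).eval()
        f_s = Tensor(rng.standard_normal((1, 128, 4, 4)).astype(np.float32))
        f_t = Tensor(rng.standard_normal((1, 128, 4, 4)).astype(np.float32))
        fused, m_c, m_s, f_prime, f_second = model.fusion(f_s, f_t, return_maps=True)
        assert fused.shape == (1, 128, 4, 4)
        f = np.concatenate([f_s.data, f_t.data], axis=1)
        # both gates are < 1, so gated features never exceed the raw ones
        assert np.all(np.abs(f_second.data) <= np.abs(f) + 1e-7)
        assert np.all((m_c.data > 0) & (m_c.data < 1))
        assert np.all((m_s.data > 0) & (m_s.data < 1))


class TestForward:
    def test_desk_scale_output_shape(self, rng):
        model = DualPathUNet(SMALL).eval()
        xs = rng.random((2, 3, 64, 64)).astype(np.float32)
        xt = rng.random((2, 3, 64, 64)).astype(np.float32)
        assert model(xs, xt).shape == (2, 1, 64, 64)

    def test_deterministic_forward(self, rng):
        model = DualPathUNet(SMALL).eval()
        xs = rng.random((1, 3, 32, 32)).astype(np.float32)
        xt = rng.random((1, 3, 32, 32)).astype(np.float32)
        a = model(xs, xt).data
        b = model(xs, xt).data
        assert np.array_equal(a, b)

    def test_zero_input_gives_zero_logits(self):
        model = DualPathUNet(SMALL).eval()
        z = np.zeros((1, 3, 32, 32), dtype=np.float32)
        assert np.all(model(z, z).data == 0)

    def test_temporal_direction_not_forced_symmetric(self, rng):
        model = DualPathUNet(SMALL).eval()
        xs = rng.random((1, 3, 32, 32)).astype(np.float32)
        xt = rng.random((1, 3, 32, 32)).astype(np.float32)
        fwd = model(xs, xt).data
        rev = model(xs, xt[:, ::-1].copy()).data
        assert not np.allclose(fwd, rev)

    def test_forward_pair_accepts_triplets(self, rng):
        hu = (rng.random((3, 32, 32)) * 500 - 200).astype(np.float32)
        pair = TripletPair(hu, hu.copy(), (0, 0))
        model = DualPathUNet(SMALL).eval()
        assert model.forward_pair(pair).shape == (32, 32)

    def test_indivisible_extent_rejected(self, rng):
        model = DualPathUNet(SMALL).eval()
        x = rng.random((1, 3, 30, 30)).astype(np.float32)
        with pytest.raises(ValueError, match="divisible"):
            model(x, x)


class TestBaseline:
    def test_output_shape_contract(self, rng):
        model = BaselineUNet(SMALL).eval()
        assert model(rng.random((1, 5, 64, 64)).astype(np.float32)).shape == (1, 1, 64, 64)

    def test_fewer_parameters_than_dual_path(self):
        assert BaselineUNet(SMALL).num_parameters() < DualPathUNet(SMALL).num_parameters()

    def test_zero_input_gives_zero_logits(self):
        model = BaselineUNet(SMALL).eval()
        assert np.all(model(np.zeros((1, 5, 32, 32), dtype=np.float32)).data == 0)


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = DualPathUNet(SMALL).eval()
        xs = rng.random((1, 3, 32, 32)).astype(np.float32)
        xt = rng.random((1, 3, 32, 32)).astype(np.float32)
        expected = model(xs, xt).data
        save_checkpoint(model, tmp_path / "ckpt.npz")
        loaded = load_checkpoint(tmp_path / "ckpt.npz")
        assert np.array_equal(loaded(xs, xt).data, expected)
        assert loaded.config == model.config

    def test_missing_checkpoint(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.npz")
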