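"""Architecture contracts: shapes, weight sharing, wiring, checkpointing."""

import numpy as np
import pytest

from gscnet import (
    ModelConfig,
    PatientTriplet,
    build_model,
    load_checkpoint,
    predict,
    save_checkpoint,
)
from gscnet import nn
from gscnet.model import SCHead

from conftest import tiny_model_config


def _images(rng, n, size):
    return rng.random((n, size, size, 3)).astype(np.float32)


# -- independent per-layer parameter arithmetic (the counting oracle) --------


def conv_p(i, o, k, bias=False):
    return o * i * k * k + (o if bias else 0)


def bn_p(c):
    return 2 * c


def linear_p(i, o):
    return i * o + o


def se_p(c, r):
    return linear_p(c, c // r) + linear_p(c // r, c)


def block_p(i, o, s):
    p = conv_p(i, o, 3) + bn_p(o) + conv_p(o, o, 3) + bn_p(o)
    if s != 1 or i != o:
        p += conv_p(i, o, 1) + bn_p(o)
    return p


def stage_p(i, o, s):
    return block_p(i, o, s) + block_p(o, o, 1)


def expected_param_count(cfg: ModelConfig) -> int:
    w1, w2, w3 = cfg.stage_widths
    f = cfg.fusion_channels
    c1, c2 = cfg.sc_conv_channels
    fc1, fc2 = cfg.sc_fc_widths
    n_l = (
        conv_p(3, w1, 7)
        + bn_p(w1)
        + stage_p(w1, w1, 1)
        + stage_p(w1, w2, 2)
        + stage_p(w2, w3, 2)
        + se_p(w3, cfg.se_reduction)
    )
    n_m = (
        conv_p(3, w1, 3)
        + bn_p(w1)
        + stage_p(w1, w1, 2)
        + stage_p(w1, w2, 2)
        + stage_p(w2, w3, 2)
        + se_p(w3, cfg.se_reduction)
    )
    n_s = (
        conv_p(3, w1, 3)
        + bn_p(w1)
        + conv_p(w1, w1, 3)
        + bn_p(w1)
        + stage_p(w1, w2, 2)
        + stage_p(w2, w3, 2)
        + se_p(w3, cfg.se_reduction)
    )
    fusion = conv_p(3 * w3, f, 1) + bn_p(f)

    def head_p(cin):
        return (
            conv_p(cin, c1, 3)
            + bn_p(c1)
            + conv_p(c1, c2, 3)
            + bn_p(c2)
            + linear_p(c2, fc1)
            + linear_p(fc1, fc2)
            + linear_p(fc2, cfg.n_classes)
        )

    heads = head_p(2 * f) * 2 + head_p(3 * f) + linear_p(3 * fc2, cfg.n_classes)
    return n_l + n_m + n_s + fusion + heads


class TestBuild:
    def test_same_seed_gives_identical_parameters(self):
        cfg = tiny_model_config()
        m1 = build_model(cfg, seed=3)
        m2 = build_model(cfg, seed=3)
        p1, p2 = m1.parameters(), m2.parameters()
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.data, b.data)
        m3 = build_model(cfg, seed=4)
        assert any(
            not np.array_equal(a.data, b.data)
            for a, b in zip(p1, m3.parameters())
        )

    def test_three_branches_and_four_heads(self, tiny_model):
        assert tiny_model.branch_l is not None
        assert tiny_model.branch_m is not None
        assert tiny_model.branch_s is not None
        n_sc_heads = sum(1 for m in tiny_model.modules() if isinstance(m, SCHead))
        assert n_sc_heads == 3
        assert tiny_model.fusion_classifier is not None  # the fourth head

    def test_parameter_count_matches_layer_arithmetic(self, tiny_model):
        assert tiny_model.num_parameters() == expected_param_count(tiny_model.cfg)

    def test_parameter_count_default_config(self):
        cfg = ModelConfig()
        assert expected_param_count(cfg) == build_model(cfg, seed=0).num_parameters()

    def test_input_size_must_divide_by_16(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            ModelConfig(input_size=100)

    def test_pretrained_mode_requires_weights_file(self):
        with pytest.raises(ValueError, match="backbone_weights"):
            build_model(tiny_model_config(init_mode="pretrained-backbone"), seed=0)


class TestSFF:
    @pytest.mark.parametrize("input_size", [32, 48])
    def test_fused_feature_shapes(self, rng, input_size):
        cfg = tiny_model_config(input_size=input_size)
        model = build_model(cfg, seed=0)
        x = _images(rng, 2, input_size)
        f_a, f_b, f_c = model.sff_forward(x, x, x)
        side = input_size // 16
        for f in (f_a, f_b, f_c):
            assert f.data.shape == (2, cfg.fusion_channels, side, side)

    def test_branch_weights_shared_across_sections(self, tiny_model, rng):
        """Identical pixel content in any two section slots yields identical
        fused features: the branch parameters are one set, not copies."""
        same = _images(rng, 2, 32)
        other = _images(rng, 2, 32)
        f_a, f_b, f_c = tiny_model.sff_forward(same, same, other)
        np.testing.assert_array_equal(f_a.data, f_b.data)
        assert not np.array_equal(f_a.data, f_c.data)

    def test_branch_parameters_are_identical_objects_across_calls(self, tiny_model):
        ids_before = [id(p.data) for p in tiny_model.branch_l.parameters()]
        assert ids_before == [id(p.data) for p in tiny_model.branch_l.parameters()]

    def test_zero_images_give_finite_output(self, tiny_model):
        zeros = np.zeros((1, 32, 32, 3), dtype=np.float32)
        f_a, _, _ = tiny_model.sff_forward(zeros, zeros, zeros)
        assert np.isfinite(f_a.data).all()

    def test_wrong_shape_reports_expected_vs_actual(self, tiny_model, rng):
        bad = _images(rng, 1, 16)
        with pytest.raises(ValueError, match=r"\(32, 32, 3\)"):
            tiny_model.sff_forward(bad, bad, bad)


class TestSC:
    def _features(self, rng, cfg, fill_a=None, fill_b=None, fill_c=None):
        shape = (2, cfg.fusion_channels, cfg.feature_size, cfg.feature_size)
        vals = []
        for fill in (fill_a, fill_b, fill_c):
            if fill is None:
                vals.append(nn.Tensor(rng.random(shape).astype(np.float32)))
            else:
                vals.append(nn.Tensor(np.full(shape, fill, dtype=np.float32)))
        return vals

    def test_head_probabilities_sum_to_one(self, tiny_model, rng):
        f_a, f_b, f_c = self._features(rng, tiny_model.cfg)
        out = tiny_model.sc_forward(f_a, f_b, f_c)
        for probs in (out.p_ab, out.p_ac, out.p_abc, out.p_fusion):
            np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_swapping_body_and_cardia_swaps_head_conditioning(self, tiny_model, rng):
        """The antrum is the anchor: the AB head sees the body slot and the AC
        head the cardia slot, so exchanging those slots changes both heads."""
        f_a, f_b, f_c = self._features(rng, tiny_model.cfg, None, 0.2, 0.9)
        out1 = tiny_model.sc_forward(f_a, f_b, f_c)
        out2 = tiny_model.sc_forward(f_a, f_c, f_b)
        assert not np.allclose(out1.p_ab.data, out2.p_ab.data)
        assert not np.allclose(out1.p_ac.data, out2.p_ac.data)

    def test_architecture_not_symmetric_under_section_permutation(self, tiny_model, rng):
        x = _images(rng, 1, 32)
        y = _images(rng, 1, 32)
        z = _images(rng, 1, 32)
        tiny_model.eval()
        out_abc = tiny_model.forward(x, y, z)
        out_bac = tiny_model.forward(y, x, z)
        assert not np.allclose(out_abc.p_fusion.data, out_bac.p_fusion.data)

    def test_fusion_head_input_width_is_sum_of_penultimates(self, tiny_model):
        assert (
            tiny_model.fusion_classifier.in_features
            == 3 * tiny_model.cfg.sc_fc_widths[1]
        )

    def test_mismatched_feature_shapes_rejected(self, tiny_model, rng):
        cfg = tiny_model.cfg
        f_a, f_b, _ = self._features(rng, cfg)
        bad = nn.Tensor(rng.random((2, cfg.fusion_channels, 1, 1)).astype(np.float32))
        with pytest.raises(ValueError, match="does not match"):
            tiny_model.sc_forward(f_a, f_b, bad)


class TestPredictAndCheckpoint:
    def _triplet(self, rng):
        return PatientTriplet(
            "t", *(rng.random((32, 32, 3)).astype(np.float32) for _ in range(3))
        )

    def test_predict_returns_probability_and_tie_goes_positive(self, tiny_model, rng):
        triplet = self._triplet(rng)
        p, label = predict(tiny_model, triplet)
        assert 0.0 <= p <= 1.0
        assert label == int(p >= 0.5)
        # at threshold exactly p the tie resolves positive
        _, tie_label = predict(tiny_model, triplet, threshold=p)
        assert tie_label == 1

    def test_repeated_prediction_identical(self, tiny_model, rng):
        triplet = self._triplet(rng)
        p1, _ = predict(tiny_model, triplet)
        p2, _ = predict(tiny_model, triplet)
        assert p1 == p2

    def test_gradient_reaches_every_parameter(self, rng):
        from gscnet.training import cgi_loss

        model = build_model(tiny_model_config(), seed=1)
        out = model.forward(
            _images(rng, 4, 32), _images(rng, 4, 32), _images(rng, 4, 32)
        )
        _, total = cgi_loss(out, [0, 1, 0, 1])
        total.backward()
        dead = [
            i
            for i, p in enumerate(model.parameters())
            if p.grad is None or not np.abs(p.grad).any()
        ]
        assert dead == []

    def test_checkpoint_roundtrip_bit_exact(self, tiny_model, rng, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        restored = load_checkpoint(path)
        assert restored.cfg == tiny_model.cfg
        s1 = tiny_model.named_state()
        s2 = restored.named_state()
        assert s1.keys() == s2.keys()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])
        triplet = self._triplet(rng)
        assert predict(restored, triplet) == predict(tiny_model, triplet)
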