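"""The four-loss objective, augmentation determinism, optimisation sanity."""

import numpy as np
import pytest

from gscnet import nn
from gscnet import (
    AugmentConfig,
    CohortConfig,
    augment,
    build_model,
    cgi_loss,
    generate_cohort,
    train,
)
from gscnet.model import HeadOutputs
from gscnet.training import TrainConfig

from conftest import tiny_model_config


def _outputs(p_true_per_head):
    """HeadOutputs where every head assigns the given true-class probabilities
    to label 1 (one entry per patient)."""
    p = np.asarray(p_true_per_head, dtype=float)
    probs = np.stack([1 - p, p], axis=1)

    def t():
        return nn.Tensor(probs.copy())

    return HeadOutputs(t(), t(), t(), t())


class TestCgiLoss:
    def test_perfect_prediction_gives_zero_component(self):
        out = _outputs([1.0, 1.0])
        bundle, _ = cgi_loss(out, [1, 1], reduction="sum")
        assert bundle.l_ab == 0.0

    def test_half_probability_is_one_bit(self):
        bundle, _ = cgi_loss(_outputs([0.5]), [1], reduction="sum")
        assert bundle.l_ab == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_batch_in_bits(self):
        """-log2(0.8) - log2(0.25) = 0.321928... + 2 = 2.321928 bits."""
        bundle, _ = cgi_loss(_outputs([0.8, 0.25]), [1, 1], reduction="sum")
        assert bundle.l_ab == pytest.approx(2.321928, abs=1e-6)

    def test_total_is_sum_of_components(self, rng):
        p = rng.uniform(0.05, 0.95, size=6)
        labels = rng.integers(0, 2, size=6)
        bundle, total = cgi_loss(_outputs(p), labels)
        parts = bundle.l_ab + bundle.l_ac + bundle.l_abc + bundle.l_fusion
        assert bundle.l_total == pytest.approx(parts, rel=1e-6)
        assert total.item() == pytest.approx(parts, rel=1e-6)

    def test_negative_class_is_penalised(self):
        """For y=0 the term is -log2(1-p): confident false positives cost."""
        confident_wrong, _ = cgi_loss(_outputs([0.9]), [0], reduction="sum")
        confident_right, _ = cgi_loss(_outputs([0.1]), [0], reduction="sum")
        assert confident_wrong.l_ab > confident_right.l_ab

    def test_base2_vs_natural_log_factor(self):
        p = 0.3
        bundle, _ = cgi_loss(_outputs([p]), [1], reduction="sum")
        assert bundle.l_ab == pytest.approx(-np.log(p) / np.log(2), rel=1e-9)

    def test_degenerate_probabilities_stay_finite(self):
        bundle, _ = cgi_loss(_outputs([0.0, 1.0]), [1, 0], reduction="sum")
        assert np.isfinite(bundle.l_total)

    def test_mean_reduction_divides_by_batch(self):
        s, _ = cgi_loss(_outputs([0.5, 0.5]), [1, 1], reduction="sum")
        m, _ = cgi_loss(_outputs([0.5, 0.5]), [1, 1], reduction="mean")
        assert s.l_ab == pytest.approx(2 * m.l_ab)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            cgi_loss(_outputs([0.5]), [2])

    def test_label_count_must_match_batch(self):
        with pytest.raises(ValueError, match="one label per patient"):
            cgi_loss(_outputs([0.5, 0.5]), [1])


class TestAugment:
    def test_disabled_config_is_identity(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        out = augment(img, AugmentConfig.disabled(), seed=3)
        np.testing.assert_array_equal(out, img)

    def test_deterministic_in_seed(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        cfg = AugmentConfig()
        np.testing.assert_array_equal(
            augment(img, cfg, seed=5), augment(img, cfg, seed=5)
        )

    def test_rotation_180_twice_is_identity(self, rng):
        img = rng.random((8, 8, 3))
        rot = np.rot90(img, k=2, axes=(0, 1))
        np.testing.assert_array_equal(np.rot90(rot, k=2, axes=(0, 1)), img)

    def test_preserves_shape_and_range(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        out = augment(img, AugmentConfig(), seed=11)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestTrain:
    def _cohort(self, n, seed, tiny_render):
        return generate_cohort(CohortConfig(n_patients=n, seed=seed), tiny_render)

    def test_loss_decreases_on_separable_cohort(self, tiny_render):
        cohort = self._cohort(20, 21, tiny_render)
        model = build_model(tiny_model_config(), seed=0)
        cfg = TrainConfig(
            batch_size=10, learning_rate=1e-3, epochs=10, seed=0, augment=False
        )
        _, history = train(model, cohort, cfg)
        assert history[-1]["l_total"] < history[0]["l_total"]

    def test_training_reproducible_from_seed(self, tiny_render):
        cohort = self._cohort(8, 22, tiny_render)
        cfg = TrainConfig(
            batch_size=4, learning_rate=1e-3, epochs=2, seed=9, augment=True
        )
        histories = []
        for _ in range(2):
            model = build_model(tiny_model_config(), seed=5)
            _, h = train(model, cohort, cfg)
            histories.append(h)
        assert histories[0] == histories[1]

    def test_loss_additivity_holds_every_epoch(self, tiny_render):
        cohort = self._cohort(8, 23, tiny_render)
        model = build_model(tiny_model_config(), seed=2)
        cfg = TrainConfig(
            batch_size=8, learning_rate=1e-4, epochs=3, seed=1, augment=False
        )
        _, history = train(model, cohort, cfg)
        for rec in history:
            parts = rec["l_ab"] + rec["l_ac"] + rec["l_abc"] + rec["l_fusion"]
            assert rec["l_total"] == pytest.approx(parts, rel=1e-5)

    def test_empty_cohort_rejected(self, tiny_render):
        empty = self._cohort(0, 1, tiny_render)
        model = build_model(tiny_model_config(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, empty, TrainConfig(epochs=1))

    def test_single_class_cohort_warns_but_proceeds(self, tiny_render):
        cohort = self._cohort(4, 1, tiny_render)
        for p in cohort.patients:
            p.label = 1
        model = build_model(tiny_model_config(), seed=0)
        cfg = TrainConfig(batch_size=4, learning_rate=1e-4, epochs=1, seed=0, augment=False)
        with pytest.warns(UserWarning, match="single class"):
            train(model, cohort, cfg)

    @pytest.mark.parametrize("head", ["ab", "ac", "abc", "fusion"])
    def test_each_head_alone_can_fit_a_tiny_cohort(self, head, tiny_render):
        """No dead wiring: optimising a single head's loss drives it down.

        The cohort is built so every head can separate it: positives have a
        quiet antrum with an inflamed body (IS_A=0, IS_B=4, IS_C=0), negatives
        the reverse (IS_A=4, IS_B=0, IS_C=0), so the antrum alone carries the
        signal and no head depends on a section it cannot see."""
        import pandas as pd

        from gscnet import PatientTriplet, SectionScores, render_section_image
        from gscnet.synthetic import Cohort

        patients = []
        for i in range(10):
            positive = i % 2 == 0
            scores = (
                SectionScores(0, 0, 2, 2, 0, 0)
                if positive
                else SectionScores(2, 2, 0, 0, 0, 0)
            )
            profile = scores.profile()
            imgs = {
                sec: render_section_image(sec, is_val, tiny_render, seed=100 + i)
                for sec, is_val in zip(
                    ("antrum", "body", "cardia"),
                    (profile.is_antrum, profile.is_body, profile.is_cardia),
                )
            }
            patients.append(
                PatientTriplet(
                    f"p{i}",
                    imgs["antrum"].astype(np.float32),
                    imgs["body"].astype(np.float32),
                    imgs["cardia"].astype(np.float32),
                    scores=scores,
                )
            )
        cohort = Cohort(patients, pd.DataFrame())
        model = build_model(tiny_model_config(), seed=3)
        labels = cohort.labels
        antrum, body, cardia = cohort.image_batches()
        optim = nn.Adam(model.parameters(), lr=2e-3)
        first = last = None
        for _ in range(40):
            out = model.forward(antrum, body, cardia)
            loss = nn.nll_base2(out.heads[head], labels, reduction="mean")
            optim.zero_grad()
            loss.backward()
            optim.step()
            last = loss.item()
            if first is None:
                first = last
        assert last < min(0.35, first / 2)
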